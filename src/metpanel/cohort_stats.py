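"""Cohort-level analytics: yields, variant breakdowns, treatability, odyssey.

All printed percentages use half-up rounding at the printed precision
(:func:`percent`); unknown stratum values are kept as their own visible row,
never dropped.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

import pandas as pd

from metpanel.classify_report import ReportRecord
from metpanel.panel_registry import PanelConfig
from metpanel.pipeline import PatientCase


def percent(numerator: int, denominator: int, decimals: int = 0) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("percent() denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


_STRATUM_FIELD = {
    "region": "region",
    "consanguinity": "consanguinity",
    "family_history": "family_history",
}


def diagnostic_yield(reports: Sequence[ReportRecord],
                     strata: str = "none", decimals: int = 0) -> pd.DataFrame:
    """Positive-report fraction overall or per stratum.

    Returns a table with n_positive, n_total and the half-up rounded
    percentage per stratum; reports with a missing stratum label form an
    explicit ``unknown`` row.
    """
    if strata == "none":
        rows = {"all": list(reports)}
    else:
        field = _STRATUM_FIELD[strata]
        rows = {}
        for r in reports:
            label = getattr(r, field) or "unknown"
            rows.setdefault(label, []).append(r)
    records = []
    for label in sorted(rows):
        group = rows[label]
        n_pos = sum(1 for r in group if r.status == "positive")
        records.append(
            {
                "stratum": label,
                "n_positive": n_pos,
                "n_total": len(group),
                "percent": percent(n_pos, len(group), decimals) if group else 0.0,
            }
        )
    return pd.DataFrame(records, columns=["stratum", "n_positive", "n_total",
                                          "percent"])


def variant_summary(reports: Sequence[ReportRecord]) -> Dict[str, object]:
    """Occurrence/unique counts and SNV/CNV splits over reported P/LP findings."""
    occurrences = []
    for r in reports:
        for f in r.findings:
            if f["final_class"] in ("P", "LP"):
                occurrences.append((f["variant_key"], f["variant_type"]))
    unique = {}
    for key, vtype in occurrences:
        unique.setdefault(key, vtype)
    n_unique = len(unique)
    n_snv = sum(1 for t in unique.values() if t == "snv")
    n_del = sum(1 for t in unique.values() if t == "cnv_deletion")
    n_dup = sum(1 for t in unique.values() if t == "cnv_duplication")
    n_cnv = n_del + n_dup
    counts: Dict[str, int] = {}
    for key, _ in occurrences:
        counts[key] = counts.get(key, 0) + 1
    recurrent = sorted(
        ((k, c) for k, c in counts.items() if c > 1),
        key=lambda kc: (-kc[1], kc[0]),
    )
    return {
        "occurrences": len(occurrences),
        "unique": n_unique,
        "snv_unique": n_snv,
        "cnv_unique": n_cnv,
        "cnv_deletions": n_del,
        "cnv_duplications": n_dup,
        "snv_share_percent": percent(n_snv, n_unique) if n_unique else 0.0,
        "cnv_deletion_share_percent": percent(n_del, n_cnv) if n_cnv else 0.0,
        "recurrent": recurrent,
    }


def treatable_fraction(reports: Sequence[ReportRecord],
                       panel: Optional[PanelConfig] = None,
                       decimals: int = 0) -> float:
    """Percent of positive cases whose (best) diagnosed disease is treatable."""
    positives = [r for r in reports if r.status == "positive"]
    if not positives:
        return 0.0
    treatable = {g.disease_id: g.treatable for g in panel.genes} if panel else None
    n_treat = 0
    for r in positives:
        f = r.findings[0] if r.findings else None
        if f is None:
            continue
        flag = treatable[f["disease_id"]] if treatable is not None else f["treatable"]
        if flag:
            n_treat += 1
    return percent(n_treat, len(positives), decimals)


def odyssey_summary(cases: Sequence[PatientCase],
                    over_threshold_years: float = 10.0) -> Dict[str, object]:
    """Symptom-onset-to-diagnosis gap: mean, range, count over threshold.

    Cases lacking either date are excluded and counted; a negative gap is a
    data error.
    """
    gaps = []
    excluded = 0
    for c in cases:
        if c.age_onset_years is None or c.age_diagnosis_years is None:
            excluded += 1
            continue
        gap = c.age_diagnosis_years - c.age_onset_years
        if gap < 0:
            raise ValueError(f"case {c.case_id}: diagnosis precedes onset")
        gaps.append(gap)
    if not gaps:
        return {"n": 0, "excluded": excluded, "mean_years": None,
                "min_years": None, "max_years": None, "n_over_threshold": 0}
    return {
        "n": len(gaps),
        "excluded": excluded,
        "mean_years": sum(gaps) / len(gaps),
        "min_years": min(gaps),
        "max_years": max(gaps),
        "n_over_threshold": sum(1 for g in gaps if g > over_threshold_years),
    }
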
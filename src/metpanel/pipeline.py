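"""End-to-end per-case orchestration of the diagnostic workflow.

Order of operations mirrors the laboratory flow: specimen QC gate, variant
triage against the panel, per-disease inheritance matching, reflex assay
ordering, interpretation of the available measurements, phase inference for
compound heterozygotes, biochemistry-informed classification, report
assembly. Multi-gene CNVs short-circuit into a syndromic finding that skips
single-gene biochemistry (a whole-chromosome-arm event is not an enzyme
deficiency question).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from pydantic import BaseModel, Field

from metpanel.classify_report import (
    ClassificationState,
    GeneFindingGroup,
    ReportRecord,
    apply_biochem,
    assign_report,
    base_classify,
    infer_phase,
)
from metpanel.inheritance_reflex import (
    BiochemResult,
    ReflexEligibility,
    interpret_biochem,
    match_inheritance,
    trigger_reflex,
)
from metpanel.panel_registry import PanelConfig
from metpanel.triage import triage_case
from metpanel.variant_io import AnnotatedSNV, CNVCall, QCSummary, specimen_qc


class PatientCase(BaseModel):
    """One patient's inputs: variants, metadata, optional measurements."""

    case_id: str
    sex: str = "unknown"
    region: Optional[str] = None
    consanguinity: Optional[bool] = None
    family_history: Optional[str] = None
    hpo_terms: List[str] = Field(default_factory=list)
    age_onset_years: Optional[float] = None
    age_testing_years: Optional[float] = None
    age_diagnosis_years: Optional[float] = None
    snvs: List[AnnotatedSNV] = Field(default_factory=list)
    cnvs: List[CNVCall] = Field(default_factory=list)
    biochem: Dict[str, float] = Field(default_factory=dict)
    qc: QCSummary = Field(
        default_factory=lambda: QCSummary(
            coverage_fraction_at_min_depth=1.0, min_depth=30
        )
    )


def _fmt_consanguinity(c: Optional[bool]) -> Optional[str]:
    if c is None:
        return None
    return "yes" if c else "no"


def analyze_case(case: PatientCase, panel: PanelConfig) -> ReportRecord:
    """Run the full workflow on one case and return its report."""
    t = panel.thresholds
    qc = specimen_qc(case.qc, t)
    triaged = triage_case(case.snvs, case.cnvs, panel)

    groups: List[GeneFindingGroup] = []
    eligibilities: List[ReflexEligibility] = []
    # (disease_id -> group) so reflex orders can be joined back
    pending: List[Tuple[GeneFindingGroup, List[str]]] = []
    syndromic_seen = set()

    for symbol in sorted(triaged):
        bucket = triaged[symbol]
        single_cnvs = [c for c in bucket.cnvs if not c.multi_gene]
        multi_cnvs = [c for c in bucket.cnvs if c.multi_gene]
        for gene in sorted(
            (g for g in panel.genes if g.symbol == symbol),
            key=lambda g: g.disease_id,
        ):
            if bucket.snvs or single_cnvs:
                eligibility = match_inheritance(
                    bucket.snvs, single_cnvs, gene, case.sex
                )
                states = [base_classify(s, gene, t) for s in bucket.snvs]
                states += [base_classify(c, gene, t) for c in single_cnvs]
                group = GeneFindingGroup(
                    gene=gene, eligibility=eligibility, states=states
                )
                groups.append(group)
                if eligibility.eligible:
                    eligibilities.append(eligibility)
                pending.append((group, list(gene.assay_ids)))
        # a multi-gene CNV becomes one syndromic group, reported once
        for c in multi_cnvs:
            if c.key in syndromic_seen:
                continue
            syndromic_seen.add(c.key)
            gene = next(g for g in panel.genes if g.symbol == symbol)
            state = base_classify(c, gene, t)
            groups.append(
                GeneFindingGroup(
                    gene=gene,
                    eligibility=ReflexEligibility(
                        gene=gene.symbol, disease_id=gene.disease_id,
                        eligible=True, genotype_pattern="het_single",
                        allele_count=1,
                    ),
                    states=[state],
                    syndromic=True,
                )
            )

    orders = trigger_reflex(eligibilities, panel)
    measured: Dict[str, BiochemResult] = {}
    for assay_id in orders:
        if assay_id in case.biochem:
            assay = panel.assay(assay_id)
            measured[assay_id] = interpret_biochem(
                case.biochem[assay_id], assay, t.grey_zone
            )

    for group, assay_ids in pending:
        if not group.eligibility.eligible:
            continue
        results = [measured[a] for a in assay_ids if a in measured]
        if not results:
            continue
        group.biochem = results
        group.phase = infer_phase(group.states, results, panel)
        group.states = [
            apply_biochem(s, results, group.gene, panel) for s in group.states
        ]

    return assign_report(
        case.case_id,
        groups,
        qc=qc,
        region=case.region,
        consanguinity=_fmt_consanguinity(case.consanguinity),
        family_history=case.family_history,
    )


def analyze_cohort(cases: Sequence[PatientCase],
                   panel: PanelConfig) -> List[ReportRecord]:
    return [analyze_case(c, panel) for c in cases]
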
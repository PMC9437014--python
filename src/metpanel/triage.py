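"""Semi-automated variant filter cascade for SNVs/indels and CNV selection.

An SNV survives triage when it is not previously asserted (likely) benign
internally and at least one inclusion criterion fires:

C1  prior internal five-class assertion P, LP or VUS;
C2  unclassified in the internal databank (gated by the same <1% rarity test
    as C3 unless ``c2_literal`` is set — the literal reading would retain
    every novel common variant);
C3  rare (external and internal healthy-cohort frequency < 1%, unknown
    counting as 0) with high/moderate predicted impact;
C4  asserted disease-causing by external databases (ClinVar/HGMD, collapsed);
C5  dbscSNV ADA and RF ensemble splice scores both > 0.6 (both required;
    an absent score fails).

Exclusion dominates: a prior internal LB/B assertion discards the variant
regardless of any other field. Retained variants with a failing quality flag
are marked for Sanger confirmation.

CNVs are retained below 2% frequency when they are homozygous deletions
(copy number 0, any span) or heterozygous deletions (1 copy) / duplications
(>2 copies) spanning more than 2 exons. Retained non-homozygous CNVs always
require orthogonal confirmation (qPCR / MLPA / CMA); homozygous deletions do
not.
"""

from __future__ import annotations

from typing import Dict, List, Literal, Optional, Set, Tuple, Union

from pydantic import BaseModel, Field

from metpanel.panel_registry import GeneRecord, PanelConfig, ThresholdConfig
from metpanel.variant_io import AnnotatedSNV, CNVCall

Criterion = Literal[
    "C1_prior_PLP_VUS",
    "C2_unclassified",
    "C3_rare_high_moderate",
    "C4_external_disease_causing",
    "C5_splice_scores",
    "CNV_hom_del",
    "CNV_het_multiexon",
]


class TriageDecision(BaseModel):
    retained: bool
    criteria_hit: List[Criterion] = Field(default_factory=list)
    excluded_by: Literal["none", "prior_benign"] = "none"
    confirmation: Literal["none", "sanger", "orthogonal_cnv"] = "none"


def _max_maf(v: AnnotatedSNV) -> float:
    """Rarity gate aggregates external and internal frequency; absent -> 0."""
    return max(v.maf_external or 0.0, v.maf_internal or 0.0)


def evaluate_snv(v: AnnotatedSNV, t: Optional[ThresholdConfig] = None) -> TriageDecision:
    """Apply the six-criteria SNV/indel cascade to one annotated variant."""
    t = t or ThresholdConfig()
    if v.prior_internal_class in ("LB", "B"):
        return TriageDecision(retained=False, excluded_by="prior_benign")
    rare = _max_maf(v) < t.maf_snv
    hit: List[Criterion] = []
    if v.prior_internal_class in ("P", "LP", "VUS"):
        hit.append("C1_prior_PLP_VUS")
    if v.prior_internal_class == "unclassified" and (t.c2_literal or rare):
        hit.append("C2_unclassified")
    if rare and v.impact in ("high", "moderate"):
        hit.append("C3_rare_high_moderate")
    if v.external_assertion == "disease_causing":
        hit.append("C4_external_disease_causing")
    if (
        v.ada_score is not None
        and v.rf_score is not None
        and v.ada_score > t.splice_score_min
        and v.rf_score > t.splice_score_min
    ):
        hit.append("C5_splice_scores")
    retained = bool(hit)
    confirmation = "sanger" if retained and not v.quality_ok else "none"
    return TriageDecision(retained=retained, criteria_hit=hit,
                          confirmation=confirmation)


def evaluate_cnv(c: CNVCall, gene: Optional[GeneRecord] = None,
                 t: Optional[ThresholdConfig] = None) -> TriageDecision:
    """Apply the CNV selection rules to one call.

    The exon-span requirement binds only to the heterozygous-deletion /
    duplication clause; a homozygous deletion of any span passes the
    structural test. Copy number 2 never passes. The span test is a
    sensitivity guard for automatic selection, so a call already confirmed
    by an orthogonal method (qPCR/MLPA/CMA) bypasses it — a confirmed
    two-exon deletion is real no matter what the caller's validation says.
    """
    t = t or ThresholdConfig()
    if (c.maf or 0.0) >= t.maf_cnv:
        return TriageDecision(retained=False)
    hit: List[Criterion] = []
    if c.copy_number == 0:
        hit.append("CNV_hom_del")
    elif c.copy_number == 1 or c.copy_number > 2:
        if c.exon_span >= t.het_cnv_min_exons or c.confirmed_by != "none":
            hit.append("CNV_het_multiexon")
    retained = bool(hit)
    confirmation = "orthogonal_cnv" if retained and c.copy_number != 0 else "none"
    return TriageDecision(retained=retained, criteria_hit=hit,
                          confirmation=confirmation)


class GeneTriageResult(BaseModel):
    """Retained variants of one case grouped by panel gene."""

    snvs: List[AnnotatedSNV] = Field(default_factory=list)
    cnvs: List[CNVCall] = Field(default_factory=list)
    decisions: Dict[str, TriageDecision] = Field(default_factory=dict)
    syndromic: bool = False


def _dedupe_snvs(snvs: List[AnnotatedSNV]) -> List[AnnotatedSNV]:
    seen: Set[tuple] = set()
    out = []
    for s in snvs:
        if s.key not in seen:
            seen.add(s.key)
            out.append(s)
    return out


def triage_case(snvs: List[AnnotatedSNV], cnvs: List[CNVCall],
                panel: PanelConfig) -> Dict[str, GeneTriageResult]:
    """Run both evaluators over a case, restricted to panel genes.

    Returns retained variants grouped by gene symbol. A multi-gene CNV is
    retained when any constituent panel gene passes the rules and is then
    attached to every such gene with a syndromic flag (large events crossing
    gene boundaries point at chromosomal syndromes, not single-gene disease).
    """
    t = panel.thresholds
    symbols = panel.gene_symbols
    by_symbol = {s: [g for g in panel.genes if g.symbol == s] for s in symbols}
    out: Dict[str, GeneTriageResult] = {}

    def bucket(sym: str) -> GeneTriageResult:
        if sym not in out:
            out[sym] = GeneTriageResult()
        return out[sym]

    for s in _dedupe_snvs(snvs):
        if s.gene not in symbols:
            continue
        d = evaluate_snv(s, t)
        if d.retained:
            b = bucket(s.gene)
            b.snvs.append(s)
            b.decisions[f"snv:{s.chrom}:{s.pos}:{s.ref}:{s.alt}"] = d
    seen_cnv: Set[tuple] = set()
    for c in cnvs:
        if c.key in seen_cnv:
            continue
        seen_cnv.add(c.key)
        panel_genes = [g for g in c.genes if g in symbols]
        if not panel_genes:
            continue
        gene_rec = by_symbol[panel_genes[0]][0]
        d = evaluate_cnv(c, gene_rec, t)
        if d.retained:
            for sym in panel_genes:
                b = bucket(sym)
                b.cnvs.append(c)
                b.decisions[f"cnv:{','.join(c.genes)}:{c.copy_number}:"
                            f"{c.exon_start}-{c.exon_end}"] = d
                if c.multi_gene:
                    b.syndromic = True
    return out
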
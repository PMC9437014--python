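"""Zygosity/inheritance matching, reflex assay ordering, biochem interpretation.

A disease entry becomes *eligible* when the retained variants' zygosity can
explain it under its mode of inheritance: autosomal recessive needs two
alleles (a homozygous variant, or two heterozygous variants treated as
potentially biallelic with unknown phase — phase is resolved later by
biochemistry or parental testing), autosomal dominant needs one, X-linked
needs a hemizygous male or homozygous female (heterozygous females only for
diseases flagged as manifesting in carriers). Eligibility plus an available
linked assay triggers a reflex biochemical order.
"""

from __future__ import annotations

from typing import List, Literal, Optional, Sequence

from pydantic import BaseModel, Field

from metpanel.panel_registry import AssayRecord, GeneRecord, PanelConfig
from metpanel.variant_io import AnnotatedSNV, CNVCall

GenotypePattern = Literal["hom", "comp_het_phase_unknown", "het_single", "hemi",
                          "het_x_female", "none"]


class DataInconsistencyError(ValueError):
    """Input contradicts itself (e.g. hemizygous call in a female sample)."""


class ReflexEligibility(BaseModel):
    gene: str
    disease_id: str
    eligible: bool
    genotype_pattern: GenotypePattern
    allele_count: int = Field(ge=0, le=2)


class BiochemResult(BaseModel):
    assay_id: str
    value: float
    units: str
    call: Literal["pathologic", "normal", "borderline"]


def _allele_contribution(zygosity: str) -> int:
    return {"hom": 2, "het": 1, "hemi": 1}[zygosity]


def _cnv_alleles(c: CNVCall) -> int:
    # 0-copy deletion hits both alleles; het deletion or duplication is one
    return 2 if c.copy_number == 0 else 1


def match_inheritance(snvs: Sequence[AnnotatedSNV], cnvs: Sequence[CNVCall],
                      gene: GeneRecord, sex: str = "unknown") -> ReflexEligibility:
    """Decide whether the retained variants in one gene fit its inheritance.

    SNV and CNV alleles combine: a heterozygous SNV plus a heterozygous
    deletion in the same gene counts as two alleles (compound, phase
    unknown), covering deletion-induced hemizygous-appearing SNVs as well.
    Raises :class:`DataInconsistencyError` for a hemizygous call in a female.
    """
    if sex == "female" and any(s.zygosity == "hemi" for s in snvs):
        raise DataInconsistencyError(
            f"hemizygous variant in {gene.symbol} for a female case"
        )
    n_variants = len(snvs) + len(cnvs)
    count = sum(_allele_contribution(s.zygosity) for s in snvs)
    count += sum(_cnv_alleles(c) for c in cnvs)
    count = min(count, 2)
    biallelic_single = any(s.zygosity == "hom" for s in snvs) or any(
        c.copy_number == 0 for c in cnvs
    )
    if n_variants == 0:
        pattern: GenotypePattern = "none"
    elif biallelic_single:
        pattern = "hom"
    elif count >= 2:
        pattern = "comp_het_phase_unknown"
    elif any(s.zygosity == "hemi" for s in snvs):
        pattern = "hemi"
    elif gene.inheritance == "XL" and sex == "female":
        pattern = "het_x_female"
    else:
        pattern = "het_single"

    if gene.inheritance == "AR":
        eligible = count >= 2
    elif gene.inheritance == "AD":
        eligible = count >= 1
    else:  # XL
        eligible = (
            pattern in ("hemi", "hom", "comp_het_phase_unknown")
            or (pattern in ("het_x_female", "het_single") and count >= 1
                and gene.female_het_reportable and sex != "male")
        )
    return ReflexEligibility(
        gene=gene.symbol,
        disease_id=gene.disease_id,
        eligible=eligible,
        genotype_pattern=pattern,
        allele_count=count,
    )


def trigger_reflex(eligibilities: Sequence[ReflexEligibility],
                   panel: PanelConfig) -> List[str]:
    """Assay ids to order for a case: one per eligible gene-linked assay.

    Genes without a linked assay produce no order; diseases sharing an
    analyte collapse to a single order. Output sorted for determinism.
    """
    ordered = set()
    by_disease = {g.disease_id: g for g in panel.genes}
    for e in eligibilities:
        if not e.eligible:
            continue
        gene = by_disease.get(e.disease_id)
        if gene is None:
            continue
        ordered.update(gene.assay_ids)
    return sorted(ordered)


def interpret_biochem(value: float, assay: AssayRecord,
                      grey_zone: float = 0.10,
                      units: Optional[str] = None) -> BiochemResult:
    """Call a measured analyte pathologic / normal / borderline.

    The grey zone is a band of width ``grey_zone`` (fractional) around the
    reference bound on the pathologic side of the interval: values beyond the
    bound by more than the band are pathologic, values inside the interval by
    more than the band are normal, anything in between (including a value
    exactly at the bound) is borderline. Deficiency assays (below_range) use
    the lower bound; accumulating biomarkers (above_range) the upper.
    """
    if units is not None and units != assay.units:
        raise ValueError(
            f"unit mismatch for {assay.assay_id}: got {units!r}, "
            f"assay reports {assay.units!r}"
        )
    if assay.pathologic_direction == "below_range":
        bound = assay.reference_low
        delta = grey_zone * abs(bound)
        if value < bound - delta:
            call = "pathologic"
        elif value > bound + delta:
            call = "normal"
        else:
            call = "borderline"
    else:
        bound = assay.reference_high
        delta = grey_zone * abs(bound)
        if value > bound + delta:
            call = "pathologic"
        elif value < bound - delta:
            call = "normal"
        else:
            call = "borderline"
    return BiochemResult(assay_id=assay.assay_id, value=value,
                         units=assay.units, call=call)
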
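"""Panel knowledge base: genes, diseases, inheritance modes, linked assays.

The registry drives every downstream stage: triage restricts variants to panel
genes, the inheritance matcher needs each disease entry's mode, reflex testing
needs the gene-to-assay links, and reporting needs the treatability flag. A
gene may carry several disease entries (e.g. distinct AR/AD disorders); each
entry is an independent :class:`GeneRecord`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

#: Closed set of metabolic-category labels used by the panel (18 categories).
CATEGORIES: frozenset = frozenset(
    {
        "lysosomal",
        "carbohydrate",
        "amino_acid_peptide",
        "organic_acid",
        "fatty_acid_oxidation",
        "urea_cycle",
        "metal_metabolism",
        "peroxisomal",
        "mitochondrial_energy",
        "glycosylation",
        "purine_pyrimidine",
        "neurotransmitter",
        "vitamin_cofactor",
        "lipid_lipoprotein",
        "steroid",
        "bile_acid_liver",
        "porphyrin_heme",
        "other_metabolic",
    }
)

Inheritance = Literal["AR", "AD", "XL"]


class GeneRecord(BaseModel):
    """One gene-disease entry of the panel.

    ``lof_mechanism`` marks diseases where loss of function is the established
    disease mechanism (novel truncating variants there classify as likely
    pathogenic). ``female_het_reportable`` makes heterozygous females eligible
    for X-linked entries whose phenotype manifests in carriers.
    """

    symbol: str
    transcript: str
    exon_count: int = Field(ge=1)
    inheritance: Inheritance
    disease_id: str
    disease_name: str
    category: str
    treatable: bool = False
    assay_ids: List[str] = Field(default_factory=list)
    chrom: str = "chr1"
    female_het_reportable: bool = False
    lof_mechanism: bool = True
    placeholder: bool = False


class AssayRecord(BaseModel):
    """A biochemical assay: enzyme activity or biomarker in dried blood spots.

    ``pathologic_direction`` states which side of the reference interval is
    disease-consistent: enzyme deficiencies are always ``below_range``;
    biomarkers accumulate (``above_range``, e.g. glucosylsphingosine) or are
    depleted (``below_range``, e.g. ceruloplasmin).
    """

    assay_id: str
    kind: Literal["enzyme_activity", "biomarker"]
    analyte: str
    pathologic_direction: Literal["below_range", "above_range"]
    reference_low: float
    reference_high: float
    units: str

    @field_validator("reference_high")
    @classmethod
    def _interval_ordered(cls, v, info):
        low = info.data.get("reference_low")
        if low is not None and not low < v:
            raise ValueError("reference_low must be < reference_high")
        return v


class ThresholdConfig(BaseModel):
    """All numeric cut-offs of the workflow, with their published defaults.

    maf_snv
        SNV rarity gate (external and internal healthy-cohort frequency < 1%).
    maf_cnv
        CNV rarity gate (< 2%).
    splice_score_min
        dbscSNV ADA and RF ensemble splice scores must both exceed 0.6.
    het_cnv_min_exons
        heterozygous deletions/duplications must affect > 2 exons, i.e. >= 3.
    qc_min_coverage_fraction / qc_min_depth
        specimen passes when >= 99.5% of targeted regions reach >= 20x.
    grey_zone
        fractional band around the pathologic-direction reference bound
        within which a biochemical value is called borderline.
    """

    maf_snv: float = Field(default=0.01, gt=0, le=1)
    maf_cnv: float = Field(default=0.02, gt=0, le=1)
    splice_score_min: float = Field(default=0.6, gt=0, le=1)
    het_cnv_min_exons: int = Field(default=3, ge=1)
    qc_min_coverage_fraction: float = Field(default=0.995, gt=0, le=1)
    qc_min_depth: int = Field(default=20, ge=1)
    healthy_cohort_size: int = Field(default=24000, ge=1)
    grey_zone: float = Field(default=0.10, ge=0, le=0.5)
    c2_literal: bool = False
    reflex_on_carrier: bool = False


class PanelConfig(BaseModel):
    genes: List[GeneRecord]
    assays: List[AssayRecord]
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)

    def assay(self, assay_id: str) -> AssayRecord:
        for a in self.assays:
            if a.assay_id == assay_id:
                return a
        raise KeyError(assay_id)

    @property
    def gene_symbols(self) -> set:
        return {g.symbol for g in self.genes}


class PanelFormatError(ValueError):
    """Config file failed to parse (message carries the offending line)."""


class PanelValidationError(ValueError):
    """Config parsed but violates panel invariants; message lists offenders."""

    def __init__(self, violations: List[str]):
        self.violations = violations
        super().__init__("invalid panel config:\n" + "\n".join(violations))


def validate_panel(panel: PanelConfig) -> List[str]:
    """Check the panel invariants and return the list of violations.

    An empty list means the panel is valid. Checks performed: at least one
    gene; category labels drawn from the closed 18-label set; unique
    (symbol, disease_id) pairs; every referenced assay id resolves; exon
    spans sane; X-linked entries on chrX.
    """
    violations: List[str] = []
    if not panel.genes:
        violations.append("panel contains no genes")
    known_assays = {a.assay_id for a in panel.assays}
    seen = set()
    for g in panel.genes:
        if g.category not in CATEGORIES:
            violations.append(f"gene {g.symbol}: unknown category {g.category!r}")
        key = (g.symbol, g.disease_id)
        if key in seen:
            violations.append(f"duplicate gene-disease entry {key}")
        seen.add(key)
        for aid in g.assay_ids:
            if aid not in known_assays:
                violations.append(f"gene {g.symbol}: dangling assay id {aid!r}")
        if g.inheritance == "XL" and g.chrom != "chrX":
            violations.append(f"gene {g.symbol}: XL entry not on chrX ({g.chrom})")
    for a in panel.assays:
        if a.kind == "enzyme_activity" and a.pathologic_direction != "below_range":
            violations.append(
                f"assay {a.assay_id}: enzyme activity must be pathologic below range"
            )
    return violations


def load_panel(path) -> PanelConfig:
    """Load and validate a panel config file (YAML dialect).

    The file has ``genes:``, ``assays:`` and optional ``thresholds:``
    sections; absent thresholds take the documented defaults. Raises
    :class:`PanelFormatError` on parse failure (naming the line) and
    :class:`PanelValidationError` listing every invariant violation.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise PanelFormatError(f"cannot parse panel config {path}{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise PanelFormatError(f"panel config {path} is not a mapping")
    panel = PanelConfig(
        genes=[GeneRecord(**g) for g in raw.get("genes", [])],
        assays=[AssayRecord(**a) for a in raw.get("assays", [])],
        thresholds=ThresholdConfig(**(raw.get("thresholds") or {})),
    )
    violations = validate_panel(panel)
    if violations:
        raise PanelValidationError(violations)
    return panel


def save_panel(panel: PanelConfig, path) -> None:
    """Serialize a panel back to the YAML dialect read by :func:`load_panel`."""
    raw = {
        "genes": [g.model_dump() for g in panel.genes],
        "assays": [a.model_dump() for a in panel.assays],
        "thresholds": panel.thresholds.model_dump(),
    }
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


def default_panel_path() -> Path:
    """Path of the packaged surrogate panel config (206 genes, 25 assays)."""
    return Path(__file__).parent / "data" / "default_panel.yaml"


def load_default_panel() -> PanelConfig:
    return load_panel(default_panel_path())


def lookup_gene(panel: PanelConfig, symbol: str) -> List[GeneRecord]:
    """All disease entries for ``symbol`` (empty list for unknown symbols)."""
    return [g for g in panel.genes if g.symbol == symbol]
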
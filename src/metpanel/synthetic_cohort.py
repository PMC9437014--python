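"""Seeded synthetic-cohort generator with ground truth.

Emulates the cohort structure of a global metabolic-panel referral
population: region mix dominated by Africa and Asia, ~30% reported parental
consanguinity among cases where it is known (half unknown), mostly
pre-school children, an autosomal-recessive-dominated disease spectrum
peaking at Gaucher disease, causal variants that are ~94% SNVs, and CNVs
that are ~85% deletions. Diagnosable cases carry mode-consistent genotypes
whose annotations pass the triage cascade; non-diagnosable cases carry only
common/benign/filtered-out variants (optionally a single heterozygous
carrier allele); an intermediate slice carries biallelic VUS in genes
without a linked assay and surfaces as "unclear". Biochemical measurements
are drawn pathologic with probability ``assay_sensitivity`` for truly
deficient patients and normal with probability ``assay_specificity``
otherwise.

Everything is driven by one seeded generator, so a fixed seed yields a
byte-identical serialized cohort.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from metpanel.panel_registry import GeneRecord, PanelConfig, load_default_panel
from metpanel.pipeline import PatientCase
from metpanel.variant_io import AnnotatedSNV, CNVCall, QCSummary, write_cnvs, write_snvs

DEFAULT_REGION_WEIGHTS: Dict[str, float] = {
    "Africa": 0.33,
    "Asia": 0.30,
    "Europe": 0.24,
    "LatinAmerica": 0.06,
    "MiddleEast": 0.06,
    "NorthAmerica": 0.01,
}

DEFAULT_DISEASE_WEIGHTS: Dict[str, float] = {
    "D_GAUCHER": 0.14, "D_NPAB": 0.09, "D_MPS1": 0.07, "D_PKU": 0.06,
    "D_WILSON": 0.05, "D_MPS4A": 0.045, "D_MPS2": 0.04, "D_GM1": 0.03,
    "D_NPC": 0.03, "D_MSUD2": 0.02, "D_CLN2": 0.02, "D_POMPE": 0.03,
    "D_FABRY": 0.02, "D_KRABBE": 0.02, "D_MLD": 0.02, "D_MPS6": 0.02,
    "D_MPS3A": 0.015, "D_MPS3B": 0.015, "D_MPS3C": 0.01, "D_MPS7": 0.01,
    "D_CAH": 0.03, "D_TYR1": 0.02, "D_BTD": 0.02, "D_GSD3": 0.03,
    "D_CYSTINURIA": 0.02, "D_LPI": 0.015, "D_FH": 0.03, "D_MENKES": 0.01,
    "D_ZSD1": 0.015, "D_ZSD12": 0.02, "D_AKU": 0.01, "D_DJS": 0.01,
    "D_FUCOSIDOSIS": 0.01, "D_PSAP": 0.005,
}

_HPO_POOL = [
    "HP:0001263",  # global developmental delay
    "HP:0002240",  # hepatomegaly
    "HP:0001250",  # seizures
    "HP:0000280",  # coarse facial features
    "HP:0001744",  # splenomegaly
    "HP:0001508",  # failure to thrive
    "HP:0002910",  # elevated transaminases
    "HP:0001252",  # hypotonia
]


class CohortParams(BaseModel):
    """Generator knobs; defaults encode the emulated study conditions."""

    n_patients: int = Field(ge=1)
    seed: int = 0
    region_weights: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    disease_weights: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DISEASE_WEIGHTS)
    )
    consanguinity_rate: float = Field(default=0.304, ge=0, le=1)
    consanguinity_known_rate: float = Field(default=0.50, ge=0, le=1)
    family_history_positive: float = Field(default=0.196, ge=0, le=1)
    family_history_negative: float = Field(default=0.036, ge=0, le=1)
    true_positive_rate: float = Field(default=0.37, ge=0, le=1)
    unclear_rate: float = Field(default=0.15, ge=0, le=1)
    snv_fraction_among_unique: float = Field(default=0.94, ge=0, le=1)
    cnv_deletion_fraction: float = Field(default=0.85, ge=0, le=1)
    assay_sensitivity: float = Field(default=0.95, ge=0, le=1)
    assay_specificity: float = Field(default=0.95, ge=0, le=1)
    vus_rate: float = Field(default=0.10, ge=0, le=1)
    prior_plp_rate: float = Field(default=0.70, ge=0, le=1)
    carrier_rate: float = Field(default=0.10, ge=0, le=1)
    ar_hom_rate: float = Field(default=0.50, ge=0, le=1)
    ar_hom_rate_consanguineous: float = Field(default=0.85, ge=0, le=1)
    benign_background_mean: float = Field(default=2.0, ge=0)
    onset_mean_years: float = Field(default=1.0, gt=0)
    onset_sigma: float = Field(default=1.0, gt=0)
    gap_mean_years: float = Field(default=2.0, gt=0)
    gap_sigma: float = Field(default=1.0, gt=0)
    gap_max_years: float = Field(default=20.0, gt=0)
    onset_known_rate: float = Field(default=0.102, ge=0, le=1)

    @model_validator(mode="after")
    def _weights_sum(self):
        for name, w in (("region_weights", self.region_weights),
                        ("disease_weights", self.disease_weights)):
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sum to {total}, expected 1")
        if self.true_positive_rate + self.unclear_rate > 1 + 1e-9:
            raise ValueError("true_positive_rate + unclear_rate exceeds 1")
        return self


class GroundTruth(BaseModel):
    case_id: str
    true_status: str  # diagnosable | not_diagnosable
    vus_only: bool = False
    true_disease: Optional[str] = None
    true_genotype_pattern: Optional[str] = None
    true_variant_classes: List[str] = Field(default_factory=list)
    biochem_truth: Dict[str, float] = Field(default_factory=dict)


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    mu = math.log(mean) - sigma ** 2 / 2.0
    return float(rng.lognormal(mu, sigma))


def _r6(x: float) -> float:
    """Clip to 6 significant digits, the precision the fixture files carry."""
    return float(f"{x:.6g}")


class _Generator:
    def __init__(self, params: CohortParams, panel: PanelConfig):
        self.p = params
        self.panel = panel
        self.rng = np.random.default_rng(params.seed)
        self.by_disease = {g.disease_id: g for g in panel.genes}
        self.gene_index = {g.disease_id: i for i, g in enumerate(panel.genes)}
        missing = [d for d in params.disease_weights if d not in self.by_disease]
        if missing:
            raise ValueError(f"disease_weights reference unknown diseases: {missing}")
        self.diseases = sorted(params.disease_weights)
        self.disease_p = np.array(
            [params.disease_weights[d] for d in self.diseases]
        )
        self.regions = sorted(params.region_weights)
        self.region_p = np.array([params.region_weights[r] for r in self.regions])
        # AR diseases without a linked assay host the unresolvable-VUS cases
        self.no_assay_ar = sorted(
            g.disease_id
            for g in panel.genes
            if g.inheritance == "AR" and not g.assay_ids and not g.placeholder
        )
        self.ar_diseases = sorted(
            g.disease_id for g in panel.genes
            if g.inheritance == "AR" and not g.placeholder
        )

    # --- variant builders -------------------------------------------------
    def _locus(self, gene: GeneRecord) -> Tuple[str, int]:
        idx = self.gene_index[gene.disease_id]
        return gene.chrom, 1_000_000 + idx * 100_000

    def _snv(self, gene: GeneRecord, zygosity: str, grade: str) -> AnnotatedSNV:
        rng = self.rng
        chrom, base = self._locus(gene)
        pos = int(base + rng.integers(0, 50_000))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        kwargs = dict(
            chrom=chrom, pos=pos, ref=str(ref), alt=str(alt),
            gene=gene.symbol, zygosity=zygosity,
            quality_ok=bool(rng.random() < 0.98),
            hgvs=f"{gene.transcript}:c.{pos - base + 1}{ref}>{alt}",
        )
        maf = _r6(rng.uniform(0, 0.005))
        if rng.random() < 0.7:
            kwargs["maf_external"] = maf
        if rng.random() < 0.7:
            kwargs["maf_internal"] = _r6(rng.uniform(0, 0.005))
        if grade == "plp":
            if rng.random() < self.p.prior_plp_rate:
                kwargs["prior_internal_class"] = "P" if rng.random() < 0.5 else "LP"
                kwargs["impact"] = "high" if rng.random() < 0.5 else "moderate"
            elif rng.random() < 0.5:
                kwargs["impact"] = "high"  # novel LoF
                kwargs["prior_internal_class"] = "absent"
            else:
                kwargs["impact"] = "moderate"
                kwargs["external_assertion"] = "disease_causing"
        elif grade == "vus":
            kwargs["impact"] = "moderate"
            kwargs["prior_internal_class"] = "absent"
        else:  # benign background
            kwargs["impact"] = "low" if rng.random() < 0.5 else "modifier"
            kwargs["maf_external"] = _r6(rng.uniform(0.02, 0.3))
            kwargs["maf_internal"] = _r6(rng.uniform(0.02, 0.3))
            if rng.random() < 0.3:
                kwargs["prior_internal_class"] = "LB" if rng.random() < 0.5 else "B"
        return AnnotatedSNV(**kwargs)

    def _cnv(self, gene: GeneRecord, copy_number: int) -> CNVCall:
        rng = self.rng
        span = int(rng.integers(3, min(6, gene.exon_count) + 1))
        start = int(rng.integers(1, gene.exon_count - span + 2))
        return CNVCall(
            genes=[gene.symbol], copy_number=copy_number,
            exon_start=start, exon_end=start + span - 1,
            maf=_r6(rng.uniform(0, 0.005)) if rng.random() < 0.5 else None,
            confirmed_by="none",
        )

    def _causal_allele(self, gene: GeneRecord, zygosity: str,
                      grade: str) -> Tuple[List[AnnotatedSNV], List[CNVCall]]:
        rng = self.rng
        # VUS-grade alleles stay SNVs: a multi-exon deletion is never
        # uncertain, and CNV evidence would defeat the unresolved-VUS purpose
        if grade == "plp" and rng.random() >= self.p.snv_fraction_among_unique \
                and gene.exon_count >= 3:
            if rng.random() < self.p.cnv_deletion_fraction:
                return [], [self._cnv(gene, copy_number=1)]
            return [], [self._cnv(gene, copy_number=3)]
        return [self._snv(gene, zygosity, grade)], []

    def _biochem_truth(self, gene: GeneRecord, deficient: bool) -> Dict[str, float]:
        rng = self.rng
        values: Dict[str, float] = {}
        for assay_id in gene.assay_ids:
            a = self.panel.assay(assay_id)
            hit = rng.random() < (
                self.p.assay_sensitivity if deficient
                else 1.0 - self.p.assay_specificity
            )
            lo, hi = a.reference_low, a.reference_high
            if hit:
                if a.pathologic_direction == "below_range":
                    values[assay_id] = _r6(lo * rng.uniform(0.05, 0.5))
                else:
                    values[assay_id] = _r6(hi * rng.uniform(1.5, 3.0))
            else:
                values[assay_id] = _r6(lo + (hi - lo) * rng.uniform(0.3, 0.7))
        return values

    # --- case builders ----------------------------------------------------
    def _metadata(self, case_id: str) -> PatientCase:
        rng = self.rng
        region = str(rng.choice(self.regions, p=self.region_p))
        consanguinity: Optional[bool] = None
        if rng.random() < self.p.consanguinity_known_rate:
            consanguinity = bool(rng.random() < self.p.consanguinity_rate)
        u = rng.random()
        if u < self.p.family_history_positive:
            family_history: Optional[str] = "positive"
        elif u < self.p.family_history_positive + self.p.family_history_negative:
            family_history = "negative"
        else:
            family_history = None
        onset = _lognormal(rng, self.p.onset_mean_years, self.p.onset_sigma)
        gap = min(_lognormal(rng, self.p.gap_mean_years, self.p.gap_sigma),
                  self.p.gap_max_years)
        onset_known = rng.random() < self.p.onset_known_rate
        n_hpo = int(rng.integers(1, 4))
        hpo = sorted(rng.choice(_HPO_POOL, size=n_hpo, replace=False).tolist())
        sex = "male" if rng.random() < 0.5 else "female"
        return PatientCase(
            case_id=case_id,
            sex=sex,
            region=region,
            consanguinity=consanguinity,
            family_history=family_history,
            hpo_terms=hpo,
            age_onset_years=round(onset, 3) if onset_known else None,
            age_testing_years=round(onset + gap, 3),
            age_diagnosis_years=round(onset + gap, 3) if onset_known else None,
            qc=QCSummary(
                coverage_fraction_at_min_depth=_r6(rng.uniform(0.995, 1.0)),
                min_depth=int(rng.integers(20, 40)),
            ),
        )

    def _add_background(self, case: PatientCase) -> None:
        rng = self.rng
        n = int(rng.poisson(self.p.benign_background_mean))
        genes = self.panel.genes
        for _ in range(n):
            g = genes[int(rng.integers(0, len(genes)))]
            zyg = "het"
            if g.inheritance == "XL":
                zyg = "hemi" if case.sex == "male" else "het"
            case.snvs.append(self._snv(g, zyg, "benign"))

    def _diagnosable(self, case: PatientCase, truth: GroundTruth) -> None:
        rng = self.rng
        disease = str(rng.choice(self.diseases, p=self.disease_p))
        gene = self.by_disease[disease]
        if gene.inheritance == "XL":
            case.sex = "male"
        grade = (
            "vus"
            if gene.assay_ids and rng.random() < self.p.vus_rate
            else "plp"
        )
        snvs: List[AnnotatedSNV] = []
        cnvs: List[CNVCall] = []
        if gene.inheritance == "AR":
            hom_rate = (
                self.p.ar_hom_rate_consanguineous
                if case.consanguinity
                else self.p.ar_hom_rate
            )
            if rng.random() < hom_rate:
                s, c = self._causal_allele(gene, "hom", grade)
                if c:  # homozygous CNV deletion
                    c[0] = c[0].model_copy(update={"copy_number": 0})
                snvs, cnvs = s, c
                pattern = "hom"
            else:
                for _ in range(2):
                    s, c = self._causal_allele(gene, "het", grade)
                    snvs += s
                    cnvs += c
                pattern = "comp_het_phase_unknown"
        elif gene.inheritance == "AD":
            s, c = self._causal_allele(gene, "het", grade)
            snvs, cnvs = s, c
            pattern = "het_single"
        else:  # XL male
            s, c = self._causal_allele(gene, "hemi", grade)
            if c:
                # a deletion on the single male X leaves zero copies
                c[0] = c[0].model_copy(update={"copy_number": 0})
            snvs, cnvs = s, c
            pattern = "hemi"
        case.snvs.extend(snvs)
        case.cnvs.extend(cnvs)
        truth.true_status = "diagnosable"
        truth.true_disease = disease
        truth.true_genotype_pattern = pattern
        truth.true_variant_classes = [
            "VUS" if grade == "vus" else "P/LP"
        ] * max(1, len(snvs) + len(cnvs))
        truth.biochem_truth = self._biochem_truth(gene, deficient=True)
        case.biochem.update(truth.biochem_truth)

    def _unclear(self, case: PatientCase, truth: GroundTruth) -> None:
        rng = self.rng
        disease = str(rng.choice(self.no_assay_ar))
        gene = self.by_disease[disease]
        for _ in range(2):
            case.snvs.append(self._snv(gene, "het", "vus"))
        truth.true_status = "not_diagnosable"
        truth.vus_only = True
        truth.true_disease = disease
        truth.true_genotype_pattern = "comp_het_phase_unknown"
        truth.true_variant_classes = ["VUS", "VUS"]

    def _negative(self, case: PatientCase, truth: GroundTruth) -> None:
        rng = self.rng
        truth.true_status = "not_diagnosable"
        if rng.random() < self.p.carrier_rate:
            disease = str(rng.choice(self.ar_diseases))
            gene = self.by_disease[disease]
            case.snvs.append(self._snv(gene, "het", "plp"))
            truth.true_genotype_pattern = "het_single"

    def generate(self) -> Tuple[List[PatientCase], List[GroundTruth]]:
        cases: List[PatientCase] = []
        truths: List[GroundTruth] = []
        p_diag = self.p.true_positive_rate
        p_unclear = self.p.unclear_rate
        for i in range(self.p.n_patients):
            case = self._metadata(f"CASE{i:05d}")
            truth = GroundTruth(case_id=case.case_id, true_status="not_diagnosable")
            u = self.rng.random()
            self._add_background(case)
            if u < p_diag:
                self._diagnosable(case, truth)
            elif u < p_diag + p_unclear:
                self._unclear(case, truth)
            else:
                self._negative(case, truth)
            if truth.true_status != "diagnosable":
                case.age_diagnosis_years = None
            case.snvs.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
            case.cnvs.sort(key=lambda c: c.key)
            cases.append(case)
            truths.append(truth)
        return cases, truths


def generate_cohort(params: CohortParams,
                    panel: Optional[PanelConfig] = None
                    ) -> Tuple[List[PatientCase], List[GroundTruth]]:
    """Generate a reproducible synthetic cohort with ground truth.

    Identical params (including seed) yield identical output. The packaged
    default panel is used unless another panel is supplied.
    """
    panel = panel or load_default_panel()
    return _Generator(params, panel).generate()


def emit_fixture_files(cases: Sequence[PatientCase], out_dir,
                       panel: Optional[PanelConfig] = None) -> List[Path]:
    """Write per-case fixture files: VCF, CNV TSV, assay TSV, metadata TSV.

    Four files per case, re-readable into equal records; output is
    deterministic (stable ordering and formatting) so checksums are stable
    across runs for a fixed cohort.
    """
    panel = panel or load_default_panel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    units = {a.assay_id: a.units for a in panel.assays}
    written: List[Path] = []
    for case in cases:
        vcf = out_dir / f"{case.case_id}.vcf"
        write_snvs(case.snvs, vcf, sample_id=case.case_id)
        cnv = out_dir / f"{case.case_id}.cnv.tsv"
        write_cnvs(case.cnvs, cnv, sample_id=case.case_id)
        assay = out_dir / f"{case.case_id}.assays.tsv"
        rows = [
            {"case_id": case.case_id, "assay_id": aid,
             "value": f"{case.biochem[aid]:.6g}", "units": units.get(aid, "")}
            for aid in sorted(case.biochem)
        ]
        pd.DataFrame(rows, columns=["case_id", "assay_id", "value", "units"]
                     ).to_csv(assay, sep="\t", index=False)
        meta = out_dir / f"{case.case_id}.meta.tsv"
        pd.DataFrame(
            [{
                "case_id": case.case_id,
                "sex": case.sex,
                "region": case.region or "",
                "consanguinity": {True: "yes", False: "no", None: ""}[case.consanguinity],
                "family_history": case.family_history or "",
                "hpo_terms": ";".join(case.hpo_terms),
                "age_onset_years": "" if case.age_onset_years is None else case.age_onset_years,
                "age_testing_years": "" if case.age_testing_years is None else case.age_testing_years,
                "age_diagnosis_years": "" if case.age_diagnosis_years is None else case.age_diagnosis_years,
                "qc_coverage": case.qc.coverage_fraction_at_min_depth,
                "qc_min_depth": case.qc.min_depth,
            }]
        ).to_csv(meta, sep="\t", index=False)
        written += [vcf, cnv, assay, meta]
    return written


def load_fixture_case(out_dir, case_id: str,
                      panel: Optional[PanelConfig] = None) -> PatientCase:
    """Re-read one case written by :func:`emit_fixture_files`."""
    from metpanel.variant_io import read_cnvs, read_snvs

    panel = panel or load_default_panel()
    out_dir = Path(out_dir)
    meta = pd.read_csv(out_dir / f"{case_id}.meta.tsv", sep="\t",
                       keep_default_na=False)
    row = meta.iloc[0]

    def _opt_float(v):
        return None if v == "" else float(v)

    assays = pd.read_csv(out_dir / f"{case_id}.assays.tsv", sep="\t")
    biochem = (
        {r["assay_id"]: float(r["value"]) for _, r in assays.iterrows()}
        if len(assays)
        else {}
    )
    return PatientCase(
        case_id=case_id,
        sex=row["sex"],
        region=row["region"] or None,
        consanguinity={"yes": True, "no": False, "": None}[str(row["consanguinity"])],
        family_history=row["family_history"] or None,
        hpo_terms=[h for h in str(row["hpo_terms"]).split(";") if h],
        age_onset_years=_opt_float(row["age_onset_years"]),
        age_testing_years=_opt_float(row["age_testing_years"]),
        age_diagnosis_years=_opt_float(row["age_diagnosis_years"]),
        snvs=read_snvs(out_dir / f"{case_id}.vcf"),
        cnvs=read_cnvs(out_dir / f"{case_id}.cnv.tsv", panel),
        biochem=biochem,
        qc=QCSummary(
            coverage_fraction_at_min_depth=float(row["qc_coverage"]),
            min_depth=int(row["qc_min_depth"]),
        ),
    )
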
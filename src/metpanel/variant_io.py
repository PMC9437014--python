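"""Read annotated SNVs (VCF) and CNV calls (TSV), QC gating, report output.

SNVs arrive as a single-sample VCF 4.2 whose INFO fields carry the
annotations the filter cascade consumes (gene, impact tier, external and
internal population frequencies, prior internal five-class assertion,
collapsed external database assertion, dbscSNV ADA/RF splice scores, quality
flag). The INFO keys are configurable via a field mapping; absent annotations
stay absent — they are never coerced to zero, because "frequency unknown" and
"frequency 0" behave differently in the rarity gate only by convention, and
that convention lives in the triage module, not the reader.

Coordinates are VCF 1-based inclusive; CNV exon indices are 1-based inclusive
on the panel transcript ("exons 8-10" spans three exons).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Literal, Optional

import pandas as pd
import pysam
from pydantic import BaseModel, Field, field_validator

from metpanel.panel_registry import PanelConfig, ThresholdConfig

Zygosity = Literal["het", "hom", "hemi"]
Impact = Literal["high", "moderate", "low", "modifier"]
PriorClass = Literal["P", "LP", "VUS", "LB", "B", "unclassified", "absent"]
ExternalAssertion = Literal["disease_causing", "benign_assertion", "none"]

#: default VCF INFO keys for each annotation field
DEFAULT_FIELD_MAP: Dict[str, str] = {
    "gene": "GENE",
    "impact": "IMPACT",
    "maf_external": "MAF_EXT",
    "maf_internal": "MAF_INT",
    "prior_internal_class": "PRIOR",
    "external_assertion": "ASSERT",
    "ada_score": "ADA",
    "rf_score": "RF",
    "quality_ok": "QOK",
    "hgvs": "HGVS",
}


class AnnotatedSNV(BaseModel):
    """One ALT allele of one sample with the annotations triage consumes."""

    chrom: str
    pos: int = Field(ge=1)
    ref: str
    alt: str
    gene: str
    zygosity: Zygosity
    impact: Impact = "modifier"
    maf_external: Optional[float] = Field(default=None, ge=0, le=1)
    maf_internal: Optional[float] = Field(default=None, ge=0, le=1)
    prior_internal_class: PriorClass = "absent"
    external_assertion: ExternalAssertion = "none"
    ada_score: Optional[float] = Field(default=None, ge=0, le=1)
    rf_score: Optional[float] = Field(default=None, ge=0, le=1)
    quality_ok: bool = True
    hgvs: str = ""

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt, self.zygosity)


class CNVCall(BaseModel):
    """A copy-number call over one or more panel genes, exon-resolved."""

    genes: List[str]
    copy_number: int = Field(ge=0)
    exon_start: int = Field(ge=1)
    exon_end: int = Field(ge=1)
    maf: Optional[float] = Field(default=None, ge=0, le=1)
    confirmed_by: Literal["none", "qPCR", "MLPA", "CMA"] = "none"

    @field_validator("exon_end")
    @classmethod
    def _span_ordered(cls, v, info):
        start = info.data.get("exon_start")
        if start is not None and v < start:
            raise ValueError("exon_end must be >= exon_start")
        return v

    @property
    def multi_gene(self) -> bool:
        return len(self.genes) > 1

    @property
    def exon_span(self) -> int:
        return self.exon_end - self.exon_start + 1

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2

    @property
    def key(self) -> tuple:
        return (tuple(self.genes), self.copy_number, self.exon_start, self.exon_end)


class QCSummary(BaseModel):
    coverage_fraction_at_min_depth: float = Field(ge=0, le=1)
    min_depth: int = Field(ge=0)


class VCFParseError(ValueError):
    pass


class FieldMapError(KeyError):
    pass


def _decode_info(value):
    if isinstance(value, tuple):
        value = value[0]
    if isinstance(value, bytes):
        value = value.decode()
    return value


def read_snvs(vcf_path, field_map: Optional[Dict[str, str]] = None,
              sample_sex: str = "unknown") -> List[AnnotatedSNV]:
    """Read a single-sample annotated VCF into :class:`AnnotatedSNV` records.

    Emits one record per ALT allele per non-reference genotype. Multi-allelic
    sites decompose into one record per ALT. Haploid genotypes (single-entry
    GT, e.g. male chrX) map to ``hemi``; ``0/1`` to ``het``; ``1/1`` to
    ``hom``. Annotations missing from INFO stay ``None``/defaults.
    """
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        unknown = set(field_map) - set(DEFAULT_FIELD_MAP)
        if unknown:
            raise FieldMapError(f"unknown annotation field(s): {sorted(unknown)}")
        fmap.update(field_map)
    out: List[AnnotatedSNV] = []
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (ValueError, OSError) as exc:
        raise VCFParseError(f"cannot open VCF {vcf_path}: {exc}") from exc
    with vf:
        for rec in vf:
            info = dict(rec.info)
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None:
                    continue
                alleles = [a for a in gt if a is not None]
                if not alleles or all(a == 0 for a in alleles):
                    continue
                for alt_index in sorted({a for a in alleles if a > 0}):
                    alt = rec.alts[alt_index - 1]
                    n_alt = sum(1 for a in alleles if a == alt_index)
                    if len(alleles) == 1:
                        zyg = "hemi"
                    elif n_alt == len(alleles):
                        zyg = "hom"
                    else:
                        zyg = "het"
                    kwargs = dict(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        gene=_decode_info(info.get(fmap["gene"], "")) or "",
                        zygosity=zyg,
                    )
                    for field in ("impact", "prior_internal_class",
                                  "external_assertion", "hgvs"):
                        v = _decode_info(info.get(fmap[field]))
                        if v is not None:
                            kwargs[field] = str(v)
                    for field in ("maf_external", "maf_internal", "ada_score",
                                  "rf_score"):
                        v = _decode_info(info.get(fmap[field]))
                        if v is not None:
                            # htslib stores Float INFO as float32; restore the
                            # 6-significant-digit precision the writer emits
                            kwargs[field] = float(f"{float(v):.6g}")
                    qok = _decode_info(info.get(fmap["quality_ok"]))
                    if qok is not None:
                        kwargs["quality_ok"] = str(qok) not in ("0", "false", "False")
                    out.append(AnnotatedSNV(**kwargs))
    return out


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
    '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Consequence impact tier">',
    '##INFO=<ID=MAF_EXT,Number=1,Type=Float,Description="External MAF">',
    '##INFO=<ID=MAF_INT,Number=1,Type=Float,Description="Internal healthy-cohort MAF">',
    '##INFO=<ID=PRIOR,Number=1,Type=String,Description="Prior internal five-class assertion">',
    '##INFO=<ID=ASSERT,Number=1,Type=String,Description="Collapsed external database assertion">',
    '##INFO=<ID=ADA,Number=1,Type=Float,Description="dbscSNV ADA splice score">',
    '##INFO=<ID=RF,Number=1,Type=Float,Description="dbscSNV RF splice score">',
    '##INFO=<ID=QOK,Number=1,Type=Integer,Description="Quality flag (1=ok)">',
    '##INFO=<ID=HGVS,Number=1,Type=String,Description="Transcript-level HGVS">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_snvs(snvs: List[AnnotatedSNV], vcf_path, sample_id: str = "SAMPLE") -> None:
    """Write records back to a single-sample VCF readable by :func:`read_snvs`.

    Output is deterministic: records sorted by (chrom, pos, ref, alt), fixed
    float formatting, stable header.
    """
    contigs = sorted({s.chrom for s in snvs})
    lines = list(VCF_HEADER_LINES)
    lines[1:1] = [f"##contig=<ID={c}>" for c in contigs]
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}")
    for s in sorted(snvs, key=lambda s: (s.chrom, s.pos, s.ref, s.alt)):
        info = [f"GENE={s.gene}", f"IMPACT={s.impact}"]
        if s.maf_external is not None:
            info.append(f"MAF_EXT={s.maf_external:.6g}")
        if s.maf_internal is not None:
            info.append(f"MAF_INT={s.maf_internal:.6g}")
        info.append(f"PRIOR={s.prior_internal_class}")
        info.append(f"ASSERT={s.external_assertion}")
        if s.ada_score is not None:
            info.append(f"ADA={s.ada_score:.6g}")
        if s.rf_score is not None:
            info.append(f"RF={s.rf_score:.6g}")
        info.append(f"QOK={1 if s.quality_ok else 0}")
        if s.hgvs:
            info.append(f"HGVS={s.hgvs}")
        gt = {"het": "0/1", "hom": "1/1", "hemi": "1"}[s.zygosity]
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t{';'.join(info)}\tGT\t{gt}"
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")


CNV_COLUMNS = ["sample", "genes", "copy_number", "exon_start", "exon_end", "maf",
               "confirmed_by"]


def read_cnvs(table_path, panel: Optional[PanelConfig] = None) -> List[CNVCall]:
    """Read CNV calls from a TSV with the documented header.

    ``genes`` is a comma-separated symbol list. When a panel is given, exon
    indices are validated against each constituent panel gene's exon count.
    """
    df = pd.read_csv(table_path, sep="\t", dtype={"genes": str})
    missing = set(CNV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CNV table missing column(s): {sorted(missing)}")
    calls: List[CNVCall] = []
    for _, row in df.iterrows():
        maf = row["maf"]
        call = CNVCall(
            genes=[g.strip() for g in str(row["genes"]).split(",") if g.strip()],
            copy_number=int(row["copy_number"]),
            exon_start=int(row["exon_start"]),
            exon_end=int(row["exon_end"]),
            maf=None if pd.isna(maf) else float(maf),
            confirmed_by=row["confirmed_by"] if isinstance(row["confirmed_by"], str) else "none",
        )
        if panel is not None:
            for g in panel.genes:
                if g.symbol in call.genes and not call.multi_gene \
                        and call.exon_end > g.exon_count:
                    raise ValueError(
                        f"CNV exon_end {call.exon_end} exceeds exon count "
                        f"{g.exon_count} of {g.symbol}"
                    )
        calls.append(call)
    return calls


def write_cnvs(calls: List[CNVCall], table_path, sample_id: str = "SAMPLE") -> None:
    rows = [
        {
            "sample": sample_id,
            "genes": ",".join(c.genes),
            "copy_number": c.copy_number,
            "exon_start": c.exon_start,
            "exon_end": c.exon_end,
            "maf": "" if c.maf is None else f"{c.maf:.6g}",
            "confirmed_by": c.confirmed_by,
        }
        for c in sorted(calls, key=lambda c: c.key)
    ]
    pd.DataFrame(rows, columns=CNV_COLUMNS).to_csv(table_path, sep="\t", index=False)


def specimen_qc(qc: QCSummary, thresholds: ThresholdConfig) -> str:
    """Specimen-level sequencing QC gate: 'pass' or 'fail'.

    Passes when coverage at the minimum depth reaches the configured fraction
    (default 99.5%) and the minimum read depth reaches the configured floor
    (default 20x). Monotone in both arguments.
    """
    ok = (
        qc.coverage_fraction_at_min_depth >= thresholds.qc_min_coverage_fraction
        and qc.min_depth >= thresholds.qc_min_depth
    )
    return "pass" if ok else "fail"


def write_report(report, path, format: str = "json") -> None:
    """Serialize a ReportRecord; byte-stable for identical inputs."""
    path = Path(path)
    if format == "json":
        payload = report.model_dump()
        path.write_text(json.dumps(payload, sort_keys=True, indent=1,
                                   default=str) + "\n")
    elif format == "tsv":
        rows = []
        for f in report.findings:
            rows.append({
                "case_id": report.case_id,
                "status": report.status,
                "gene": f["gene"],
                "variant": f["variant_key"],
                "final_class": f["final_class"],
                "genotype_pattern": f["genotype_pattern"],
                "disease": f["disease_id"],
                "treatable": f["treatable"],
            })
        if not rows:
            rows.append({"case_id": report.case_id, "status": report.status,
                         "gene": "", "variant": "", "final_class": "",
                         "genotype_pattern": "", "disease": "", "treatable": ""})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path):
    from metpanel.classify_report import ReportRecord

    return ReportRecord(**json.loads(Path(path).read_text()))
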
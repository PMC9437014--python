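"""Shared fixtures: the packaged panel and the six narrated clinical cases."""

import pytest
from hypothesis import settings

from metpanel.panel_registry import load_default_panel
from metpanel.pipeline import PatientCase
from metpanel.variant_io import AnnotatedSNV, CNVCall

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


def snv(gene, chrom, pos, zygosity, **kw):
    return AnnotatedSNV(chrom=chrom, pos=pos, ref="G", alt="A", gene=gene,
                        zygosity=zygosity, **kw)


def narrated_cases():
    """The six worked clinical scenarios used throughout the suite.

    An infant with a heterozygous novel frameshift plus a confirmed
    heterozygous two-exon DBT deletion (maple syrup urine disease II); a
    Gaucher compound heterozygote (curated missense + exon 8-10 deletion)
    with deficient enzyme and raised lyso-Gb1; a GM1-gangliosidosis case
    whose frameshift appears hemizygous inside an exon 1-17 deletion; a
    PSAP compound-het VUS pair with a normal biomarker; a homozygous
    intronic GALNS splice candidate excluded by a normal enzyme; and a TPP1
    missense pair whose normal enzyme activity places them in cis.
    """
    return {
        "DBT": PatientCase(
            case_id="DBT", sex="male",
            snvs=[snv("DBT", "chr1", 2000, "het", impact="high",
                      maf_external=0.0001)],
            cnvs=[CNVCall(genes=["DBT"], copy_number=1, exon_start=2,
                          exon_end=3, confirmed_by="MLPA")],
        ),
        "GBA": PatientCase(
            case_id="GBA", sex="male",
            snvs=[snv("GBA", "chr1", 1448, "het", impact="moderate",
                      prior_internal_class="P")],
            cnvs=[CNVCall(genes=["GBA"], copy_number=1, exon_start=8,
                          exon_end=10, confirmed_by="qPCR")],
            biochem={"ENZ_GBA": 0.3, "BM_LYSOGB1": 30.0},
        ),
        "GLB1": PatientCase(
            case_id="GLB1", sex="male",
            snvs=[snv("GLB1", "chr3", 500, "hemi", impact="high",
                      maf_external=0.0)],
            cnvs=[CNVCall(genes=["GLB1"], copy_number=1, exon_start=1,
                          exon_end=17, confirmed_by="CMA")],
            biochem={"ENZ_BGAL": 0.5},
        ),
        "PSAP": PatientCase(
            case_id="PSAP", sex="female",
            snvs=[snv("PSAP", "chr10", 100, "het", impact="moderate",
                      maf_external=0.0005),
                  snv("PSAP", "chr10", 900, "het", impact="moderate",
                      maf_external=0.0002)],
            biochem={"BM_LYSOGB1": 3.0},
        ),
        "GALNS": PatientCase(
            case_id="GALNS", sex="female",
            snvs=[snv("GALNS", "chr16", 1020, "hom", impact="modifier",
                      ada_score=0.88, rf_score=0.79, maf_external=0.0)],
            biochem={"ENZ_GALNS": 6.0},
        ),
        "TPP1": PatientCase(
            case_id="TPP1", sex="male",
            snvs=[snv("TPP1", "chr11", 340, "het", impact="moderate",
                      maf_external=0.0001),
                  snv("TPP1", "chr11", 1033, "het", impact="moderate",
                      maf_external=0.0)],
            biochem={"ENZ_TPP1": 14.0},
        ),
    }


@pytest.fixture()
def cases():
    return narrated_cases()
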
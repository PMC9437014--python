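"""Regenerate the packaged surrogate panel config (src/metpanel/data/default_panel.yaml).

The shipped panel carries every gene the workflow's documentation discusses,
with inheritance modes and assay links matching their diseases, plus marked
placeholder entries (``placeholder: true``, GPADnnn symbols) padding the gene
count to 206 across the 18 metabolic categories. Reference intervals are
synthetic round numbers; no test depends on placeholder biology.

Run from the repo root:  python scripts/build_default_panel.py
"""

from pathlib import Path

import yaml

ENZ = "enzyme_activity"
BM = "biomarker"

# assay_id, kind, analyte, direction, low, high, units
ASSAYS = [
    ("ENZ_GBA", ENZ, "beta-glucocerebrosidase", "below_range", 2.0, 20.0, "umol/L/h"),
    ("ENZ_ASM", ENZ, "acid sphingomyelinase", "below_range", 1.5, 15.0, "umol/L/h"),
    ("ENZ_BGAL", ENZ, "beta-galactosidase", "below_range", 3.0, 30.0, "umol/L/h"),
    ("ENZ_GALNS", ENZ, "N-acetylgalactosamine-6-sulfatase", "below_range", 1.0, 12.0, "umol/L/h"),
    ("ENZ_TPP1", ENZ, "tripeptidyl peptidase 1", "below_range", 2.5, 25.0, "umol/L/h"),
    ("ENZ_IDUA", ENZ, "alpha-L-iduronidase", "below_range", 1.2, 14.0, "umol/L/h"),
    ("ENZ_IDS", ENZ, "iduronate-2-sulfatase", "below_range", 2.0, 24.0, "umol/L/h"),
    ("ENZ_ARSB", ENZ, "arylsulfatase B", "below_range", 1.0, 10.0, "umol/L/h"),
    ("ENZ_GUSB", ENZ, "beta-glucuronidase", "below_range", 2.0, 18.0, "umol/L/h"),
    ("ENZ_HGSNAT", ENZ, "heparan-alpha-glucosaminide N-acetyltransferase", "below_range", 0.8, 8.0, "umol/L/h"),
    ("ENZ_NAGLU", ENZ, "alpha-N-acetylglucosaminidase", "below_range", 0.6, 6.0, "umol/L/h"),
    ("ENZ_SGSH", ENZ, "heparan N-sulfatase", "below_range", 0.5, 5.0, "umol/L/h"),
    ("ENZ_AGAL", ENZ, "alpha-galactosidase A", "below_range", 1.5, 16.0, "umol/L/h"),
    ("ENZ_GAA", ENZ, "acid alpha-glucosidase", "below_range", 1.0, 11.0, "umol/L/h"),
    ("ENZ_GALC", ENZ, "galactocerebrosidase", "below_range", 0.8, 9.0, "umol/L/h"),
    ("ENZ_ARSA", ENZ, "arylsulfatase A", "below_range", 1.5, 15.0, "umol/L/h"),
    ("ENZ_FUCA", ENZ, "alpha-L-fucosidase", "below_range", 2.0, 22.0, "umol/L/h"),
    ("ENZ_BTD", ENZ, "biotinidase", "below_range", 3.5, 35.0, "umol/L/h"),
    ("BM_LYSOGB1", BM, "glucosylsphingosine (lyso-Gb1)", "above_range", 0.0, 6.8, "ng/mL"),
    ("BM_LYSOSM", BM, "lyso-sphingomyelin", "above_range", 0.0, 2.0, "ng/mL"),
    ("BM_LYSOSM509", BM, "lyso-sphingomyelin-509", "above_range", 0.0, 1.4, "ng/mL"),
    ("BM_PHE", BM, "phenylalanine", "above_range", 25.0, 120.0, "umol/L"),
    ("BM_17OHP", BM, "17-hydroxyprogesterone", "above_range", 0.2, 10.0, "nmol/L"),
    ("BM_CERULO", BM, "ceruloplasmin", "below_range", 20.0, 60.0, "mg/dL"),
    ("BM_SUAC", BM, "succinylacetone", "above_range", 0.1, 2.0, "umol/L"),
]

# symbol, transcript, exons, inh, disease_id, disease_name, category,
# treatable, assay_ids, chrom, female_het_reportable
REAL_GENES = [
    ("GBA", "NM_000157.4", 11, "AR", "D_GAUCHER", "Gaucher disease", "lysosomal", True, ["ENZ_GBA", "BM_LYSOGB1"], "chr1", False),
    ("SMPD1", "NM_000543.5", 6, "AR", "D_NPAB", "Niemann-Pick disease type A/B", "lysosomal", True, ["ENZ_ASM", "BM_LYSOSM"], "chr11", False),
    ("NPC1", "NM_000271.5", 25, "AR", "D_NPC", "Niemann-Pick disease type C1", "lysosomal", True, ["BM_LYSOSM509"], "chr18", False),
    ("PSAP", "NM_002778.4", 15, "AR", "D_PSAP", "Prosaposin deficiency", "lysosomal", False, ["BM_LYSOGB1"], "chr10", False),
    ("DBT", "NM_001918.5", 11, "AR", "D_MSUD2", "Maple syrup urine disease type II", "amino_acid_peptide", True, [], "chr1", False),
    ("GLB1", "NM_000404.4", 17, "AR", "D_GM1", "GM1 gangliosidosis type I", "lysosomal", False, ["ENZ_BGAL"], "chr3", False),
    ("GALNS", "NM_000512.5", 14, "AR", "D_MPS4A", "Mucopolysaccharidosis type IVA", "lysosomal", True, ["ENZ_GALNS"], "chr16", False),
    ("TPP1", "NM_000391.4", 13, "AR", "D_CLN2", "Neuronal ceroid lipofuscinosis type 2", "lysosomal", True, ["ENZ_TPP1"], "chr11", False),
    ("IDUA", "NM_000203.5", 14, "AR", "D_MPS1", "Mucopolysaccharidosis type I", "lysosomal", True, ["ENZ_IDUA"], "chr4", False),
    ("IDS", "NM_000202.8", 9, "XL", "D_MPS2", "Mucopolysaccharidosis type II", "lysosomal", True, ["ENZ_IDS"], "chrX", False),
    ("ARSB", "NM_000046.5", 8, "AR", "D_MPS6", "Mucopolysaccharidosis type VI", "lysosomal", True, ["ENZ_ARSB"], "chr5", False),
    ("GUSB", "NM_000181.4", 12, "AR", "D_MPS7", "Mucopolysaccharidosis type VII", "lysosomal", False, ["ENZ_GUSB"], "chr7", False),
    ("HGSNAT", "NM_152419.3", 18, "AR", "D_MPS3C", "Mucopolysaccharidosis type IIIC", "lysosomal", False, ["ENZ_HGSNAT"], "chr8", False),
    ("NAGLU", "NM_000263.4", 6, "AR", "D_MPS3B", "Mucopolysaccharidosis type IIIB", "lysosomal", False, ["ENZ_NAGLU"], "chr17", False),
    ("SGSH", "NM_000199.5", 8, "AR", "D_MPS3A", "Mucopolysaccharidosis type IIIA", "lysosomal", False, ["ENZ_SGSH"], "chr17", False),
    ("SLC3A1", "NM_000341.4", 10, "AR", "D_CYSTINURIA", "Cystinuria type A", "amino_acid_peptide", True, [], "chr2", False),
    ("LDLR", "NM_000527.5", 18, "AD", "D_FH", "Familial hypercholesterolemia", "lipid_lipoprotein", True, [], "chr19", False),
    ("AGL", "NM_000642.3", 34, "AR", "D_GSD3", "Glycogen storage disease type III", "carbohydrate", True, [], "chr1", False),
    ("ATP7A", "NM_000052.7", 23, "XL", "D_MENKES", "Menkes disease", "metal_metabolism", True, [], "chrX", False),
    ("CYP21A2", "NM_000500.9", 10, "AR", "D_CAH", "Congenital adrenal hyperplasia (21-hydroxylase)", "steroid", True, ["BM_17OHP"], "chr6", False),
    ("SLC7A7", "NM_001126106.3", 11, "AR", "D_LPI", "Lysinuric protein intolerance", "amino_acid_peptide", True, [], "chr14", False),
    ("ATP7B", "NM_000053.4", 21, "AR", "D_WILSON", "Wilson disease", "metal_metabolism", True, ["BM_CERULO"], "chr13", False),
    ("PAH", "NM_000277.3", 13, "AR", "D_PKU", "Phenylketonuria", "amino_acid_peptide", True, ["BM_PHE"], "chr12", False),
    ("PEX1", "NM_000466.3", 24, "AR", "D_ZSD1", "Zellweger spectrum disorder (PEX1)", "peroxisomal", False, [], "chr7", False),
    ("PEX12", "NM_000286.3", 3, "AR", "D_ZSD12", "Zellweger spectrum disorder (PEX12)", "peroxisomal", False, [], "chr17", False),
    ("GLA", "NM_000169.3", 7, "XL", "D_FABRY", "Fabry disease", "lysosomal", True, ["ENZ_AGAL"], "chrX", True),
    ("GAA", "NM_000152.5", 20, "AR", "D_POMPE", "Pompe disease", "lysosomal", True, ["ENZ_GAA"], "chr17", False),
    ("GALC", "NM_000153.4", 17, "AR", "D_KRABBE", "Krabbe disease", "lysosomal", False, ["ENZ_GALC"], "chr14", False),
    ("ARSA", "NM_000487.6", 8, "AR", "D_MLD", "Metachromatic leukodystrophy", "lysosomal", False, ["ENZ_ARSA"], "chr22", False),
    ("FUCA1", "NM_000147.5", 8, "AR", "D_FUCOSIDOSIS", "Fucosidosis", "lysosomal", False, ["ENZ_FUCA"], "chr1", False),
    ("BTD", "NM_000060.4", 4, "AR", "D_BTD", "Biotinidase deficiency", "vitamin_cofactor", True, ["ENZ_BTD"], "chr3", False),
    ("FAH", "NM_000137.4", 14, "AR", "D_TYR1", "Tyrosinemia type I", "amino_acid_peptide", True, ["BM_SUAC"], "chr15", False),
    ("HGD", "NM_000187.4", 14, "AR", "D_AKU", "Alkaptonuria", "amino_acid_peptide", False, [], "chr3", False),
    ("ABCC2", "NM_000392.5", 32, "AR", "D_DJS", "Dubin-Johnson syndrome", "bile_acid_liver", False, [], "chr10", False),
]

# placeholder counts per category, padding the panel to 206 genes while
# keeping the three largest categories at their documented sizes
# (lysosomal 48, carbohydrate 35, amino acid/peptide 33)
PAD = {
    "lysosomal": 29,
    "carbohydrate": 34,
    "amino_acid_peptide": 27,
    "organic_acid": 12,
    "fatty_acid_oxidation": 10,
    "urea_cycle": 8,
    "mitochondrial_energy": 10,
    "glycosylation": 8,
    "purine_pyrimidine": 6,
    "neurotransmitter": 5,
    "vitamin_cofactor": 6,
    "metal_metabolism": 3,
    "peroxisomal": 5,
    "lipid_lipoprotein": 4,
    "steroid": 2,
    "bile_acid_liver": 2,
    "porphyrin_heme": 1,
}


def build():
    genes = []
    for (sym, tx, ex, inh, did, dname, cat, treat, aids, chrom, fhr) in REAL_GENES:
        genes.append(
            dict(
                symbol=sym, transcript=tx, exon_count=ex, inheritance=inh,
                disease_id=did, disease_name=dname, category=cat,
                treatable=treat, assay_ids=aids, chrom=chrom,
                female_het_reportable=fhr, lof_mechanism=True, placeholder=False,
            )
        )
    i = 0
    for cat, n in PAD.items():
        for _ in range(n):
            i += 1
            inh = "AD" if i % 12 == 0 else ("XL" if i % 17 == 0 else "AR")
            chrom = "chrX" if inh == "XL" else f"chr{(i % 22) + 1}"
            genes.append(
                dict(
                    symbol=f"GPAD{i:03d}", transcript=f"NM_9{i:05d}.1",
                    exon_count=4 + (i % 27), inheritance=inh,
                    disease_id=f"D_GPAD{i:03d}",
                    disease_name=f"Placeholder disorder {i} (synthetic)",
                    category=cat, treatable=(i % 5 < 2), assay_ids=[],
                    chrom=chrom, female_het_reportable=False,
                    lof_mechanism=True, placeholder=True,
                )
            )
    # keep the file compact: drop fields that equal the model defaults
    defaults = dict(treatable=False, assay_ids=[], chrom="chr1",
                    female_het_reportable=False, lof_mechanism=True,
                    placeholder=False)
    genes = [
        {k: v for k, v in g.items() if not (k in defaults and v == defaults[k])}
        for g in genes
    ]
    assays = [
        dict(assay_id=a, kind=k, analyte=an, pathologic_direction=d,
             reference_low=lo, reference_high=hi, units=u)
        for (a, k, an, d, lo, hi, u) in ASSAYS
    ]
    assert len(genes) == 206, len(genes)
    assert len(assays) == 25, len(assays)
    return {"genes": genes, "assays": assays, "thresholds": {}}


if __name__ == "__main__":
    out = Path(__file__).resolve().parent.parent / "src" / "metpanel" / "data" / "default_panel.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(yaml.safe_dump(build(), sort_keys=True))
    print(f"wrote {out}")
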
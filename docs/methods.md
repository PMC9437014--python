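# Methods

This note documents the decision model implemented by `metpanel`, the
assumptions behind it, the tunable parameters and their defaults, what the
synthetic-cohort generator does and does not emulate, and the numerical
conventions.

## The diagnostic decision model

The pipeline models a laboratory workflow in which targeted panel
sequencing (SNV + CNV detection) and biochemical assays (enzyme activities
and biomarkers in dried blood spots) are performed by the same laboratory,
with the biochemical arm triggered *reflexively* by the genetic findings.
One case flows through six stages:

1. **Specimen QC.** A sequencing run passes when ≥ 99.5% of targeted
   regions reach ≥ 20× depth (`qc_min_coverage_fraction`, `qc_min_depth`).
   The gate is monotone in both arguments; failing specimens are flagged
   on the report rather than silently dropped.

2. **SNV triage.** Each annotated variant is tested against five inclusion
   criteria (prior internal curation P/LP/VUS; unclassified; rare with
   high/moderate impact; external disease-causing assertion; both dbscSNV
   splice scores above threshold) and one dominant exclusion (prior
   internal LB/B). Rarity aggregates external and internal healthy-cohort
   frequency by maximum, with *absent* frequencies counting as zero —
   a variant never seen is not penalized for missing annotation. The
   "unclassified" criterion is rarity-gated by default: read literally it
   would retain every novel common variant, which only makes sense when a
   human reviewer absorbs the flood; an automated tool needs a defensible
   gate. The literal reading remains available (`c2_literal`). Splice
   criterion: both ADA and RF must exceed 0.6; an absent score fails —
   prediction-based rescue requires both ensembles to agree.

3. **CNV selection.** Below 2% frequency: homozygous deletions of any
   span; heterozygous deletions and duplications spanning > 2 exons
   (`het_cnv_min_exons = 3`). The span test is a sensitivity guard on
   automated calling, so a call already confirmed by qPCR/MLPA/CMA
   bypasses it — this is what lets a confirmed two-exon deletion
   participate in a compound-heterozygous diagnosis. Retained
   non-homozygous CNVs always carry an orthogonal-confirmation
   requirement; homozygous deletions do not (their signal is unambiguous).
   Copy-neutral calls never pass. Multi-gene CNVs are retained when any
   constituent panel gene passes and are reported once, flagged syndromic,
   as a chromosomal-event diagnosis that skips single-gene biochemistry.

4. **Inheritance matching.** Alleles are counted across variant types
   (hom = 2, het = 1, hemi = 1; 0-copy deletion = 2, 1-copy deletion or
   duplication = 1, capped at 2). AR requires two alleles; two
   heterozygous variants are treated as *potentially* biallelic with
   unknown phase — phase is a downstream question for biochemistry or
   parental testing, not a reason to discard a candidate. AD requires one.
   XL requires a hemizygous male, a homozygous/biallelic female, or a
   heterozygous female in diseases flagged `female_het_reportable`
   (e.g. Fabry). A hemizygous call in a female raises a data-inconsistency
   error rather than guessing. A heterozygous SNV appearing hemizygous
   inside a heterozygous deletion is handled naturally by the combined
   count (the GM1-gangliosidosis pattern).

5. **Reflex biochemistry.** Eligible genotypes in genes with linked assays
   produce orders (deduplicated across diseases sharing an analyte).
   Measured values are called against the reference interval on the
   pathologic side only: with grey-zone fraction *g* (default 0.10),
   values beyond the bound by more than *g*·bound are pathologic, inside
   the interval by more than *g*·bound are normal, between (including the
   bound itself) borderline. Enzyme deficiencies are always `below_range`;
   biomarkers may accumulate or deplete. Single heterozygous AR findings
   (carriers) do not trigger reflex by default (`reflex_on_carrier`).

6. **Classification and reporting.** The five-tier base classification
   uses a small transparent rule subset (see the table in
   `classify_report`'s module docstring): curated assertions are honored,
   novel truncating variants in loss-of-function-mechanism genes are LP,
   novel rare missense are VUS, and splice-prediction-only candidates are
   VUS with a `computational_only` tag. Biochemical evidence then acts at
   strong functional weight, bounded to one class level per step:

   - pathologic → VUS upgrades to LP, unless the variant already carries
     contradictory evidence (it stays VUS);
   - normal → computational-only candidates become non-reportable;
     curated P/LP stay reported but flagged conflicting (a curated
     assertion is never silently dropped by one assay);
   - normal *enzyme activity* with a compound-het pair → the pair is
     inferred to be in cis and excluded: two trans loss-of-function
     alleles cannot coexist with normal enzyme activity. A normal
     *biomarker* does not support cis inference — downstream metabolite
     levels can normalize for reasons a direct enzyme measurement cannot —
     so a compound-het VUS pair with a normal biomarker stays reported as
     unclear with parental-testing and biomarker-follow-up
     recommendations;
   - borderline → no class change; follow-up recommendation.

   Report status comes from a total decision table over (best reportable
   class × biochemistry call × genotype eligibility): P/LP with an
   eligible genotype is positive unless contradicted by a normal result
   (then unclear); VUS is unclear whatever the assay says (a pathologic
   assay alone cannot promote a case to positive when the genetics stay
   uncertain and contradicted); anything else is negative. Two structural
   zeros follow: a pathologic result never coexists with a negative
   report (pathologic results only arise after an eligible candidate
   genotype), and a normal result never coexists with a positive report.

## Tunable parameters

| parameter | default | units/meaning |
|---|---|---|
| `maf_snv` | 0.01 | SNV rarity gate (fraction) |
| `maf_cnv` | 0.02 | CNV rarity gate (fraction) |
| `splice_score_min` | 0.6 | dbscSNV ADA/RF threshold |
| `het_cnv_min_exons` | 3 | minimum exon span, het CNVs (">2 exons") |
| `qc_min_coverage_fraction` | 0.995 | coverage at minimum depth |
| `qc_min_depth` | 20 | read depth floor (×) |
| `healthy_cohort_size` | 24000 | internal frequency reference (metadata) |
| `grey_zone` | 0.10 | borderline band around the pathologic bound |
| `c2_literal` | false | ungated "unclassified" criterion |
| `reflex_on_carrier` | false | reflex for single-het AR findings |

## The packaged panel

The shipped configuration contains 206 gene-disease entries across 18
metabolic categories and 25 assays. The 34 non-placeholder genes are those
the package's documentation and tests discuss (lysosomal storage disorders
dominating, plus aminoacidopathies, metal, peroxisomal, steroid and other
categories); the remainder are clearly marked placeholders (`placeholder:
true`, `GPADnnn` symbols) that pad the panel to its documented size — no
test depends on placeholder biology. Assay reference intervals are
synthetic round numbers chosen so that pathologic, borderline and normal
zones are well separated; curating real intervals is out of scope. A JSON
schema for the config dialect ships at
`src/metpanel/data/panel_schema.json`.

## The synthetic cohort

The generator emulates the *structure* of a global referral cohort:

- region mix Africa 0.33 / Asia 0.30 / Europe 0.24 / Latin America 0.06 /
  Middle East 0.06 / North America 0.01;
- consanguinity reported for half of cases, positive in 30.4% of those;
  family history positive 19.6%, negative 3.6%, otherwise unknown;
- symptom onset log-normal with mean ≈ 1 year; onset-to-diagnosis gap
  log-normal with mean ≈ 2 years, truncated at 20 (shapes config-exposed:
  the emulated summaries state means and ranges, not distributions);
  onset known for ~10% of cases;
- a diagnosable fraction (`true_positive_rate`, default 0.37) drawn from a
  disease spectrum peaking at Gaucher disease, Niemann-Pick A/B, MPS I,
  PKU and Wilson disease; genotypes are mode-consistent (AR homozygous
  more likely under consanguinity, otherwise compound het; AD het;
  XL male hemizygous);
- causal alleles are SNVs with probability 0.94, otherwise CNVs (85%
  deletions); causal variants carry annotations that pass triage (curated
  P/LP with probability 0.70, otherwise novel LoF or externally asserted);
  with probability `vus_rate` (0.10) a causal variant is VUS-grade —
  drawn only in assay-linked diseases, where biochemistry can resolve it;
- an `unclear_rate` slice (0.15) carries biallelic VUS in AR genes
  *without* assays, surfacing as unresolvable unclear reports (so that
  "variant reported" exceeds "diagnosed", as in real cohorts);
- remaining cases carry only common/benign background variants, 10% with
  a single carrier allele;
- assay values are drawn pathologic with probability `assay_sensitivity`
  for truly deficient patients and normal with probability
  `assay_specificity` otherwise (defaults 0.95/0.95), in zones well clear
  of the grey band.

What it does **not** emulate: sequencing reads or coverage profiles, real
allele frequencies or linkage, phenotype-genotype correlation (HPO terms
are decorative draws), region-specific disease spectra or yields, assay
analytics, and parental segregation data. Consequently, passing tests
demonstrate the correctness and calibration of the *decision layer* under
controlled conditions — not the performance of any upstream caller or
assay on real specimens.

## Numerical conventions and edge cases

- Printed percentages use **half-up** rounding at the stated precision
  (`cohort_stats.percent`), which reproduces paired count/percent
  summaries exactly; banker's rounding would not.
- VCF coordinates are 1-based inclusive; CNV exon indices are 1-based
  inclusive on the panel transcript ("exons 8–10" spans three exons).
- Absent annotations are represented as absent, never coerced to zero;
  the rarity gate's absent→0 convention is applied at evaluation time.
- Multi-allelic VCF sites decompose to one record per ALT allele;
  duplicate variant records are deduplicated on
  (chrom, pos, ref, alt, zygosity) before triage.
- Floats written to fixture files carry 6 significant digits; the
  generator clips its draws to the same precision so that in-memory and
  round-tripped cohorts compare equal, and htslib's float32 INFO storage
  is reversed on read by re-rounding.
- A value exactly at a reference bound is borderline by construction.
- Ties in report ordering break by class rank, then allele count, then
  gene symbol and variant key, making reports byte-stable.

## Known limitations

- The ACMG rule subset is deliberately small; it reproduces the
  documented decision behavior but is not a general-purpose classifier
  (no segregation, de novo, or hotspot evidence).
- Phenotype overlap is recorded (HPO terms) but not scored; "explaining
  the phenotype" is approximated by a gene-disease match of an eligible
  genotype.
- Mitochondrial and Y-linked inheritance are not modeled; the readers
  accept such records but the matcher handles AR/AD/XL only.
- X-linked sub-modes are collapsed into the per-disease
  `female_het_reportable` flag rather than an XLR/XLD distinction.
- The cis-inference rule trusts a single normal enzyme measurement;
  a laboratory would usually confirm by parental testing (recorded as a
  recommendation, never computed).
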
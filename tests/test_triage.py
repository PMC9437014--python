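"""Filter-cascade unit and property tests.

The random-oracle equivalence check (10,000 records against a single-
expression re-statement of the cascade) lives in the acceptance suite;
here are the worked examples, the dominance/monotonicity properties and
case-level composition.
"""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from metpanel.panel_registry import ThresholdConfig
from metpanel.triage import evaluate_cnv, evaluate_snv, triage_case
from metpanel.variant_io import AnnotatedSNV, CNVCall

T = ThresholdConfig()


def _snv(**kw):
    base = dict(chrom="chr1", pos=1, ref="A", alt="T", gene="GBA",
                zygosity="het")
    base.update(kw)
    return AnnotatedSNV(**base)


class TestSNVCascade:
    def test_prior_pathogenic_retained_c1(self):
        d = evaluate_snv(_snv(prior_internal_class="P", maf_external=0.003), T)
        assert d.retained and d.criteria_hit == ["C1_prior_PLP_VUS"]

    def test_rare_high_impact_retained_c3(self):
        d = evaluate_snv(_snv(maf_external=0.005, impact="high"), T)
        assert d.retained and "C3_rare_high_moderate" in d.criteria_hit

    def test_unclassified_rare_hits_c2_and_c3(self):
        d = evaluate_snv(_snv(prior_internal_class="unclassified",
                              maf_external=0.005, impact="high"), T)
        assert set(d.criteria_hit) >= {"C2_unclassified", "C3_rare_high_moderate"}

    def test_unclassified_common_needs_literal_switch(self):
        v = _snv(prior_internal_class="unclassified", maf_external=0.05,
                 impact="low")
        assert not evaluate_snv(v, T).retained
        literal = ThresholdConfig(c2_literal=True)
        assert evaluate_snv(v, literal).criteria_hit == ["C2_unclassified"]

    def test_common_low_impact_discarded(self):
        d = evaluate_snv(_snv(maf_external=0.05, impact="low",
                              ada_score=0.3, rf_score=0.2), T)
        assert not d.retained and d.criteria_hit == []

    def test_benign_prior_dominates_external_assertion(self):
        d = evaluate_snv(_snv(prior_internal_class="LB",
                              external_assertion="disease_causing"), T)
        assert not d.retained and d.excluded_by == "prior_benign"

    def test_splice_scores_retain_common_synonymous(self):
        d = evaluate_snv(_snv(ada_score=0.7, rf_score=0.61,
                              maf_external=0.009, impact="low"), T)
        assert d.retained and d.criteria_hit == ["C5_splice_scores"]

    def test_single_splice_score_insufficient(self):
        assert not evaluate_snv(_snv(ada_score=0.9, impact="low",
                                     maf_external=0.05), T).retained

    def test_internal_frequency_counts_in_rarity_gate(self):
        d = evaluate_snv(_snv(maf_external=0.001, maf_internal=0.05,
                              impact="high"), T)
        assert not d.retained

    def test_low_quality_retained_variant_needs_sanger(self):
        d = evaluate_snv(_snv(prior_internal_class="P", quality_ok=False), T)
        assert d.retained and d.confirmation == "sanger"

    def test_retained_implies_criteria_and_no_exclusion(self):
        d = evaluate_snv(_snv(prior_internal_class="VUS"), T)
        assert d.retained and d.criteria_hit and d.excluded_by == "none"


benign_free_snvs = st.builds(
    _snv,
    prior_internal_class=st.sampled_from(["P", "LP", "VUS", "unclassified",
                                          "absent"]),
    impact=st.sampled_from(["high", "moderate", "low", "modifier"]),
    maf_external=st.one_of(st.none(), st.floats(0, 0.2)),
    maf_internal=st.one_of(st.none(), st.floats(0, 0.2)),
    external_assertion=st.sampled_from(["disease_causing", "benign_assertion",
                                        "none"]),
    ada_score=st.one_of(st.none(), st.floats(0, 1)),
    rf_score=st.one_of(st.none(), st.floats(0, 1)),
)


@given(v=benign_free_snvs, delta=st.floats(0, 0.2))
def test_lowering_maf_never_discards(v, delta):
    before = evaluate_snv(v, T).retained
    rarer = v.model_copy(update={
        "maf_external": max(0.0, (v.maf_external or 0.0) - delta)})
    assert not (before and not evaluate_snv(rarer, T).retained)


@given(v=benign_free_snvs, delta=st.floats(0, 1))
def test_raising_splice_scores_never_discards(v, delta):
    before = evaluate_snv(v, T).retained
    up = v.model_copy(update={
        "ada_score": min(1.0, (v.ada_score or 0.0) + delta),
        "rf_score": min(1.0, (v.rf_score or 0.0) + delta)})
    assert not (before and not evaluate_snv(up, T).retained)


@given(v=benign_free_snvs, benign=st.sampled_from(["LB", "B"]))
def test_benign_exclusion_dominates(v, benign):
    d = evaluate_snv(v.model_copy(update={"prior_internal_class": benign}), T)
    assert not d.retained and d.excluded_by == "prior_benign"


def _cnv(cn, start, end, maf=None, confirmed="none"):
    return CNVCall(genes=["GBA"], copy_number=cn, exon_start=start,
                   exon_end=end, maf=maf, confirmed_by=confirmed)


class TestCNVSelection:
    def test_het_deletion_three_exons_retained_with_confirmation(self):
        d = evaluate_cnv(_cnv(1, 8, 10), t=T)
        assert d.retained and d.confirmation == "orthogonal_cnv"

    def test_het_deletion_two_exons_discarded(self):
        assert not evaluate_cnv(_cnv(1, 2, 3), t=T).retained

    def test_confirmed_two_exon_deletion_bypasses_span_guard(self):
        d = evaluate_cnv(_cnv(1, 2, 3, confirmed="MLPA"), t=T)
        assert d.retained and d.confirmation == "orthogonal_cnv"

    def test_hom_deletion_single_exon_no_confirmation(self):
        d = evaluate_cnv(_cnv(0, 4, 4, maf=0.001), t=T)
        assert d.retained and d.confirmation == "none"
        assert d.criteria_hit == ["CNV_hom_del"]

    def test_duplication_above_maf_discarded(self):
        assert not evaluate_cnv(_cnv(3, 1, 5, maf=0.03), t=T).retained

    def test_copy_neutral_never_retained(self):
        assert not evaluate_cnv(_cnv(2, 1, 20), t=T).retained


class TestCaseComposition:
    def test_off_panel_variant_dropped(self, panel):
        out = triage_case([_snv(gene="NOTAGENE", prior_internal_class="P")],
                          [], panel)
        assert out == {}

    def test_gaucher_compound_grouped_under_gene(self, panel):
        out = triage_case(
            [_snv(gene="GBA", prior_internal_class="P")],
            [CNVCall(genes=["GBA"], copy_number=1, exon_start=8, exon_end=10)],
            panel)
        assert set(out) == {"GBA"}
        assert len(out["GBA"].snvs) == 1 and len(out["GBA"].cnvs) == 1

    def test_duplicate_variants_deduplicated(self, panel):
        v = _snv(gene="GBA", prior_internal_class="P")
        out = triage_case([v, v.model_copy()], [], panel)
        assert len(out["GBA"].snvs) == 1

    def test_multigene_cnv_flagged_syndromic(self, panel):
        genes = ["GBA", "SMPD1"] + [f"OFFP{i}" for i in range(38)]
        out = triage_case([], [CNVCall(genes=genes, copy_number=1,
                                       exon_start=1, exon_end=5)], panel)
        assert out["GBA"].syndromic and out["SMPD1"].syndromic
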
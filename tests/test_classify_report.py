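import itertools

import pytest

from metpanel.classify_report import (
    ClassificationState,
    GeneFindingGroup,
    ReportRecord,
    apply_biochem,
    assign_report,
    base_classify,
    biochem_crosstab,
    decide_status,
    infer_phase,
)
from metpanel.inheritance_reflex import BiochemResult, ReflexEligibility
from metpanel.panel_registry import ThresholdConfig
from metpanel.variant_io import AnnotatedSNV, CNVCall

T = ThresholdConfig()


def _snv(**kw):
    base = dict(chrom="chr1", pos=1, ref="A", alt="T", gene="GBA",
                zygosity="het")
    base.update(kw)
    return AnnotatedSNV(**base)


def _result(assay_id, call, value=1.0):
    return BiochemResult(assay_id=assay_id, value=value, units="u", call=call)


class TestBaseClassify:
    @pytest.mark.parametrize(
        "fields,expected_class,expected_tag",
        [
            (dict(prior_internal_class="P"), "P", "curated_internal"),
            (dict(prior_internal_class="LP"), "LP", "curated_internal"),
            (dict(prior_internal_class="VUS"), "VUS", "curated_internal"),
            (dict(external_assertion="disease_causing"), "LP",
             "curated_external"),
            (dict(impact="high", maf_external=0.0001), "LP", "novel_lof"),
            (dict(impact="moderate", maf_external=0.0001), "VUS",
             "novel_missense"),
            (dict(impact="modifier", ada_score=0.9, rf_score=0.8), "VUS",
             "computational_only"),
        ],
    )
    def test_rule_table(self, panel, fields, expected_class, expected_tag):
        gene = next(g for g in panel.genes if g.symbol == "GBA")
        state = base_classify(_snv(**fields), gene, T)
        assert state.base_class == expected_class
        assert expected_tag in state.evidence
        assert state.final_class == state.base_class

    def test_cnv_deletion_is_lp(self, panel):
        gene = next(g for g in panel.genes if g.symbol == "DBT")
        cnv = CNVCall(genes=["DBT"], copy_number=1, exon_start=2, exon_end=3)
        assert base_classify(cnv, gene, T).final_class == "LP"

    def test_cnv_duplication_is_vus(self, panel):
        gene = next(g for g in panel.genes if g.symbol == "IDS")
        cnv = CNVCall(genes=["IDS"], copy_number=3, exon_start=1, exon_end=5)
        assert base_classify(cnv, gene, T).final_class == "VUS"

    def test_prior_vus_with_benign_assertion_conflicts(self, panel):
        gene = next(g for g in panel.genes if g.symbol == "GBA")
        state = base_classify(
            _snv(prior_internal_class="VUS",
                 external_assertion="benign_assertion"), gene, T)
        assert "conflicting_evidence" in state.evidence


class TestApplyBiochem:
    def _gene(self, panel, symbol="GBA"):
        return next(g for g in panel.genes if g.symbol == symbol)

    def test_pathologic_upgrades_vus_to_lp(self, panel):
        gene = self._gene(panel)
        state = base_classify(_snv(impact="moderate", maf_external=0.0), gene, T)
        out = apply_biochem(state, [_result("ENZ_GBA", "pathologic")], gene,
                            panel)
        assert out.final_class == "LP"
        assert "functional_pathologic" in out.evidence

    def test_conflicting_vus_stays_vus_despite_pathologic(self, panel):
        gene = self._gene(panel)
        state = base_classify(
            _snv(prior_internal_class="VUS",
                 external_assertion="benign_assertion"), gene, T)
        out = apply_biochem(state, [_result("ENZ_GBA", "pathologic")], gene,
                            panel)
        assert out.final_class == "VUS"

    def test_normal_excludes_computational_candidate(self, panel):
        gene = self._gene(panel, "GALNS")
        state = base_classify(_snv(gene="GALNS", impact="modifier",
                                   ada_score=0.9, rf_score=0.8), gene, T)
        out = apply_biochem(state, [_result("ENZ_GALNS", "normal")], gene,
                            panel)
        assert not out.reportable

    def test_normal_flags_curated_but_keeps_reported(self, panel):
        gene = self._gene(panel)
        state = base_classify(_snv(prior_internal_class="P"), gene, T)
        out = apply_biochem(state, [_result("ENZ_GBA", "normal")], gene, panel)
        assert out.reportable
        assert "conflicting_evidence" in out.evidence
        assert out.final_class == "P"

    def test_borderline_changes_nothing(self, panel):
        gene = self._gene(panel)
        state = base_classify(_snv(impact="moderate", maf_external=0.0), gene, T)
        out = apply_biochem(state, [_result("ENZ_GBA", "borderline")], gene,
                            panel)
        assert out.final_class == "VUS" and out.reportable

    def test_assay_gene_mismatch_rejected(self, panel):
        gene = self._gene(panel)
        state = base_classify(_snv(prior_internal_class="P"), gene, T)
        with pytest.raises(ValueError, match="not linked"):
            apply_biochem(state, [_result("ENZ_TPP1", "normal")], gene, panel)

    def test_moves_bounded_to_one_level(self, panel):
        """Biochemistry never drives P->B or B->P in a single step."""
        gene = self._gene(panel)
        rank = {"P": 4, "LP": 3, "VUS": 2, "LB": 1, "B": 0}
        for prior, call in itertools.product(
                ["P", "LP", "VUS"], ["pathologic", "normal", "borderline"]):
            state = base_classify(_snv(prior_internal_class=prior), gene, T)
            out = apply_biochem(state, [_result("ENZ_GBA", call)], gene, panel)
            assert abs(rank[out.final_class] - rank[state.base_class]) <= 1


class TestInferPhase:
    def _states(self, panel):
        gene = next(g for g in panel.genes if g.symbol == "TPP1")
        return [base_classify(_snv(gene="TPP1", pos=i, impact="moderate",
                                   maf_external=0.0), gene, T)
                for i in (340, 1033)]

    def test_normal_enzyme_implies_cis(self, panel):
        assert infer_phase(self._states(panel),
                           [_result("ENZ_TPP1", "normal")], panel) == "cis"

    def test_pathologic_supports_trans(self, panel):
        assert infer_phase(self._states(panel),
                           [_result("ENZ_TPP1", "pathologic")],
                           panel) == "trans_supported"

    def test_normal_biomarker_stays_unknown(self, panel):
        assert infer_phase(self._states(panel),
                           [_result("BM_LYSOGB1", "normal")], panel) == "unknown"

    def test_no_assay_unknown(self, panel):
        assert infer_phase(self._states(panel), [], panel) == "unknown"


def test_decision_table_total_and_unique():
    """Every (class, biochem, eligibility) combination maps to one status."""
    classes = [None, "P", "LP", "VUS", "LB", "B"]
    calls = ["pathologic", "normal", "borderline", "absent"]
    for cls, call, eligible in itertools.product(classes, calls,
                                                 [True, False]):
        status = decide_status(cls, call, eligible)
        assert status in ("positive", "unclear", "negative")
        if call == "normal":
            assert status != "positive"
        if call == "pathologic" and eligible and cls in ("P", "LP", "VUS"):
            assert status != "negative"


def _group(panel, symbol, states, eligible=True, pattern="hom", biochem=(),
           phase="unknown", syndromic=False):
    gene = next(g for g in panel.genes if g.symbol == symbol)
    return GeneFindingGroup(
        gene=gene,
        eligibility=ReflexEligibility(gene=symbol, disease_id=gene.disease_id,
                                      eligible=eligible,
                                      genotype_pattern=pattern,
                                      allele_count=2 if eligible else 1),
        states=states, biochem=list(biochem), phase=phase,
        syndromic=syndromic)


class TestAssignReport:
    def test_no_groups_negative(self):
        rep = assign_report("C0", [])
        assert rep.status == "negative" and rep.findings == []

    def test_carrier_genotype_excluded(self, panel):
        gene = next(g for g in panel.genes if g.symbol == "GBA")
        state = base_classify(_snv(prior_internal_class="P"), gene, T)
        rep = assign_report("C1", [_group(panel, "GBA", [state],
                                          eligible=False,
                                          pattern="het_single")])
        assert rep.status == "negative"
        assert rep.findings == []
        (exc,) = rep.excluded
        assert "genotype_insufficient" in exc["evidence"]

    def test_syndromic_cnv_positive(self, panel):
        gene = next(g for g in panel.genes if g.symbol == "GBA")
        cnv = CNVCall(genes=["GBA", "SMPD1"], copy_number=1, exon_start=1,
                      exon_end=5)
        state = base_classify(cnv, gene, T)
        rep = assign_report("C2", [_group(panel, "GBA", [state],
                                          syndromic=True)])
        assert rep.status == "positive" and rep.syndromic_flag

    def test_findings_ordered_class_then_gene(self, panel):
        g_vus = _group(panel, "TPP1",
                       [base_classify(_snv(gene="TPP1", impact="moderate",
                                           maf_external=0.0),
                                      next(g for g in panel.genes
                                           if g.symbol == "TPP1"), T)])
        g_p = _group(panel, "GBA",
                     [base_classify(_snv(prior_internal_class="P"),
                                    next(g for g in panel.genes
                                         if g.symbol == "GBA"), T)])
        rep = assign_report("C3", [g_vus, g_p])
        assert [f["final_class"] for f in rep.findings] == ["P", "VUS"]
        assert rep.status == "positive"


class TestCrosstab:
    def _report(self, status, biochem):
        return ReportRecord(case_id="x", status=status,
                            biochem_summary=biochem)

    def test_structural_zeros_on_scenario_fixture(self):
        reports = [
            self._report("positive", {"E": "pathologic"}),
            self._report("unclear", {"E": "pathologic"}),
            self._report("negative", {"E": "normal"}),
            self._report("unclear", {"E": "normal"}),
            self._report("negative", {}),            # not counted
            self._report("positive", {"E": "borderline"}),  # not counted
        ]
        tab = biochem_crosstab(reports)
        assert tab.loc["pathologic", "negative"] == 0
        assert tab.loc["normal", "positive"] == 0
        assert tab.loc["pathologic", "positive"] == 1
        assert tab.loc["normal", "negative"] == 1
        assert int(tab.to_numpy().sum()) == 4

    def test_empty_input_all_zero(self):
        assert int(biochem_crosstab([]).to_numpy().sum()) == 0
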
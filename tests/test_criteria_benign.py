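"""The eight automated benign codes, plus the cross-code exclusivity
properties (BA1/BS1, BA1/PM2, PP3/BP4)."""

import pytest
from hypothesis import given, settings, strategies as st
from intervaltree import Interval, IntervalTree

from acmgrules import (
    AcmgCode,
    EngineConfig,
    GeneDisease,
    InheritanceMode,
    InSilicoScores,
    PopulationFrequencies,
    ReferenceBundle,
    StrengthLevel,
)
from acmgrules.core_model import ClinVarEntry
from acmgrules.criteria_benign import (
    evaluate_ba1_bs1,
    evaluate_bp1,
    evaluate_bp3,
    evaluate_bp4,
    evaluate_bp6,
    evaluate_bp7,
    evaluate_bs2,
)
from acmgrules.criteria_pathogenic import evaluate_pm2, insilico_consensus

CFG = EngineConfig()


def _bundle(**kw) -> ReferenceBundle:
    b = ReferenceBundle()
    for key, value in kw.items():
        setattr(b, key, value)
    return b


class TestBa1Bs1:
    def _eval(self, make_variant, af, loeuf=0.8):
        bundle = _bundle(gene_constraint={"G": (loeuf, None)})
        v = make_variant(gene="G", freq=PopulationFrequencies(gnomad_af=af))
        return evaluate_ba1_bs1(v, bundle, CFG)

    def test_very_common_variant_is_ba1_stand_alone(self, make_variant):
        (call,) = self._eval(make_variant, 0.1)  # bin 2 BA1 cutoff 2e-2
        assert call.code is AcmgCode.BA1
        assert call.strength is StrengthLevel.STAND_ALONE

    def test_standard_band_is_bs1_strong(self, make_variant):
        (call,) = self._eval(make_variant, 1.5e-2)
        assert call.code is AcmgCode.BS1
        assert call.strength is StrengthLevel.STRONG

    def test_supporting_band_is_bs1_supporting(self, make_variant):
        (call,) = self._eval(make_variant, 5e-3)
        assert call.code is AcmgCode.BS1
        assert call.strength is StrengthLevel.SUPPORTING

    def test_absent_frequencies_give_nothing(self, make_variant, empty_bundle):
        v = make_variant(gene="G")
        assert evaluate_ba1_bs1(v, empty_bundle, CFG) == []

    @given(af=st.floats(min_value=0.0, max_value=1.0,
                        allow_nan=False, allow_infinity=False),
           loeuf=st.one_of(st.none(), st.floats(min_value=0.01, max_value=3.0)))
    @settings(max_examples=300, deadline=None)
    def test_ba1_and_bs1_mutually_exclusive_and_ba1_excludes_pm2(self, af, loeuf):
        bundle = _bundle(gene_constraint={"G": (loeuf, None)})
        from acmgrules import AnnotatedVariant
        v = AnnotatedVariant(chrom="1", pos=10, ref="A", alt="T", gene="G",
                             freq=PopulationFrequencies(gnomad_af=af))
        calls = evaluate_ba1_bs1(v, bundle, CFG)
        codes = {c.code for c in calls}
        assert not ({AcmgCode.BA1, AcmgCode.BS1} <= codes)
        pm2 = evaluate_pm2(v, bundle, CFG)
        if AcmgCode.BA1 in codes or AcmgCode.BS1 in codes:
            assert pm2 is None


class TestBs2:
    def _variant(self, make_variant, mode, **freq_kw):
        return make_variant(
            gene="G",
            gene_disease=(GeneDisease("d", InheritanceMode(mode)),),
            freq=PopulationFrequencies(**freq_kw),
        )

    def test_recessive_at_twice_threshold_strong(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.8, None)})
        v = self._variant(make_variant, "AR", gnomad_hom_count=4)
        assert evaluate_bs2(v, bundle, CFG).strength is StrengthLevel.STRONG

    def test_recessive_between_thresholds_moderate(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.8, None)})
        v = self._variant(make_variant, "AR", gnomad_hom_count=3)
        assert evaluate_bs2(v, bundle, CFG).strength is StrengthLevel.MODERATE

    def test_dominant_requires_constrained_gene(self, make_variant):
        v = self._variant(make_variant, "AD", gnomad_af=1e-4, gnomad_ac=10,
                          gnomad_controls_ac=8, thousand_genomes_ac=6)
        constrained = _bundle(gene_constraint={"G": (0.3, None)})
        tolerant = _bundle(gene_constraint={"G": (0.7, None)})
        assert evaluate_bs2(v, constrained, CFG).strength is StrengthLevel.STRONG
        assert evaluate_bs2(v, tolerant, CFG) is None

    def test_dominant_low_allele_count_excluded(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.3, None)})
        v = self._variant(make_variant, "AD", gnomad_af=1e-4, gnomad_ac=10,
                          gnomad_controls_ac=2, thousand_genomes_ac=6)
        assert evaluate_bs2(v, bundle, CFG) is None

    def test_x_linked_hemizygous_males_strong(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.8, None)})
        v = self._variant(make_variant, "XL", hemizygous_male_count=5)
        assert evaluate_bs2(v, bundle, CFG).strength is StrengthLevel.STRONG

    def test_no_inheritance_records_not_applied(self, make_variant, empty_bundle):
        v = make_variant(gene="G", freq=PopulationFrequencies(gnomad_hom_count=10))
        assert evaluate_bs2(v, empty_bundle, CFG) is None


class TestBp1:
    def test_missense_in_truncating_mechanism_gene(self, make_variant):
        bundle = _bundle(bp1_genes=frozenset({"G"}))
        v = make_variant(gene="G", consequences=frozenset({"missense variant"}))
        assert evaluate_bp1(v, bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_truncating_variant_not_applied(self, make_variant):
        bundle = _bundle(bp1_genes=frozenset({"G"}))
        v = make_variant(gene="G", consequences=frozenset({"stop gained"}))
        assert evaluate_bp1(v, bundle, CFG) is None

    def test_unlisted_gene_not_applied(self, make_variant, empty_bundle):
        v = make_variant(gene="G", consequences=frozenset({"missense variant"}))
        assert evaluate_bp1(v, empty_bundle, CFG) is None


class TestBp3:
    REPEAT = {"1": IntervalTree([Interval(0, 5000)])}

    def test_short_inframe_deletion_in_repeat_strong(self, make_variant):
        bundle = _bundle(repeat_coding=self.REPEAT)
        v = make_variant(ref="A" + "CGT" * 3, alt="A",
                         consequences=frozenset({"inframe deletion"}))
        call = evaluate_bp3(v, bundle, CFG)
        assert call.strength is StrengthLevel.STRONG
        assert any(k == "repeat_intervals" for k, _ in call.details)

    def test_longer_inframe_insertion_supporting(self, make_variant):
        bundle = _bundle(repeat_coding=self.REPEAT)
        v = make_variant(ref="A", alt="A" + "CGT" * 7,  # 21 nt
                         consequences=frozenset({"inframe insertion"}))
        assert evaluate_bp3(v, bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_outside_repeat_not_applied(self, make_variant, empty_bundle):
        v = make_variant(ref="A" + "CGT" * 3, alt="A",
                         consequences=frozenset({"inframe deletion"}))
        assert evaluate_bp3(v, empty_bundle, CFG) is None

    def test_frameshift_length_not_applied(self, make_variant):
        bundle = _bundle(repeat_coding=self.REPEAT)
        v = make_variant(ref="ACGTA", alt="A",  # 4 nt, out of frame
                         consequences=frozenset({"inframe deletion"}))
        assert evaluate_bp3(v, bundle, CFG) is None

    def test_very_long_repeat_indel_not_scored(self, make_variant):
        bundle = _bundle(repeat_coding=self.REPEAT)
        v = make_variant(ref="A" + "CGT" * 20, alt="A",  # 60 nt
                         consequences=frozenset({"inframe deletion"}))
        assert evaluate_bp3(v, bundle, CFG) is None


class TestBp4:
    def test_two_benign_tools_tied_upweight(self, make_variant, empty_bundle):
        v = make_variant(scores=InSilicoScores(revel=0.1, dann=0.05))  # both moderate
        assert evaluate_bp4(v, empty_bundle, CFG).strength is StrengthLevel.STRONG

    def test_single_supporting_tool_not_enough(self, make_variant, empty_bundle):
        v = make_variant(scores=InSilicoScores(revel=0.25))
        assert evaluate_bp4(v, empty_bundle, CFG) is None

    def test_strong_pathogenic_signal_disqualifies(self, make_variant, empty_bundle):
        v = make_variant(scores=InSilicoScores(revel=0.95, dann=0.05))
        assert evaluate_bp4(v, empty_bundle, CFG) is None

    @given(
        revel=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        dann=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
        phylop=st.one_of(st.none(), st.floats(-10, 12, allow_nan=False)),
        gerp=st.one_of(st.none(), st.floats(-12, 7, allow_nan=False)),
        absplice=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    )
    @settings(max_examples=400, deadline=None)
    def test_pp3_and_bp4_never_co_fire(self, revel, dann, phylop, gerp, absplice):
        from acmgrules import AnnotatedVariant
        v = AnnotatedVariant(
            chrom="1", pos=10, ref="A", alt="T",
            scores=InSilicoScores(revel=revel, dann=dann, phylop=phylop,
                                  gerp=gerp, absplice=absplice),
        )
        pp3, bp4 = insilico_consensus(v, CFG)
        assert pp3 is None or bp4 is None


class TestBp6:
    def test_practice_guidelines_stand_alone(self, make_variant, empty_bundle):
        v = make_variant(clinvar_top=ClinVarEntry("B", "practice guidelines", "1"))
        assert evaluate_bp6(v, empty_bundle, CFG).strength is StrengthLevel.STAND_ALONE

    def test_multiple_submitters_strong(self, make_variant, empty_bundle):
        v = make_variant(clinvar_top=ClinVarEntry(
            "LB", "criteria provided, multiple submitters, no conflicts", "2"))
        assert evaluate_bp6(v, empty_bundle, CFG).strength is StrengthLevel.STRONG

    def test_pathogenic_assertion_not_applied(self, make_variant, empty_bundle):
        v = make_variant(clinvar_top=ClinVarEntry("P", "practice guidelines", "3"))
        assert evaluate_bp6(v, empty_bundle, CFG) is None


class TestBp7:
    def _variant(self, make_variant, phylop, absplice, consequence="synonymous variant"):
        return make_variant(consequences=frozenset({consequence}),
                            scores=InSilicoScores(phylop=phylop, absplice=absplice))

    def test_low_conservation_no_splice_impact_supporting(self, make_variant, empty_bundle):
        v = self._variant(make_variant, phylop=3.0, absplice=0.04)
        assert evaluate_bp7(v, empty_bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_exceptionally_low_scores_strong(self, make_variant, empty_bundle):
        v = self._variant(make_variant, phylop=0.1, absplice=0.005,
                          consequence="intron variant")
        assert evaluate_bp7(v, empty_bundle, CFG).strength is StrengthLevel.STRONG

    def test_conserved_position_not_applied(self, make_variant, empty_bundle):
        v = self._variant(make_variant, phylop=8.0, absplice=0.01)
        assert evaluate_bp7(v, empty_bundle, CFG) is None

    def test_coding_missense_not_eligible(self, make_variant, empty_bundle):
        v = self._variant(make_variant, phylop=0.1, absplice=0.005,
                          consequence="missense variant")
        assert evaluate_bp7(v, empty_bundle, CFG) is None

    def test_missing_scores_not_applied(self, make_variant, empty_bundle):
        v = self._variant(make_variant, phylop=None, absplice=0.005)
        assert evaluate_bp7(v, empty_bundle, CFG) is None

    @given(phylop=st.floats(-5, 10, allow_nan=False),
           absplice=st.floats(0, 1, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_strong_region_is_subset_of_eligibility(self, phylop, absplice):
        from acmgrules import AnnotatedVariant
        v = AnnotatedVariant(chrom="1", pos=10, ref="A", alt="T",
                             consequences=frozenset({"synonymous variant"}),
                             scores=InSilicoScores(phylop=phylop, absplice=absplice))
        call = evaluate_bp7(v, ReferenceBundle(), CFG)
        if call is not None and call.strength is StrengthLevel.STRONG:
            assert phylop < CFG.bp7_phylop_eligible
            assert absplice < CFG.bp7_absplice_eligible
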
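"""The ten automated pathogenic codes, exercised at their decision
boundaries against purpose-built reference bundles."""

import pytest
from intervaltree import Interval, IntervalTree

from acmgrules import (
    AcmgCode,
    EngineConfig,
    InSilicoScores,
    PopulationFrequencies,
    ReferenceBundle,
    StrengthLevel,
)
from acmgrules.core_model import AminoAcidChange, ClinVarEntry, TranscriptConsequence
from acmgrules.criteria_pathogenic import (
    evaluate_pm1,
    evaluate_pm2,
    evaluate_pm4,
    evaluate_pp2,
    evaluate_pp3,
    evaluate_pp5,
    evaluate_ps1_pm5,
    evaluate_ps3,
    evaluate_ps4,
    evaluate_pvs1,
)
from acmgrules.reference_builders import HotspotDomain, PathogenicAaEntry

CFG = EngineConfig()


def _bundle(**kw) -> ReferenceBundle:
    b = ReferenceBundle()
    for key, value in kw.items():
        setattr(b, key, value)
    return b


def _tx(consequence, n=2):
    return tuple(
        TranscriptConsequence(f"TX{i}", frozenset({consequence}), is_canonical=(i == 0))
        for i in range(n)
    )


class TestPvs1:
    def _variant(self, make_variant, consequence="stop gained", n_tx=2, **kw):
        return make_variant(
            gene="G", consequences=frozenset({consequence}),
            transcript_consequences=_tx(consequence, n_tx), **kw,
        )

    def test_constrained_gene_gets_very_strong(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.3, None)})
        call = evaluate_pvs1(self._variant(make_variant), bundle, CFG)
        assert call.code is AcmgCode.PVS1
        assert call.strength is StrengthLevel.VERY_STRONG

    def test_tolerant_gene_downgraded_to_strong(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (1.2, None)})
        call = evaluate_pvs1(self._variant(make_variant), bundle, CFG)
        assert call.strength is StrengthLevel.STRONG

    def test_lof_in_single_of_several_transcripts_not_applied(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.3, None)})
        txs = (_tx("stop gained", 1) + _tx("missense variant", 2))
        v = make_variant(gene="G", consequences=frozenset({"stop gained"}),
                         transcript_consequences=txs)
        assert evaluate_pvs1(v, bundle, CFG) is None

    def test_low_impact_splice_variant_double_downgraded(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.3, None)})
        v = self._variant(make_variant, consequence="splice donor variant",
                          scores=InSilicoScores(absplice=0.03))
        assert evaluate_pvs1(v, bundle, CFG).strength is StrengthLevel.MODERATE

    def test_final_exon_window_excludes(self, make_variant):
        bundle = _bundle(
            gene_constraint={"G": (0.3, None)},
            final_coding_exons={"TX1": ("1", 0, 1000)},
        )
        inside = self._variant(make_variant, pos=980)   # within last 50 bp
        outside = self._variant(make_variant, pos=900)
        assert evaluate_pvs1(inside, bundle, CFG) is None
        assert evaluate_pvs1(outside, bundle, CFG) is not None

    def test_strength_monotone_nonincreasing_in_loeuf(self, make_variant):
        previous = 6
        for loeuf in [0.1, 0.5, 0.9, 0.99, 1.0, 1.2, 2.0]:
            bundle = _bundle(gene_constraint={"G": (loeuf, None)})
            strength = int(evaluate_pvs1(self._variant(make_variant), bundle, CFG).strength)
            assert strength <= previous
            previous = strength


class TestPs1Pm5:
    def _bundle(self, weight=3, alt_aa="H"):
        entry = PathogenicAaEntry(
            ref_aa="R", alt_aa=alt_aa, nucleotide_key=("1", 900, "G", "C"),
            review_weight=weight, clinvar_id="CV9",
        )
        return _bundle(pathogenic_aa_index={("G", 175): (entry,)})

    def _variant(self, make_variant, alt_aa="H", **kw):
        return make_variant(
            gene="G", consequences=frozenset({"missense variant"}),
            amino_acid_change=AminoAcidChange(175, "R", alt_aa), **kw,
        )

    def test_same_substitution_different_nucleotide_is_ps1(self, make_variant):
        call = evaluate_ps1_pm5(self._variant(make_variant), self._bundle(), CFG)
        assert call.code is AcmgCode.PS1
        assert call.strength is StrengthLevel.STRONG  # review weight 3

    def test_ps1_strength_capped_at_strong(self, make_variant):
        call = evaluate_ps1_pm5(self._variant(make_variant), self._bundle(weight=5), CFG)
        assert call.strength is StrengthLevel.STRONG

    def test_different_substitution_same_residue_is_pm5_capped_moderate(self, make_variant):
        call = evaluate_ps1_pm5(
            self._variant(make_variant, alt_aa="L"), self._bundle(weight=5), CFG
        )
        assert call.code is AcmgCode.PM5
        assert call.strength is StrengthLevel.MODERATE

    def test_identical_nucleotide_change_skipped(self, make_variant):
        v = self._variant(make_variant, chrom="1", pos=900, ref="G", alt="C")
        assert evaluate_ps1_pm5(v, self._bundle(), CFG) is None


class TestPs3:
    def test_single_publication_genomic_match_supporting(self, make_variant):
        v = make_variant()
        bundle = _bundle(literature_genomic={v.key: frozenset({"p1"})})
        call = evaluate_ps3(v, bundle, CFG)
        assert call.strength is StrengthLevel.SUPPORTING
        assert ("pubmed_ids", "p1") in call.details

    def test_protein_fallback_with_many_publications_strong(self, make_variant):
        v = make_variant(gene="G", amino_acid_change=AminoAcidChange(273, "R", "H"))
        bundle = _bundle(
            literature_protein={("G", "R273H"): frozenset(f"p{i}" for i in range(6))}
        )
        assert evaluate_ps3(v, bundle, CFG).strength is StrengthLevel.STRONG

    def test_mid_tier_publication_count_moderate(self, make_variant):
        v = make_variant()
        bundle = _bundle(literature_genomic={v.key: frozenset({"p1", "p2", "p3"})})
        assert evaluate_ps3(v, bundle, CFG).strength is StrengthLevel.MODERATE

    def test_no_hits_not_applied(self, make_variant, empty_bundle):
        assert evaluate_ps3(make_variant(), empty_bundle, CFG) is None


class TestPs4:
    def test_genome_wide_association_with_large_or_strong(self, make_variant):
        v = make_variant()
        bundle = _bundle(gwas_index={("1", v.pos): (4.2, 1e-12)})
        assert evaluate_ps4(v, bundle, CFG).strength is StrengthLevel.STRONG

    def test_moderate_or_tier(self, make_variant):
        v = make_variant()
        bundle = _bundle(gwas_index={("1", v.pos): (2.0, 1e-9)})
        assert evaluate_ps4(v, bundle, CFG).strength is StrengthLevel.MODERATE

    def test_topmed_rare_allele_proxy_supporting(self, make_variant, empty_bundle):
        v = make_variant(freq=PopulationFrequencies(topmed_ac=3))
        assert evaluate_ps4(v, empty_bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_topmed_boundary_count_not_applied(self, make_variant, empty_bundle):
        v = make_variant(freq=PopulationFrequencies(topmed_ac=5, topmed_hom_count=0))
        assert evaluate_ps4(v, empty_bundle, CFG) is None

    def test_topmed_homozygote_band_supporting(self, make_variant, empty_bundle):
        v = make_variant(freq=PopulationFrequencies(topmed_ac=50, topmed_hom_count=4))
        assert evaluate_ps4(v, empty_bundle, CFG).strength is StrengthLevel.SUPPORTING


def _domain_bundle(n_path, n_benign, n_vus, start=0, end=2000):
    d = HotspotDomain("D1", "1", start, end, n_path=n_path, n_benign=n_benign,
                      n_vus=n_vus)
    return _bundle(hotspot_domains={"1": IntervalTree([Interval(start, end, d)])})


class TestPm1:
    def test_mixed_domain_lowered_to_supporting(self, make_variant):
        # 667/1000 pathogenic (< 75%) and 167/1000 benign (> 15%)
        bundle = _domain_bundle(667, 167, 166)
        assert evaluate_pm1(make_variant(), bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_highly_enriched_domain_raised_to_strong(self, make_variant):
        bundle = _domain_bundle(19, 1, 0)
        assert evaluate_pm1(make_variant(), bundle, CFG).strength is StrengthLevel.STRONG

    def test_default_moderate(self, make_variant):
        bundle = _domain_bundle(20, 3, 2)  # 80% path, 12% benign
        assert evaluate_pm1(make_variant(), bundle, CFG).strength is StrengthLevel.MODERATE

    def test_outside_all_domains_not_applied(self, make_variant):
        bundle = _domain_bundle(19, 1, 0, start=5000, end=6000)
        assert evaluate_pm1(make_variant(pos=100), bundle, CFG) is None


class TestPm2:
    def test_absent_from_both_databases_moderate(self, make_variant, empty_bundle):
        call = evaluate_pm2(make_variant(gene="G"), empty_bundle, CFG)
        assert call.strength is StrengthLevel.MODERATE

    def test_between_cutoffs_supporting(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.8, None)})  # bin 2
        v = make_variant(gene="G", freq=PopulationFrequencies(gnomad_af=1e-5))
        assert evaluate_pm2(v, bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_above_supporting_cutoff_not_applied(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.8, None)})
        v = make_variant(gene="G", freq=PopulationFrequencies(gnomad_af=1e-3))
        assert evaluate_pm2(v, bundle, CFG) is None

    def test_larger_of_the_two_frequencies_governs(self, make_variant):
        bundle = _bundle(gene_constraint={"G": (0.8, None)})
        v = make_variant(gene="G", freq=PopulationFrequencies(
            gnomad_af=1e-7, thousand_genomes_af=1e-3))
        assert evaluate_pm2(v, bundle, CFG) is None


class TestPm4:
    def test_short_inframe_deletion_supporting(self, make_variant, empty_bundle):
        v = make_variant(ref="A" + "CGT" * 3, alt="A",  # 9 nt = 3 residues
                         consequences=frozenset({"inframe deletion"}))
        assert evaluate_pm4(v, empty_bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_long_inframe_insertion_strong(self, make_variant, empty_bundle):
        v = make_variant(ref="A", alt="A" + "CGT" * 11,  # 33 nt = 11 residues
                         consequences=frozenset({"inframe insertion"}))
        assert evaluate_pm4(v, empty_bundle, CFG).strength is StrengthLevel.STRONG

    def test_inside_repeat_region_not_applied(self, make_variant):
        bundle = _bundle(repeat_coding={"1": IntervalTree([Interval(0, 5000)])})
        v = make_variant(ref="A" + "CGT" * 3, alt="A",
                         consequences=frozenset({"inframe deletion"}))
        assert evaluate_pm4(v, bundle, CFG) is None

    def test_stop_loss_treated_as_minimal_extension(self, make_variant, empty_bundle):
        v = make_variant(ref="A", alt="G", consequences=frozenset({"stop loss"}))
        assert evaluate_pm4(v, empty_bundle, CFG).strength is StrengthLevel.SUPPORTING


class TestPp2:
    def test_missense_in_listed_gene_supporting(self, make_variant):
        bundle = _bundle(pp2_genes={"G": 0.25})
        v = make_variant(gene="G", consequences=frozenset({"missense variant"}))
        assert evaluate_pp2(v, bundle, CFG).strength is StrengthLevel.SUPPORTING

    def test_tightly_constrained_gene_moderate(self, make_variant):
        bundle = _bundle(pp2_genes={"G": 0.08})
        v = make_variant(gene="G", consequences=frozenset({"missense variant"}))
        assert evaluate_pp2(v, bundle, CFG).strength is StrengthLevel.MODERATE

    def test_non_missense_not_applied(self, make_variant):
        bundle = _bundle(pp2_genes={"G": 0.08})
        v = make_variant(gene="G", consequences=frozenset({"synonymous variant"}))
        assert evaluate_pp2(v, bundle, CFG) is None


class TestPp3:
    def test_single_tool_above_supporting_applies_at_its_tier(self, make_variant, empty_bundle):
        v = make_variant(scores=InSilicoScores(revel=0.8))
        assert evaluate_pp3(v, empty_bundle, CFG).strength is StrengthLevel.MODERATE

    def test_two_tools_tied_at_supporting_upweight_to_moderate(self, make_variant, empty_bundle):
        v = make_variant(scores=InSilicoScores(revel=0.7, dann=0.995))
        call = evaluate_pp3(v, empty_bundle, CFG)
        assert call.strength is StrengthLevel.MODERATE

    def test_single_supporting_tool_not_enough(self, make_variant, empty_bundle):
        v = make_variant(scores=InSilicoScores(revel=0.7))
        assert evaluate_pp3(v, empty_bundle, CFG) is None

    def test_strong_benign_signal_disqualifies(self, make_variant, empty_bundle):
        # REVEL pathogenic-moderate but DANN below its strong-benign bound
        v = make_variant(scores=InSilicoScores(revel=0.8, dann=0.005))
        assert evaluate_pp3(v, empty_bundle, CFG) is None

    def test_result_invariant_to_ladder_ordering(self, make_variant, empty_bundle):
        v = make_variant(scores=InSilicoScores(revel=0.8, dann=0.9995, phylop=8.0))
        forward = evaluate_pp3(v, empty_bundle, CFG)
        reversed_cfg = EngineConfig(
            tool_ladders=dict(reversed(list(CFG.tool_ladders.items())))
        )
        backward = evaluate_pp3(v, empty_bundle, reversed_cfg)
        assert forward.strength == backward.strength
        assert forward.details == backward.details


class TestPp5:
    def test_expert_panel_assertion_stand_alone(self, make_variant, empty_bundle):
        v = make_variant(clinvar_top=ClinVarEntry("P", "reviewed by expert panel", "1"))
        assert evaluate_pp5(v, empty_bundle, CFG).strength is StrengthLevel.STAND_ALONE

    def test_single_submitter_moderate(self, make_variant, empty_bundle):
        v = make_variant(clinvar_top=ClinVarEntry(
            "LP", "criteria provided, single submitter", "2"))
        assert evaluate_pp5(v, empty_bundle, CFG).strength is StrengthLevel.MODERATE

    def test_vus_assertion_not_applied(self, make_variant, empty_bundle):
        v = make_variant(clinvar_top=ClinVarEntry("VUS", "reviewed by expert panel", "3"))
        assert evaluate_pp5(v, empty_bundle, CFG) is None

    def test_no_assertion_criteria_not_applied(self, make_variant, empty_bundle):
        v = make_variant(clinvar_top=ClinVarEntry(
            "P", "no assertion criteria provided", "4"))
        assert evaluate_pp5(v, empty_bundle, CFG) is None
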
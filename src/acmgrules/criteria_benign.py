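"""The eight automated benign evidence codes (BA1, BS1, BS2, BP1, BP3,
BP4, BP6, BP7).

BA1/BS1 read the same LOEUF-stratified frequency ladder as PM2 but from
the high-frequency end, so BA1 and PM2 can never co-fire.  BP4 is the
benign side of the shared in-silico consensus defined next to PP3.
"""

from __future__ import annotations

from typing import Optional

from .core_model import (
    AcmgCode,
    AnnotatedVariant,
    EngineConfig,
    EvidenceCall,
    InheritanceMode,
    StrengthLevel,
)
from .criteria_pathogenic import (
    _BENIGN_SIG,
    _call,
    _clinvar_assertion_call,
    insilico_consensus,
)
from .reference_builders import ReferenceBundle


# ---------------------------------------------------------------------------
# BA1 / BS1 — too common in the population
# ---------------------------------------------------------------------------


def evaluate_ba1_bs1(v: AnnotatedVariant, bundle: ReferenceBundle,
                     config: EngineConfig) -> list[EvidenceCall]:
    """High population frequency against the gene's LOEUF bin.

    Above the BA1 cutoff the variant is benign stand-alone (and BS1 is
    not considered); from the BS1 standard cutoff up to the BA1 cutoff
    BS1 applies at strong; between the BS1 supporting and standard
    cutoffs BS1 applies at supporting.
    """
    af = v.freq.max_af()
    if af is None:
        return []
    bins = config.loeuf_bins
    bin_idx = bins.bin_index(bundle.loeuf(v.gene))
    ba1_cut = bins.ba1[bin_idx]
    bs1_std = bins.bs1_standard[bin_idx]
    bs1_sup = bins.bs1_supporting[bin_idx]

    if af > ba1_cut:
        return [_call(
            AcmgCode.BA1, StrengthLevel.STAND_ALONE,
            f"AF {af} above BA1 cutoff {ba1_cut} (LOEUF bin {bin_idx})",
            (("af", str(af)), ("loeuf_bin", str(bin_idx))),
        )]
    if af >= bs1_std:
        return [_call(
            AcmgCode.BS1, StrengthLevel.STRONG,
            f"AF {af} at or above BS1 standard cutoff {bs1_std} (LOEUF bin {bin_idx})",
            (("af", str(af)), ("loeuf_bin", str(bin_idx))),
        )]
    if af >= bs1_sup:
        return [_call(
            AcmgCode.BS1, StrengthLevel.SUPPORTING,
            f"AF {af} between BS1 supporting {bs1_sup} and standard {bs1_std} "
            f"cutoffs (LOEUF bin {bin_idx})",
            (("af", str(af)), ("loeuf_bin", str(bin_idx))),
        )]
    return []


# ---------------------------------------------------------------------------
# BS2 — observed in healthy individuals
# ---------------------------------------------------------------------------


def evaluate_bs2(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Healthy-population observations, stratified by inheritance mode.

    Recessive: homozygote count above the recessive threshold (strong at
    twice the threshold, else moderate).  Dominant: only in LoF-constrained
    genes (LOEUF below the dominant bound), requiring low AF and allele
    counts meeting the dominant threshold in every resource.  X-linked:
    healthy hemizygous males or homozygous females above the X-linked
    threshold.
    """
    modes = {g.inheritance for g in v.gene_disease}
    if not modes:
        return None
    bins = config.loeuf_bins
    bin_idx = bins.bin_index(bundle.loeuf(v.gene))
    candidates: list[tuple[StrengthLevel, str]] = []

    if InheritanceMode.AR in modes:
        threshold = bins.bs2_recessive_hom[bin_idx]
        hom = v.freq.gnomad_hom_count
        if hom is not None and hom > threshold:
            strength = (StrengthLevel.STRONG if hom >= 2 * threshold
                        else StrengthLevel.MODERATE)
            candidates.append((
                strength,
                f"recessive disease gene with {hom} healthy homozygotes "
                f"(threshold {threshold})",
            ))

    if InheritanceMode.AD in modes:
        loeuf = bundle.loeuf(v.gene)
        if loeuf is not None and loeuf < config.bs2_dominant_loeuf_max:
            af = v.freq.max_af() or 0.0
            threshold = bins.bs2_dominant_allele[bin_idx]
            counts = [
                v.freq.gnomad_controls_ac or 0,
                v.freq.gnomad_ac or 0,
                v.freq.thousand_genomes_ac or 0,
            ]
            if af <= bins.bs2_af[bin_idx] and min(counts) >= threshold:
                candidates.append((
                    StrengthLevel.STRONG,
                    f"dominant disease gene (LOEUF {loeuf}) with allele counts "
                    f"{counts} at or above threshold {threshold} in healthy "
                    f"populations",
                ))

    if InheritanceMode.XL in modes:
        threshold = bins.bs2_x_linked[bin_idx]
        hemi = v.freq.hemizygous_male_count
        hom_f = v.freq.homozygous_female_count
        if (hemi is not None and hemi > threshold) or (
                hom_f is not None and hom_f > threshold):
            candidates.append((
                StrengthLevel.STRONG,
                f"X-linked disease gene with {hemi or 0} healthy hemizygous "
                f"males / {hom_f or 0} homozygous females (threshold {threshold})",
            ))

    if not candidates:
        return None
    strength, note = max(candidates, key=lambda c: int(c[0]))
    return _call(AcmgCode.BS2, strength, note)


# ---------------------------------------------------------------------------
# BP1 — missense where truncation is the disease mechanism
# ---------------------------------------------------------------------------


def evaluate_bp1(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Missense variant in a gene whose pathogenic variants are
    predominantly truncating."""
    if v.gene is None or v.gene not in bundle.bp1_genes:
        return None
    if not any("missense" in c for c in v.consequences):
        return None
    return _call(
        AcmgCode.BP1, StrengthLevel.SUPPORTING,
        f"missense variant in truncating-mechanism gene {v.gene}",
    )


# ---------------------------------------------------------------------------
# BP3 — in-frame indel in a repeat region
# ---------------------------------------------------------------------------


def evaluate_bp3(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """In-frame indel inside a repeat∩coding interval.

    Indels shorter than the strong bound get strong; up to the supporting
    bound get supporting; longer repeat indels are not scored.  Indels
    shorter than one codon are excluded unless they cause a stop loss.
    """
    length = v.indel_length
    if length % 3 != 0:
        return None
    if length < config.bp3_min_nt and "stop loss" not in v.consequences:
        return None
    span_end = v.pos - 1 + max(len(v.ref), 1)
    overlap = bundle.repeat_overlap(v.chrom, v.pos - 1, span_end)
    if not overlap:
        return None

    if length < config.bp3_strong_max_nt:
        strength = StrengthLevel.STRONG
    elif length < config.bp3_supporting_max_nt:
        strength = StrengthLevel.SUPPORTING
    else:
        return None
    intervals = ",".join(f"[{s},{e})" for s, e in overlap)
    return _call(
        AcmgCode.BP3, strength,
        f"{length}-nt in-frame indel within repeat region {intervals}",
        (("repeat_intervals", intervals),),
    )


# ---------------------------------------------------------------------------
# BP4 — benign in-silico consensus (mirror of PP3)
# ---------------------------------------------------------------------------


def evaluate_bp4(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Multiple computational tools independently support a benign effect."""
    _, bp4_call = insilico_consensus(v, config)
    return bp4_call


# ---------------------------------------------------------------------------
# BP6 — reputable-source (ClinVar) benign assertion
# ---------------------------------------------------------------------------


def evaluate_bp6(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Same review-status weighting as PP5, for B/LB ClinVar assertions."""
    return _clinvar_assertion_call(v, config, AcmgCode.BP6, _BENIGN_SIG)


# ---------------------------------------------------------------------------
# BP7 — synonymous/intronic/intergenic with no predicted impact
# ---------------------------------------------------------------------------


BP7_TERMS = ("synonymous", "intron", "intergenic")  # synonymous checked first


def evaluate_bp7(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Low conservation plus no predicted splicing impact.

    Eligible consequences: synonymous (prioritised), intronic, intergenic.
    PhyloP below the eligibility bound and ABSplice below its bound give
    supporting; exceptionally low conservation with minimal splicing
    impact raises the call to strong.
    """
    matched = next(
        (term for term in BP7_TERMS
         if any(term in c for c in v.consequences)),
        None,
    )
    if matched is None:
        return None
    phylop, absplice = v.scores.phylop, v.scores.absplice
    if phylop is None or absplice is None:
        return None
    if not (phylop < config.bp7_phylop_eligible
            and absplice < config.bp7_absplice_eligible):
        return None
    strength = StrengthLevel.SUPPORTING
    if absplice < config.bp7_absplice_strong and phylop < config.bp7_phylop_strong:
        strength = StrengthLevel.STRONG
    return _call(
        AcmgCode.BP7, strength,
        f"{matched} variant with PhyloP {phylop} and ABSplice {absplice}",
        (("phylop", str(phylop)), ("absplice", str(absplice))),
    )


#: evaluators in engine execution order (BA1/BS1 share one routine)
BENIGN_EVALUATORS = (
    evaluate_ba1_bs1,
    evaluate_bs2,
    evaluate_bp1,
    evaluate_bp3,
    evaluate_bp4,
    evaluate_bp6,
    evaluate_bp7,
)
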
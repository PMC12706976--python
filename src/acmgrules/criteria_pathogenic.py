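"""The ten automated pathogenic evidence codes.

Each ``evaluate_*`` function inspects one :class:`AnnotatedVariant`
against the reference bundle and configuration and returns an
:class:`EvidenceCall` at a dynamically weighted strength, or ``None`` when
the code does not apply.  All functions are pure.

This module also hosts the shared in-silico consensus used by PP3 and its
benign mirror BP4, so the two codes are computed from a single routine and
can never contradict each other.
"""

from __future__ import annotations

from typing import Optional

from .core_model import (
    AcmgCode,
    AnnotatedVariant,
    EngineConfig,
    EvidenceCall,
    StrengthLevel,
    normalize_chrom,
)
from .reference_builders import ReferenceBundle

#: consequence terms treated as predicted loss of function for PVS1
LOF_CONSEQUENCES = frozenset({
    "frameshift variant",
    "stop gained",
    "start loss",
    "splice donor variant",
    "splice acceptor variant",
})

SPLICE_CONSEQUENCES = frozenset({"splice donor variant", "splice acceptor variant"})

_PATHOGENIC_SIG = frozenset({"P", "LP", "pathogenic", "likely pathogenic",
                             "Pathogenic", "Likely pathogenic"})
_BENIGN_SIG = frozenset({"B", "LB", "benign", "likely benign",
                         "Benign", "Likely benign"})


def _call(code: AcmgCode, strength: StrengthLevel, rationale: str,
          details: tuple[tuple[str, str], ...] = ()) -> EvidenceCall:
    return EvidenceCall(code=code, strength=strength, rationale=rationale,
                       source="auto", details=details)


# ---------------------------------------------------------------------------
# PVS1 — predicted loss of function
# ---------------------------------------------------------------------------


def evaluate_pvs1(v: AnnotatedVariant, bundle: ReferenceBundle,
                  config: EngineConfig) -> Optional[EvidenceCall]:
    """Loss-of-function variant in a gene where LoF causes disease.

    Strength starts at very strong and loses one step per failed
    confidence check: LOEUF at or above the full-strength bound, splice
    impact below the low-impact cutoff, splice impact below the
    minimal-impact cutoff.
    """
    lof = v.consequences & LOF_CONSEQUENCES
    for tx in v.transcript_consequences:
        lof |= tx.consequences & LOF_CONSEQUENCES
    if not lof:
        return None

    if len(v.transcript_consequences) > 1:
        n_lof_tx = sum(
            1 for tx in v.transcript_consequences if tx.consequences & LOF_CONSEQUENCES
        )
        if n_lof_tx <= 1:
            return None

    if bundle.in_final_exon_window(v.chrom, v.pos, config.pvs1_final_exon_window):
        return None

    loeuf = bundle.loeuf(v.gene)
    level = int(StrengthLevel.VERY_STRONG)
    notes = [f"LoF consequence(s): {', '.join(sorted(lof))}"]
    if loeuf is None or loeuf >= config.pvs1_loeuf_full_strength:
        level -= 1
        notes.append(
            f"gene LOEUF {'unavailable' if loeuf is None else loeuf} not below "
            f"{config.pvs1_loeuf_full_strength}: downgraded"
        )
    else:
        notes.append(f"gene LOEUF {loeuf} below {config.pvs1_loeuf_full_strength}")

    if lof & SPLICE_CONSEQUENCES and v.scores.absplice is not None:
        if v.scores.absplice < config.pvs1_splice_low_impact:
            level -= 1
            notes.append(
                f"ABSplice {v.scores.absplice} below low-impact cutoff "
                f"{config.pvs1_splice_low_impact}: downgraded"
            )
        if v.scores.absplice < config.pvs1_splice_minimal_impact:
            level -= 1
            notes.append(
                f"ABSplice {v.scores.absplice} below minimal-impact cutoff "
                f"{config.pvs1_splice_minimal_impact}: downgraded"
            )

    strength = StrengthLevel(max(level, int(StrengthLevel.SUPPORTING)))
    details = (("loeuf", str(loeuf)),)
    if v.scores.absplice is not None:
        details += (("absplice", str(v.scores.absplice)),)
    return _call(AcmgCode.PVS1, strength, "; ".join(notes), details)


# ---------------------------------------------------------------------------
# PS1 / PM5 — known pathogenic amino-acid substitution / same residue
# ---------------------------------------------------------------------------


def evaluate_ps1_pm5(v: AnnotatedVariant, bundle: ReferenceBundle,
                     config: EngineConfig) -> Optional[EvidenceCall]:
    """Compare a missense change against the known-pathogenic residue index.

    Same amino-acid substitution via a different nucleotide change gives
    PS1; a different substitution at the same residue gives PM5.  A variant
    identical to an indexed nucleotide change is skipped here (that
    evidence belongs to PP5, and a ClinVar variant must not support
    itself).  Strength follows the indexed record's review weight, capped
    at strong for PS1 and moderate for PM5.
    """
    if v.amino_acid_change is None or v.gene is None:
        return None
    if not any("missense" in c for c in v.consequences):
        return None

    aa = v.amino_acid_change
    entries = bundle.pathogenic_aa_index.get((v.gene, aa.position), ())
    if not entries:
        return None
    if any(e.nucleotide_key == v.key for e in entries):
        return None  # exact ClinVar match is PP5 territory

    same_sub = [e for e in entries if e.ref_aa == aa.ref_aa and e.alt_aa == aa.alt_aa]
    if same_sub:
        best = max(same_sub, key=lambda e: e.review_weight)
        strength = StrengthLevel(min(best.review_weight, config.ps1_max_strength))
        return _call(
            AcmgCode.PS1, strength,
            f"same substitution {aa} as known pathogenic variant "
            f"(ClinVar {best.clinvar_id}, review weight {best.review_weight})",
            (("clinvar_id", best.clinvar_id),),
        )

    best = max(entries, key=lambda e: e.review_weight)
    strength = StrengthLevel(min(best.review_weight, config.pm5_max_strength))
    return _call(
        AcmgCode.PM5, strength,
        f"novel substitution {aa} at residue with known pathogenic "
        f"p.{best.ref_aa}{aa.position}{best.alt_aa} "
        f"(ClinVar {best.clinvar_id}, review weight {best.review_weight})",
        (("clinvar_id", best.clinvar_id),),
    )


# ---------------------------------------------------------------------------
# PS3 — functional-study literature support
# ---------------------------------------------------------------------------


def evaluate_ps3(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Literature-mined functional evidence, weighted by the number of
    unique publications (genomic match preferred over gene:protein)."""
    pmids = bundle.literature_genomic.get(v.key)
    matched = "genomic"
    if not pmids and v.gene is not None and v.amino_acid_change is not None:
        aa = v.amino_acid_change
        pmids = bundle.literature_protein.get(
            (v.gene, f"{aa.ref_aa}{aa.position}{aa.alt_aa}")
        )
        matched = "protein"
    if not pmids:
        return None

    n = len(pmids)
    if n >= config.ps3_strong_min_pubs:
        strength = StrengthLevel.STRONG
    elif n >= config.ps3_moderate_min_pubs:
        strength = StrengthLevel.MODERATE
    else:
        strength = StrengthLevel.SUPPORTING
    return _call(
        AcmgCode.PS3, strength,
        f"{n} unique publication(s) with functional evidence ({matched} match)",
        (("pubmed_ids", ",".join(sorted(pmids))),),
    )


# ---------------------------------------------------------------------------
# PS4 — case-control / GWAS prevalence
# ---------------------------------------------------------------------------


def evaluate_ps4(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """GWAS odds-ratio evidence; without a GWAS entry, rarity in the
    TOPMed case-control cohort serves as a supporting-level proxy."""
    hit = bundle.gwas_index.get((normalize_chrom(v.chrom), v.pos))
    if hit is not None:
        odds, pval = hit
        if pval < config.ps4_genome_wide_p and odds >= config.ps4_strong_or:
            strength = StrengthLevel.STRONG
        elif pval < config.ps4_genome_wide_p and odds >= config.ps4_moderate_or:
            strength = StrengthLevel.MODERATE
        elif pval < config.ps4_supporting_p and odds > config.ps4_supporting_or:
            strength = StrengthLevel.SUPPORTING
        else:
            return None
        return _call(
            AcmgCode.PS4, strength,
            f"GWAS association OR {odds}, p {pval}",
            (("odds_ratio", str(odds)), ("p_value", str(pval))),
        )

    ac = v.freq.topmed_ac
    hom = v.freq.topmed_hom_count
    if ac is not None and ac < config.ps4_topmed_max_ac:
        return _call(
            AcmgCode.PS4, StrengthLevel.SUPPORTING,
            f"TOPMed alternate allele count {ac} below {config.ps4_topmed_max_ac}",
            (("topmed_ac", str(ac)),),
        )
    if hom is not None and config.ps4_topmed_hom_min <= hom <= config.ps4_topmed_hom_max:
        return _call(
            AcmgCode.PS4, StrengthLevel.SUPPORTING,
            f"TOPMed homozygote count {hom} in "
            f"[{config.ps4_topmed_hom_min}, {config.ps4_topmed_hom_max}]",
            (("topmed_hom_count", str(hom)),),
        )
    return None


# ---------------------------------------------------------------------------
# PM1 — mutational hotspot / well-established functional domain
# ---------------------------------------------------------------------------


def evaluate_pm1(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Variant inside a pathogenic-enriched domain; strength follows the
    domain's pathogenic/benign composition."""
    hits = bundle.hotspots_at(v.chrom, v.pos)
    if not hits:
        return None
    d = hits[0]
    strength = StrengthLevel.MODERATE
    if (d.path_frac > config.pm1_strong_path_frac
            and d.benign_frac < config.pm1_strong_benign_frac):
        strength = StrengthLevel.STRONG
    elif (d.path_frac < config.pm1_supporting_path_frac
            and d.benign_frac > config.pm1_supporting_benign_frac):
        strength = StrengthLevel.SUPPORTING
    return _call(
        AcmgCode.PM1, strength,
        f"in hotspot domain {d.domain_id} "
        f"({d.n_path}/{d.n_total} pathogenic, {d.n_benign}/{d.n_total} benign)",
        (("domain_id", d.domain_id),
         ("path_frac", f"{d.path_frac:.4f}"),
         ("benign_frac", f"{d.benign_frac:.4f}")),
    )


# ---------------------------------------------------------------------------
# PM2 — absent / ultra-rare in population databases
# ---------------------------------------------------------------------------


def evaluate_pm2(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Rarity against the gene's LOEUF-stratified cutoffs: below the
    standard cutoff (or absent everywhere) is moderate, between standard
    and supporting cutoffs is supporting."""
    bins = config.loeuf_bins
    bin_idx = bins.bin_index(bundle.loeuf(v.gene))
    standard = bins.pm2_standard[bin_idx]
    supporting = bins.pm2_supporting[bin_idx]

    af = v.freq.max_af()
    if af is None:
        return _call(
            AcmgCode.PM2, StrengthLevel.MODERATE,
            "absent from gnomAD and 1000 Genomes",
            (("loeuf_bin", str(bin_idx)),),
        )
    if af < standard:
        return _call(
            AcmgCode.PM2, StrengthLevel.MODERATE,
            f"AF {af} below standard cutoff {standard} (LOEUF bin {bin_idx})",
            (("af", str(af)), ("loeuf_bin", str(bin_idx))),
        )
    if af < supporting:
        return _call(
            AcmgCode.PM2, StrengthLevel.SUPPORTING,
            f"AF {af} between standard {standard} and supporting {supporting} "
            f"cutoffs (LOEUF bin {bin_idx})",
            (("af", str(af)), ("loeuf_bin", str(bin_idx))),
        )
    return None


# ---------------------------------------------------------------------------
# PM4 — protein-length change outside repeats
# ---------------------------------------------------------------------------


PM4_CONSEQUENCES = frozenset({"stop loss", "inframe insertion", "inframe deletion"})


def evaluate_pm4(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """In-frame indel or stop loss changing protein length, outside
    repeat regions; strength scales with the length change in residues.

    Stop-loss substitutions (no length change at the nucleotide level) are
    treated as extension events at the minimum supporting strength.
    """
    if not (v.consequences & PM4_CONSEQUENCES):
        return None
    span_end = v.pos - 1 + max(len(v.ref), 1)
    if bundle.repeat_overlap(v.chrom, v.pos - 1, span_end):
        return None

    aa_len = v.indel_length // 3
    if aa_len >= config.pm4_strong_min_aa:
        strength = StrengthLevel.STRONG
    elif aa_len >= config.pm4_moderate_min_aa:
        strength = StrengthLevel.MODERATE
    else:
        strength = StrengthLevel.SUPPORTING
    return _call(
        AcmgCode.PM4, strength,
        f"protein-length change of {aa_len} residue(s) outside repeat regions",
        (("aa_length", str(aa_len)),),
    )


# ---------------------------------------------------------------------------
# PP2 — missense in a missense-constrained gene
# ---------------------------------------------------------------------------


def evaluate_pp2(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Missense variant in a gene where missense change is the dominant
    pathogenic mechanism; strongly constrained genes (missense O/E below
    the moderate bound) upgrade to moderate."""
    if v.gene is None or v.gene not in bundle.pp2_genes:
        return None
    if not any("missense" in c for c in v.consequences):
        return None
    oe = bundle.pp2_genes[v.gene]
    strength = StrengthLevel.SUPPORTING
    note = f"missense in missense-constrained gene {v.gene}"
    if oe is not None and oe < config.pp2_oe_moderate:
        strength = StrengthLevel.MODERATE
        note += f" (missense O/E {oe} below {config.pp2_oe_moderate})"
    elif oe is not None:
        note += f" (missense O/E {oe})"
    return _call(AcmgCode.PP2, strength, note,
                 (("missense_oe", str(oe)),))


# ---------------------------------------------------------------------------
# PP3 / BP4 — in-silico consensus (shared routine)
# ---------------------------------------------------------------------------


def insilico_consensus(
    v: AnnotatedVariant, config: EngineConfig
) -> tuple[Optional[EvidenceCall], Optional[EvidenceCall]]:
    """Evaluate the computational-predictor consensus once, returning
    (PP3 call or None, BP4 call or None).

    Per tool, the score maps to a pathogenic and/or benign contribution
    level through that tool's calibration ladder.  A side is disqualified
    when any tool crosses the opposite side's *strong* threshold.  On each
    side: the base level is the maximum contribution; a tie of two or more
    tools at that maximum upweights one level (capped at very strong); a
    single tool at supporting is not enough.  If both sides survive, the
    consensus is contradictory and neither code is applied — so PP3 and
    BP4 can never co-fire.
    """
    path_contrib: dict[str, StrengthLevel] = {}
    benign_contrib: dict[str, StrengthLevel] = {}
    path_disqualified = benign_disqualified = False

    for tool in sorted(config.tool_ladders):
        ladder = config.tool_ladders[tool]
        score = getattr(v.scores, tool, None)
        if score is None:
            continue
        p_level = ladder.pathogenic_level(score)
        b_level = ladder.benign_level(score)
        if p_level:
            path_contrib[tool] = p_level
        if b_level:
            benign_contrib[tool] = b_level
        if ladder.strong_benign is not None and score <= ladder.strong_benign:
            path_disqualified = True
        if ladder.strong_pathogenic is not None and score >= ladder.strong_pathogenic:
            benign_disqualified = True

    def finalize(contrib: dict[str, StrengthLevel]) -> Optional[tuple[StrengthLevel, list[str]]]:
        if not contrib:
            return None
        top = max(contrib.values())
        if top == StrengthLevel.SUPPORTING and len(contrib) == 1:
            return None  # a single supporting-level tool is not evidence
        at_top = sorted(t for t, lvl in contrib.items() if lvl == top)
        if len(at_top) >= 2:
            level = StrengthLevel(min(int(top) + 1, int(StrengthLevel.VERY_STRONG)))
        else:
            level = top
        return level, sorted(contrib)

    pp3 = None if path_disqualified else finalize(path_contrib)
    bp4 = None if benign_disqualified else finalize(benign_contrib)
    if pp3 is not None and bp4 is not None:
        return None, None  # contradictory consensus is not evidence either way

    pp3_call = bp4_call = None
    if pp3 is not None:
        level, tools = pp3
        pp3_call = _call(
            AcmgCode.PP3, level,
            f"pathogenic in-silico consensus from {', '.join(tools)}",
            tuple((t, str(getattr(v.scores, t))) for t in tools),
        )
    if bp4 is not None:
        level, tools = bp4
        bp4_call = _call(
            AcmgCode.BP4, level,
            f"benign in-silico consensus from {', '.join(tools)}",
            tuple((t, str(getattr(v.scores, t))) for t in tools),
        )
    return pp3_call, bp4_call


def evaluate_pp3(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """Multiple computational tools independently support pathogenicity."""
    pp3_call, _ = insilico_consensus(v, config)
    return pp3_call


# ---------------------------------------------------------------------------
# PP5 — reputable-source (ClinVar) pathogenic assertion
# ---------------------------------------------------------------------------


def _clinvar_assertion_call(
    v: AnnotatedVariant, config: EngineConfig, code: AcmgCode,
    accepted: frozenset[str],
) -> Optional[EvidenceCall]:
    top = v.clinvar_top
    if top is None or top.significance not in accepted:
        return None
    weight = config.review_weights.weight(top.review_status)
    if weight < 1:
        return None
    return _call(
        code, StrengthLevel(int(weight)),
        f"ClinVar {top.significance} assertion, review status "
        f"'{top.review_status}' (id {top.clinvar_id})",
        (("clinvar_id", top.clinvar_id), ("review_status", top.review_status)),
    )


def evaluate_pp5(v: AnnotatedVariant, bundle: ReferenceBundle,
                 config: EngineConfig) -> Optional[EvidenceCall]:
    """ClinVar P/LP assertion weighted by review status; expert-panel and
    practice-guideline assertions reach stand-alone strength."""
    return _clinvar_assertion_call(v, config, AcmgCode.PP5, _PATHOGENIC_SIG)


#: evaluators in engine execution order (PS1/PM5 share one routine)
PATHOGENIC_EVALUATORS = (
    evaluate_pvs1,
    evaluate_ps1_pm5,
    evaluate_ps3,
    evaluate_ps4,
    evaluate_pm1,
    evaluate_pm2,
    evaluate_pm4,
    evaluate_pp2,
    evaluate_pp3,
    evaluate_pp5,
)
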
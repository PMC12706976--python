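"""Per-variant orchestration: run the automated criteria, apply external
calls, then combine evidence into a five-tier classification.

The combining procedure follows the ACMG/AMP 2015 tables with two
extensions: a pathogenic stand-alone level (mirroring BA1) and an ordered
two-pass conflict check.  Evidence on both polarities above the high
conflict threshold routes straight to Uncertain; after the strong
pathogenic/benign checks fail, a lower threshold catches weaker mixed
evidence before the likely-pathogenic/likely-benign rules run.  Codes
count at their effective (dynamically weighted) level.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .annotation_io import ExternalCall
from .core_model import (
    AcmgCode,
    AnnotatedVariant,
    Category,
    ClassificationResult,
    ConflictStage,
    EngineConfig,
    EvidenceCall,
    Polarity,
    StrengthLevel,
)
from .criteria_benign import BENIGN_EVALUATORS
from .criteria_pathogenic import PATHOGENIC_EVALUATORS
from .reference_builders import ReferenceBundle

logger = logging.getLogger("acmgrules")

_LOG_EVERY = 10_000


# ---------------------------------------------------------------------------
# evidence collection
# ---------------------------------------------------------------------------


def evaluate_all(
    v: AnnotatedVariant,
    bundle: ReferenceBundle,
    config: EngineConfig,
    external: Sequence[ExternalCall] = (),
) -> list[EvidenceCall]:
    """Run every automated evaluator, then fold in external calls.

    External calls with strength 0 remove the code for this variant;
    other calls set or override the code at the given strength with
    source=manual.  Duplicate calls for the same code: last wins (with a
    warning).  At most one call per code is returned.
    """
    calls: dict[AcmgCode, EvidenceCall] = {}
    for evaluate in PATHOGENIC_EVALUATORS + BENIGN_EVALUATORS:
        result = evaluate(v, bundle, config)
        if result is None:
            continue
        for call in result if isinstance(result, list) else (result,):
            calls[call.code] = call

    seen: set[AcmgCode] = set()
    for ext in external:
        if ext.code in seen:
            logger.warning(
                "duplicate external call for %s on %s; last wins",
                ext.code.value, ext.variant_key,
            )
        seen.add(ext.code)
        if ext.strength == 0:
            calls.pop(ext.code, None)
        else:
            calls[ext.code] = EvidenceCall(
                code=ext.code,
                strength=StrengthLevel(ext.strength),
                rationale=ext.rationale,
                source="manual",
            )
    return list(calls.values())


# ---------------------------------------------------------------------------
# combining criteria
# ---------------------------------------------------------------------------


def _level_counts(evidence: Iterable[EvidenceCall], polarity: Polarity) -> Counter:
    return Counter(
        int(e.strength) for e in evidence if e.code.polarity == polarity
    )


def _meets_pathogenic(c: Counter) -> bool:
    sa, vs, s, m, su = c[5], c[4], c[3], c[2], c[1]
    if sa >= 1:
        return True  # pathogenic stand-alone extension
    if vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and su >= 1) or su >= 2):
        return True
    if s >= 2:
        return True
    if s >= 1 and (m >= 3 or (m >= 2 and su >= 2) or (m >= 1 and su >= 4)):
        return True
    return False


def _meets_benign(c: Counter) -> bool:
    return c[5] >= 1 or c[3] >= 2


def _meets_likely_pathogenic(c: Counter) -> bool:
    vs, s, m, su = c[4], c[3], c[2], c[1]
    if vs >= 1 and m >= 1:
        return True
    if s >= 1 and (m >= 1 or su >= 2):
        return True
    if m >= 3 or (m >= 2 and su >= 2) or (m >= 1 and su >= 4):
        return True
    return False


def _meets_likely_benign(c: Counter) -> bool:
    return (c[3] >= 1 and c[1] >= 1) or c[1] >= 2


def combine(
    evidence: Sequence[EvidenceCall],
    config: EngineConfig,
    variant_key: tuple[str, int, str, str] = ("NA", 1, "N", "A"),
    gene: Optional[str] = None,
) -> ClassificationResult:
    """Apply the ordered combining procedure to one evidence set.

    Order: high-threshold conflict check, pathogenic rules (including the
    stand-alone extension), benign rules, low-threshold conflict check,
    likely-pathogenic rules, likely-benign rules, else Uncertain.
    """
    path_counts = _level_counts(evidence, Polarity.PATHOGENIC)
    benign_counts = _level_counts(evidence, Polarity.BENIGN)
    path_sum = sum(level * n for level, n in path_counts.items())
    benign_sum = sum(level * n for level, n in benign_counts.items())

    def result(category: Category, stage: ConflictStage) -> ClassificationResult:
        return ClassificationResult(
            variant_key=variant_key,
            gene=gene,
            category=category,
            evidence=tuple(evidence),
            conflict_stage=stage,
            pathogenic_score_sum=path_sum,
            benign_score_sum=benign_sum,
        )

    if path_sum >= config.conflict_high and benign_sum >= config.conflict_high:
        return result(Category.UNCERTAIN, ConflictStage.HIGH)
    if _meets_pathogenic(path_counts):
        return result(Category.PATHOGENIC, ConflictStage.NONE)
    if _meets_benign(benign_counts):
        return result(Category.BENIGN, ConflictStage.NONE)
    if path_sum >= config.conflict_low and benign_sum >= config.conflict_low:
        return result(Category.UNCERTAIN, ConflictStage.LOW)
    if _meets_likely_pathogenic(path_counts):
        return result(Category.LIKELY_PATHOGENIC, ConflictStage.NONE)
    if _meets_likely_benign(benign_counts):
        return result(Category.LIKELY_BENIGN, ConflictStage.NONE)
    return result(Category.UNCERTAIN, ConflictStage.NONE)


# ---------------------------------------------------------------------------
# streaming classification
# ---------------------------------------------------------------------------


def classify_variant(
    v: AnnotatedVariant,
    bundle: ReferenceBundle,
    config: EngineConfig,
    external: Sequence[ExternalCall] = (),
) -> ClassificationResult:
    evidence = evaluate_all(v, bundle, config, external)
    return combine(evidence, config, variant_key=v.key, gene=v.gene)


def classify_stream(
    variants: Iterable[AnnotatedVariant],
    bundle: ReferenceBundle,
    config: EngineConfig,
    external_map: Optional[Mapping[tuple[str, int, str, str], Sequence[ExternalCall]]] = None,
) -> Iterator[ClassificationResult]:
    """Order-preserving classification of a variant stream.

    A per-variant failure yields an Uncertain result carrying the error
    instead of aborting the stream.
    """
    external_map = external_map or {}
    for i, v in enumerate(variants, start=1):
        try:
            yield classify_variant(v, bundle, config, external_map.get(v.key, ()))
        except Exception as exc:  # degradation contract: never abort mid-stream
            logger.error("variant %s failed: %s", v.key, exc)
            yield ClassificationResult(
                variant_key=v.key,
                gene=v.gene,
                category=Category.UNCERTAIN,
                evidence=(),
                conflict_stage=ConflictStage.NONE,
                pathogenic_score_sum=0,
                benign_score_sum=0,
                error=str(exc),
            )
        if i % _LOG_EVERY == 0:
            logger.info("classified %d variants", i)


def group_external_calls(
    calls: Iterable[ExternalCall],
) -> dict[tuple[str, int, str, str], list[ExternalCall]]:
    """Group a flat external-call list by variant key, preserving order."""
    grouped: dict[tuple[str, int, str, str], list[ExternalCall]] = {}
    for call in calls:
        grouped.setdefault(call.variant_key, []).append(call)
    return grouped
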
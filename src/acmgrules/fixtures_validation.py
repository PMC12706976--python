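"""Synthetic fixture generation and benchmark metrics.

The generator emits a mutually consistent trio of files — annotated
variants, a reference bundle and a truth TSV — from a scenario table in
which every automated evidence code is triggered at a known strength,
plus combination and conflict scenarios.  Truth labels come from the
scenario table (the expected combining outcome), not from the engine, so
the fixtures detect combining regressions as well as rule regressions.

The metrics functions reproduce the usual benchmark quantities:
one-vs-rest sensitivity/specificity/precision/F1 per category bucket
(P/LP, B/LB, VUS) and per-code concordance at the variant level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotation_io import (
    TruthRecord,
    write_annotated_variants,
    write_truth_tsv,
)
from .core_model import (
    AcmgCode,
    Category,
    ClassificationResult,
    ReviewWeightMap,
    StrengthLevel,
)
from .reference_builders import (
    ClinvarLikeRecord,
    ReferenceBundle,
    build_bp1_gene_list,
    build_clinvar_assertion_index,
    build_gwas_index,
    build_hotspot_domains,
    build_literature_index,
    build_pathogenic_aa_index,
    build_pp2_gene_list,
    build_repeat_coding_intervals,
)
from intervaltree import Interval, IntervalTree


# ---------------------------------------------------------------------------
# scenario table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """One generator scenario: the code(s) it targets, the strength each
    should fire at, and the category the combiner should reach."""

    name: str
    expected: tuple[tuple[AcmgCode, StrengthLevel], ...]
    category: Category


S = StrengthLevel

DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("pvs1", ((AcmgCode.PVS1, S.VERY_STRONG),), Category.UNCERTAIN),
    ScenarioSpec("pvs1_splice", ((AcmgCode.PVS1, S.MODERATE),), Category.UNCERTAIN),
    ScenarioSpec("ps1", ((AcmgCode.PS1, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("pm5", ((AcmgCode.PM5, S.MODERATE),), Category.UNCERTAIN),
    ScenarioSpec("ps3", ((AcmgCode.PS3, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("ps3_protein", ((AcmgCode.PS3, S.SUPPORTING),), Category.UNCERTAIN),
    ScenarioSpec("ps4_gwas", ((AcmgCode.PS4, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("ps4_topmed", ((AcmgCode.PS4, S.SUPPORTING),), Category.UNCERTAIN),
    ScenarioSpec("pm1", ((AcmgCode.PM1, S.MODERATE),), Category.UNCERTAIN),
    ScenarioSpec("pm1_strong", ((AcmgCode.PM1, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("pm2", ((AcmgCode.PM2, S.MODERATE),), Category.UNCERTAIN),
    ScenarioSpec("pm4", ((AcmgCode.PM4, S.MODERATE),), Category.UNCERTAIN),
    ScenarioSpec("pp2", ((AcmgCode.PP2, S.MODERATE),), Category.UNCERTAIN),
    ScenarioSpec("pp3", ((AcmgCode.PP3, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("pp5", ((AcmgCode.PP5, S.STAND_ALONE),), Category.PATHOGENIC),
    ScenarioSpec("ba1", ((AcmgCode.BA1, S.STAND_ALONE),), Category.BENIGN),
    ScenarioSpec("bs1", ((AcmgCode.BS1, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("bs1_supporting", ((AcmgCode.BS1, S.SUPPORTING),), Category.UNCERTAIN),
    ScenarioSpec("bs2", ((AcmgCode.BS2, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("bp1", ((AcmgCode.BP1, S.SUPPORTING),), Category.UNCERTAIN),
    ScenarioSpec("bp3", ((AcmgCode.BP3, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("bp4", ((AcmgCode.BP4, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec("bp6", ((AcmgCode.BP6, S.STAND_ALONE),), Category.BENIGN),
    ScenarioSpec("bp7", ((AcmgCode.BP7, S.STRONG),), Category.UNCERTAIN),
    ScenarioSpec(
        "combo_lp",
        ((AcmgCode.PVS1, S.VERY_STRONG), (AcmgCode.PM2, S.MODERATE)),
        Category.LIKELY_PATHOGENIC,
    ),
    ScenarioSpec(
        "combo_p",
        ((AcmgCode.PVS1, S.VERY_STRONG), (AcmgCode.PP5, S.STRONG)),
        Category.PATHOGENIC,
    ),
    ScenarioSpec(
        "conflict_high",
        ((AcmgCode.PVS1, S.VERY_STRONG), (AcmgCode.BA1, S.STAND_ALONE)),
        Category.UNCERTAIN,
    ),
    ScenarioSpec(
        "conflict_low",
        ((AcmgCode.PM1, S.STRONG), (AcmgCode.BS1, S.STRONG)),
        Category.UNCERTAIN,
    ),
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_per_scenario: int = 1
    scenarios: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIOS

    def __post_init__(self) -> None:
        if self.n_per_scenario < 1:
            raise ValueError("n_per_scenario must be >= 1")
        targeted = {code for s in self.scenarios for code, _ in s.expected}
        # every automated code must be exercised by at least one scenario
        missing = {c.value for c in AcmgCode if c.automated} - {c.value for c in targeted}
        if missing:
            raise ValueError(f"scenarios never trigger: {sorted(missing)}")


@dataclass(frozen=True)
class FixturePaths:
    variants_json: Path
    bundle_dir: Path
    truth_tsv: Path


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

_CHROM = "7"
_SCENARIO_STRIDE = 1_000_000
_REPLICATE_STRIDE = 1_000

# review statuses by weight, used when seeding ClinVar-like records
_RS_W5 = "reviewed by expert panel"
_RS_W3 = "criteria provided, multiple submitters, no conflicts"
_RS_W2 = "criteria provided, single submitter"


class _Collector:
    """Accumulates the raw tables the builders consume."""

    def __init__(self) -> None:
        self.variants: list[dict] = []
        self.truth: list[TruthRecord] = []
        self.clinvar: list[ClinvarLikeRecord] = []
        self.domains: list[tuple[str, str, int, int]] = []
        self.repeats: list[tuple[str, int, int]] = []
        self.coding: list[tuple[str, int, int]] = []
        self.gwas: list[dict] = []
        self.literature: list[dict] = []
        self.constraint: dict[str, tuple[Optional[float], Optional[float]]] = {}


def _variant(chrom: str, pos: int, ref: str, alt: str, gene: str, **extra) -> dict:
    rec = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gene": gene}
    rec.update(extra)
    return rec


def _two_tx(consequence: str) -> list[dict]:
    return [
        {"transcript_id": "TX1", "consequences": [consequence], "is_canonical": True},
        {"transcript_id": "TX2", "consequences": [consequence]},
    ]


def _hotspot_records(
    gene: str, chrom: str, base: int, n_path: int, n_benign: int, n_vus: int
) -> list[ClinvarLikeRecord]:
    sigs = ["P"] * n_path + ["B"] * n_benign + ["VUS"] * n_vus
    return [
        ClinvarLikeRecord(
            variant_key=(chrom, base + 2 * k, "A", "G"),
            gene=gene,
            significance=sig,
            review_status=_RS_W2,
            consequences=frozenset({"missense variant"}),
            clinvar_id=f"CV_{gene}_{k}",
        )
        for k, sig in enumerate(sigs)
    ]


def _build_scenario(
    scn: ScenarioSpec, idx: int, n: int, rng: np.random.Generator, col: _Collector
) -> None:
    base = _SCENARIO_STRIDE * (idx + 1)
    gene = f"G{scn.name.upper()}"
    name = scn.name

    # per-gene constraint.  Most scenarios sit in a mid-constraint gene
    # (LOEUF 0.8, bin 2); LoF scenarios use a constrained gene (LOEUF 0.3,
    # bin 0).  mis_oe 0.5 keeps a gene out of the PP2 list when its
    # ClinVar-like records would otherwise qualify it.
    lof_scenario = name in ("pvs1", "pvs1_splice", "combo_lp", "combo_p", "conflict_high")
    loeuf = 0.3 if lof_scenario else 0.8
    if name == "pp2":
        col.constraint[gene] = (loeuf, 0.08)
    elif name in ("pm1", "pm1_strong", "conflict_low"):
        col.constraint[gene] = (loeuf, 0.5)
    else:
        col.constraint[gene] = (loeuf, None)

    # neutral AF band: between the PM2 supporting and BS1 supporting
    # cutoffs of the gene's bin, so no frequency code fires by accident
    def neutral_af() -> float:
        if lof_scenario:
            return float(rng.uniform(1e-5, 4e-4))  # bin 0
        return float(rng.uniform(1e-4, 1e-3))  # bin 2

    # scenario-level reference data (shared by all replicates)
    span = (base - 10, base + n * _REPLICATE_STRIDE + 10)
    if name in ("pm1", "pm1_strong", "conflict_low"):
        comp = (20, 3, 2) if name == "pm1" else (19, 1, 0)
        col.clinvar.extend(_hotspot_records(gene, _CHROM, base + 1, *comp))
        col.domains.append((f"DOM_{gene}", _CHROM, span[0], span[1]))
    if name == "bp3":
        col.repeats.append((_CHROM, span[0], span[1]))
        col.coding.append((_CHROM, span[0] - 5, span[1] + 5))
    if name == "bp1":
        sigs = [("P", "stop gained")] * 7 + [
            ("P", "missense variant"), ("B", "stop gained"),
            ("VUS", "missense variant"), ("VUS", "stop gained"),
        ]
        col.clinvar.extend(
            ClinvarLikeRecord(
                variant_key=(_CHROM, base + 3 * k + 1, "C", "T"),
                gene=gene,
                significance=sig,
                review_status=_RS_W2,
                consequences=frozenset({cons}),
                clinvar_id=f"CV_{gene}_{k}",
            )
            for k, (sig, cons) in enumerate(sigs)
        )

    for j in range(n):
        pos = base + j * _REPLICATE_STRIDE
        key = (_CHROM, pos)
        v: Optional[dict] = None

        if name in ("pvs1", "combo_lp", "combo_p", "conflict_high"):
            freq: dict = {}
            if name == "combo_lp":
                pass  # absent from every population resource -> PM2 moderate
            elif name == "conflict_high":
                freq = {"gnomad_af": float(rng.uniform(0.05, 0.5))}
            else:
                freq = {"gnomad_af": neutral_af()}
            extra: dict = {
                "consequences": ["stop gained"],
                "transcript_consequences": _two_tx("stop gained"),
                "freq": freq,
            }
            if name == "combo_p":
                extra["clinvar_top"] = {
                    "significance": "P", "review_status": _RS_W3,
                    "clinvar_id": f"CV_{gene}_top",
                }
            v = _variant(_CHROM, pos, "C", "T", gene, **extra)

        elif name == "pvs1_splice":
            v = _variant(
                _CHROM, pos, "G", "A", gene,
                consequences=["splice donor variant"],
                transcript_consequences=_two_tx("splice donor variant"),
                freq={"gnomad_af": neutral_af()},
                scores={"absplice": float(rng.uniform(0.011, 0.049))},
            )

        elif name in ("ps1", "pm5"):
            indexed_alt = "H"
            var_alt = "H" if name == "ps1" else "L"
            status = _RS_W3 if name == "ps1" else _RS_W5
            col.clinvar.append(
                ClinvarLikeRecord(
                    variant_key=(_CHROM, pos + 7, "G", "C"),  # different nucleotide
                    gene=gene,
                    significance="P",
                    review_status=status,
                    consequences=frozenset({"missense variant"}),
                    amino_acid_change=_aa(175 + j, "R", indexed_alt),
                    clinvar_id=f"CV_{gene}_{j}",
                )
            )
            v = _variant(
                _CHROM, pos, "G", "T", gene,
                consequences=["missense variant"],
                amino_acid_change={"position": 175 + j, "ref_aa": "R", "alt_aa": var_alt},
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "ps3":
            for p in range(6):
                col.literature.append({
                    "type": "genomic", "chrom": _CHROM, "pos": str(pos),
                    "ref": "A", "alt": "C", "gene": "", "protein_change": "",
                    "pmid": f"{30000000 + idx * 1000 + j * 10 + p}",
                })
            v = _variant(
                _CHROM, pos, "A", "C", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "ps3_protein":
            col.literature.append({
                "type": "protein", "chrom": "", "pos": "", "ref": "", "alt": "",
                "gene": gene, "protein_change": f"G{12 + j}D",
                "pmid": f"{31000000 + j}",
            })
            v = _variant(
                _CHROM, pos, "G", "A", gene,
                consequences=["missense variant"],
                amino_acid_change={"position": 12 + j, "ref_aa": "G", "alt_aa": "D"},
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "ps4_gwas":
            col.gwas.append({
                "chrom": _CHROM, "pos": str(pos),
                "or": f"{float(rng.uniform(3.5, 8.0)):.3f}",
                "pvalue": "1e-12",
            })
            v = _variant(
                _CHROM, pos, "T", "C", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "ps4_topmed":
            v = _variant(
                _CHROM, pos, "T", "G", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af(), "topmed_ac": int(rng.integers(0, 5))},
            )

        elif name in ("pm1", "pm1_strong"):
            v = _variant(
                _CHROM, pos, "A", "T", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "pm2":
            v = _variant(
                _CHROM, pos, "C", "G", gene,
                consequences=["missense variant"],
            )

        elif name == "pm4":
            ref = "A" + "CGT" * 4  # 12-nt in-frame deletion -> 4 residues
            v = _variant(
                _CHROM, pos, ref, "A", gene,
                consequences=["inframe deletion"],
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "pp2":
            v = _variant(
                _CHROM, pos, "G", "C", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "pp3":
            v = _variant(
                _CHROM, pos, "A", "G", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
                scores={
                    "revel": float(rng.uniform(0.78, 0.93)),
                    "dann": float(rng.uniform(0.9991, 0.9999)),
                },
            )

        elif name == "pp5":
            v = _variant(
                _CHROM, pos, "C", "A", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
                clinvar_top={
                    "significance": "P", "review_status": _RS_W5,
                    "clinvar_id": f"CV_{gene}_{j}",
                },
            )

        elif name == "ba1":
            v = _variant(
                _CHROM, pos, "G", "T", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": float(rng.uniform(0.05, 0.5))},
            )

        elif name == "bs1":
            v = _variant(
                _CHROM, pos, "A", "C", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": float(rng.uniform(0.0105, 0.0195))},
            )

        elif name == "bs1_supporting":
            v = _variant(
                _CHROM, pos, "A", "G", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": float(rng.uniform(0.0021, 0.0095))},
            )

        elif name == "bs2":
            v = _variant(
                _CHROM, pos, "T", "A", gene,
                consequences=["missense variant"],
                gene_disease=[{"disease": "synthetic recessive disorder",
                               "inheritance": "AR"}],
                freq={"gnomad_af": neutral_af(),
                      "gnomad_hom_count": int(rng.integers(4, 10))},
            )

        elif name == "bp1":
            v = _variant(
                _CHROM, pos, "C", "T", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "bp3":
            ref = "T" + "AGC" * 3  # 9-nt in-frame deletion inside a repeat
            v = _variant(
                _CHROM, pos, ref, "T", gene,
                consequences=["inframe deletion"],
                freq={"gnomad_af": neutral_af()},
            )

        elif name == "bp4":
            v = _variant(
                _CHROM, pos, "G", "A", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
                scores={
                    "revel": float(rng.uniform(0.02, 0.18)),
                    "dann": float(rng.uniform(0.02, 0.09)),
                },
            )

        elif name == "bp6":
            v = _variant(
                _CHROM, pos, "A", "T", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": neutral_af()},
                clinvar_top={
                    "significance": "B", "review_status": "practice guidelines",
                    "clinvar_id": f"CV_{gene}_{j}",
                },
            )

        elif name == "bp7":
            v = _variant(
                _CHROM, pos, "C", "T", gene,
                consequences=["synonymous variant"],
                freq={"gnomad_af": neutral_af()},
                scores={
                    "phylop": float(rng.uniform(0.0, 0.2)),
                    "absplice": float(rng.uniform(0.002, 0.009)),
                },
            )

        elif name == "conflict_low":
            v = _variant(
                _CHROM, pos, "G", "A", gene,
                consequences=["missense variant"],
                freq={"gnomad_af": float(rng.uniform(0.0105, 0.0195))},
            )

        if v is None:
            raise ValueError(f"unknown scenario {name!r}")

        col.variants.append(v)
        col.truth.append(
            TruthRecord(
                variant_key=(v["chrom"], v["pos"], v["ref"], v["alt"]),
                expert_category=scn.category,
                expert_codes=frozenset(scn.expected),
            )
        )


def _aa(position: int, ref_aa: str, alt_aa: str):
    from .core_model import AminoAcidChange

    return AminoAcidChange(position=position, ref_aa=ref_aa, alt_aa=alt_aa)


def generate_fixtures(spec: FixtureSpec, out_dir) -> FixturePaths:
    """Write the annotated-variant JSON, reference bundle directory and
    truth TSV for a fixture spec; byte-identical for identical (spec, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    col = _Collector()

    for idx, scn in enumerate(spec.scenarios):
        _build_scenario(scn, idx, spec.n_per_scenario, rng, col)

    review_map = ReviewWeightMap()
    bundle = ReferenceBundle()
    bundle.pathogenic_aa_index = build_pathogenic_aa_index(col.clinvar, review_map)
    bundle.clinvar_assertion_index = build_clinvar_assertion_index(col.clinvar, review_map)
    bundle.bp1_genes = build_bp1_gene_list(col.clinvar)
    bundle.pp2_genes = build_pp2_gene_list(col.clinvar, col.constraint)
    for d in build_hotspot_domains(col.clinvar, col.domains, review_map):
        bundle.hotspot_domains.setdefault(d.chrom, IntervalTree()).add(
            Interval(d.start, d.end, d)
        )
    bundle.repeat_coding = build_repeat_coding_intervals(col.repeats, col.coding)
    bundle.gwas_index = build_gwas_index(col.gwas)
    bundle.literature_genomic, bundle.literature_protein = build_literature_index(
        col.literature
    )
    bundle.gene_constraint = dict(col.constraint)
    # a distant final coding exon, so the exclusion-window lookup is exercised
    bundle.final_coding_exons = {"TX_FAR": ("20", 5_000_000, 5_000_300)}

    paths = FixturePaths(
        variants_json=out / "variants.json",
        bundle_dir=out / "bundle",
        truth_tsv=out / "truth.tsv",
    )
    write_annotated_variants(col.variants, paths.variants_json)
    bundle.save(paths.bundle_dir)
    write_truth_tsv(col.truth, paths.truth_tsv)
    return paths


# ---------------------------------------------------------------------------
# benchmark metrics
# ---------------------------------------------------------------------------


def _pct(numerator: int, denominator: int) -> Optional[float]:
    """Percentage to 2 dp, half-up; undefined denominators give None."""
    if denominator == 0:
        return None
    value = Decimal(numerator) / Decimal(denominator) * 100
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CategoryMetrics:
    bucket: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> Optional[float]:
        return _pct(self.tp, self.tp + self.fp)

    @property
    def f1(self) -> Optional[float]:
        if self.tp + self.fp == 0 or self.tp + self.fn == 0:
            return None
        p = self.tp / (self.tp + self.fp)
        s = self.tp / (self.tp + self.fn)
        if p + s == 0:
            return None
        value = Decimal(str(2 * p * s / (p + s) * 100))
        return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


BUCKETS = ("P/LP", "B/LB", "VUS")


def _join(
    results: Sequence[ClassificationResult], truth: Sequence[TruthRecord]
) -> list[tuple[ClassificationResult, TruthRecord]]:
    res_by_key: dict = {}
    for r in results:
        if r.variant_key in res_by_key:
            raise ValueError(f"duplicate result key {r.variant_key}")
        res_by_key[r.variant_key] = r
    truth_by_key: dict = {}
    for t in truth:
        if t.variant_key in truth_by_key:
            raise ValueError(f"duplicate truth key {t.variant_key}")
        truth_by_key[t.variant_key] = t
    joined = [
        (res_by_key[k], truth_by_key[k]) for k in res_by_key if k in truth_by_key
    ]
    if not joined:
        raise ValueError("no variant keys shared between results and truth")
    unmatched = (set(res_by_key) | set(truth_by_key)) - {
        r.variant_key for r, _ in joined
    }
    if unmatched:
        import logging

        logging.getLogger("acmgrules").warning(
            "%d variant keys present on only one side of the join", len(unmatched)
        )
    return joined


def category_metrics(
    results: Sequence[ClassificationResult], truth: Sequence[TruthRecord]
) -> dict[str, CategoryMetrics]:
    """One-vs-rest confusion per collapsed category bucket."""
    joined = _join(results, truth)
    metrics: dict[str, CategoryMetrics] = {}
    for bucket in BUCKETS:
        tp = fp = tn = fn = 0
        for result, record in joined:
            predicted = result.category.bucket == bucket
            actual = record.expert_category.bucket == bucket
            if predicted and actual:
                tp += 1
            elif predicted and not actual:
                fp += 1
            elif actual:
                fn += 1
            else:
                tn += 1
        metrics[bucket] = CategoryMetrics(bucket=bucket, tp=tp, fp=fp, tn=tn, fn=fn)
    return metrics


@dataclass(frozen=True)
class CodeConcordance:
    code: AcmgCode
    predicted_count: int
    truth_count: int
    tp: int
    fp: int
    tn: int
    fn: int
    strength_matches: int  # among tp where the truth carries a strength
    strength_compared: int

    @property
    def sensitivity(self) -> Optional[float]:
        return _pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return _pct(self.tn, self.tn + self.fp)

    @property
    def f1(self) -> Optional[float]:
        if self.tp + self.fp == 0 or self.tp + self.fn == 0:
            return None
        p = self.tp / (self.tp + self.fp)
        s = self.tp / (self.tp + self.fn)
        if p + s == 0:
            return None
        value = Decimal(str(2 * p * s / (p + s) * 100))
        return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def code_concordance(
    results: Sequence[ClassificationResult], truth: Sequence[TruthRecord]
) -> list[CodeConcordance]:
    """Per-code variant-level agreement.

    A code counts as applied on a variant regardless of strength;
    strength agreement is tallied separately over the true positives
    whose truth record states a strength.
    """
    joined = _join(results, truth)
    rows: list[CodeConcordance] = []
    for code in sorted(AcmgCode, key=lambda c: c.value):
        tp = fp = tn = fn = 0
        s_match = s_total = 0
        pred_count = truth_count = 0
        for result, record in joined:
            pred = {e.code: e.strength for e in result.evidence}
            actual = {c: s for c, s in record.expert_codes}
            if code in pred:
                pred_count += 1
            if code in actual:
                truth_count += 1
            if code in pred and code in actual:
                tp += 1
                if actual[code] is not None:
                    s_total += 1
                    if actual[code] == pred[code]:
                        s_match += 1
            elif code in pred:
                fp += 1
            elif code in actual:
                fn += 1
            else:
                tn += 1
        rows.append(
            CodeConcordance(
                code=code, predicted_count=pred_count, truth_count=truth_count,
                tp=tp, fp=fp, tn=tn, fn=fn,
                strength_matches=s_match, strength_compared=s_total,
            )
        )
    return rows


def write_metrics_tsv(
    categories: Mapping[str, CategoryMetrics],
    codes: Iterable[CodeConcordance],
    path,
) -> None:
    """Metrics TSV: one row per category bucket, then one per code."""

    def fmt(x: Optional[float]) -> str:
        return "" if x is None else f"{x:.2f}"

    with open(path, "w") as fh:
        fh.write("row_type\tname\ttp\tfp\ttn\tfn\tsensitivity\tspecificity"
                 "\tprecision\tf1\tstrength_matches\tstrength_compared\n")
        for bucket in BUCKETS:
            m = categories[bucket]
            fh.write(
                f"category\t{bucket}\t{m.tp}\t{m.fp}\t{m.tn}\t{m.fn}"
                f"\t{fmt(m.sensitivity)}\t{fmt(m.specificity)}"
                f"\t{fmt(m.precision)}\t{fmt(m.f1)}\t\t\n"
            )
        for row in codes:
            fh.write(
                f"code\t{row.code.value}\t{row.tp}\t{row.fp}\t{row.tn}\t{row.fn}"
                f"\t{fmt(row.sensitivity)}\t{fmt(row.specificity)}\t"
                f"\t{fmt(row.f1)}\t{row.strength_matches}\t{row.strength_compared}\n"
            )
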
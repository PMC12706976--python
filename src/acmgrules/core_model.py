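"""Domain types and runtime configuration for the ACMG/AMP rule engine.

The engine classifies germline variants into the five ACMG/AMP 2015
categories (pathogenic, likely pathogenic, uncertain significance, likely
benign, benign) by applying evidence codes at dynamically weighted
strengths.  Every strength is an integer on a single ladder::

    1 = supporting, 2 = moderate, 3 = strong, 4 = very strong, 5 = stand-alone

and 0 means "not applied".  All numeric cutoffs used by the individual
criteria live in :class:`EngineConfig`, which serialises to a flat,
namespaced key/value JSON file so that no threshold is hard-coded inside
rule logic.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence

logger = logging.getLogger("acmgrules")

# ---------------------------------------------------------------------------
# Strength ladder
# ---------------------------------------------------------------------------


class StrengthLevel(enum.IntEnum):
    """Evidence strength on the 0-5 integer ladder."""

    NOT_APPLIED = 0
    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5

    @property
    def label(self) -> str:
        """lower_snake display name used in output files."""
        return _STRENGTH_LABELS[int(self)]


_STRENGTH_LABELS = {
    0: "not_applied",
    1: "supporting",
    2: "moderate",
    3: "strong",
    4: "very_strong",
    5: "stand_alone",
}

_LABEL_TO_STRENGTH = {v: StrengthLevel(k) for k, v in _STRENGTH_LABELS.items()}


def strength_from_label(label: str) -> StrengthLevel:
    try:
        return _LABEL_TO_STRENGTH[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown strength name: {label!r}") from None


def upweight(level: int) -> StrengthLevel:
    """Move one step up the ladder, capped at stand-alone."""
    return StrengthLevel(min(int(level) + 1, 5))


def downweight(level: int) -> StrengthLevel:
    """Move one step down the ladder; applied codes never drop below supporting."""
    return StrengthLevel(max(int(level) - 1, 1))


# ---------------------------------------------------------------------------
# ACMG codes
# ---------------------------------------------------------------------------


class Polarity(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class AcmgCode(str, enum.Enum):
    """The 28 ACMG/AMP 2015 evidence codes."""

    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"
    BA1 = "BA1"
    BS1 = "BS1"
    BS2 = "BS2"
    BS3 = "BS3"
    BS4 = "BS4"
    BP1 = "BP1"
    BP2 = "BP2"
    BP3 = "BP3"
    BP4 = "BP4"
    BP5 = "BP5"
    BP6 = "BP6"
    BP7 = "BP7"

    @property
    def polarity(self) -> Polarity:
        return Polarity.BENIGN if self.value.startswith("B") else Polarity.PATHOGENIC

    @property
    def automated(self) -> bool:
        return self in AUTOMATED_CODES


#: Codes the engine evaluates itself.  The remaining nine require patient /
#: family information (de novo status, segregation, phenotype specificity,
#: functional assays run in-house) and enter only through the external call
#: file.
AUTOMATED_CODES = frozenset(
    AcmgCode(c)
    for c in (
        "PVS1", "PS1", "PS3", "PS4",
        "PM1", "PM2", "PM4", "PM5",
        "PP2", "PP3", "PP5",
        "BA1", "BS1", "BS2",
        "BP1", "BP3", "BP4", "BP6", "BP7",
    )
)

MANUAL_CODES = frozenset(set(AcmgCode) - AUTOMATED_CODES)


# ---------------------------------------------------------------------------
# Variant annotations
# ---------------------------------------------------------------------------


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"
    MNV = "MNV"


def infer_variant_type(ref: str, alt: str) -> VariantType:
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if len(ref) == len(alt):
        return VariantType.MNV
    if len(ref) < len(alt) and alt.startswith(ref):
        return VariantType.INSERTION
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantType.DELETION
    return VariantType.DELINS


@dataclass(frozen=True)
class PopulationFrequencies:
    """Allele frequencies and counts from population resources.

    ``None`` means the variant was not observed in (or not annotated
    against) that resource — which is itself evidence for PM2.
    """

    gnomad_af: Optional[float] = None
    gnomad_ac: Optional[int] = None
    gnomad_hom_count: Optional[int] = None
    gnomad_controls_ac: Optional[int] = None
    thousand_genomes_af: Optional[float] = None
    thousand_genomes_ac: Optional[int] = None
    topmed_af: Optional[float] = None
    topmed_ac: Optional[int] = None
    topmed_hom_count: Optional[int] = None
    hemizygous_male_count: Optional[int] = None
    homozygous_female_count: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("gnomad_af", "thousand_genomes_af", "topmed_af"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "gnomad_ac", "gnomad_hom_count", "gnomad_controls_ac",
            "thousand_genomes_ac", "topmed_ac", "topmed_hom_count",
            "hemizygous_male_count", "homozygous_female_count",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def max_af(self) -> Optional[float]:
        """Largest non-null of the gnomAD / 1000 Genomes AFs (None if both null)."""
        values = [v for v in (self.gnomad_af, self.thousand_genomes_af) if v is not None]
        return max(values) if values else None


@dataclass(frozen=True)
class InSilicoScores:
    """Per-tool computational predictor scores (higher = more deleterious)."""

    phylop: Optional[float] = None
    gerp: Optional[float] = None
    revel: Optional[float] = None
    dann: Optional[float] = None
    absplice: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("revel", "dann", "absplice"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def as_dict(self) -> dict[str, Optional[float]]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AminoAcidChange:
    """Protein-level substitution: residue position plus reference/alternate AA."""

    position: int
    ref_aa: str
    alt_aa: str

    def __str__(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class TranscriptConsequence:
    transcript_id: str
    consequences: frozenset[str]
    amino_acid_change: Optional[AminoAcidChange] = None
    is_canonical: bool = False


@dataclass(frozen=True)
class ClinVarEntry:
    significance: str  # one of P, LP, B, LB, VUS, conflicting
    review_status: str
    clinvar_id: str


class InheritanceMode(str, enum.Enum):
    AR = "AR"
    AD = "AD"
    XL = "XL"
    OTHER = "other"


@dataclass(frozen=True)
class GeneDisease:
    disease: str
    inheritance: InheritanceMode


def normalize_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class AnnotatedVariant:
    """One variant with every annotation the criteria consume."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: Optional[VariantType] = None
    gene: Optional[str] = None
    consequences: frozenset[str] = frozenset()
    transcript_consequences: tuple[TranscriptConsequence, ...] = ()
    amino_acid_change: Optional[AminoAcidChange] = None
    clinvar_top: Optional[ClinVarEntry] = None
    pubmed_ids: tuple[str, ...] = ()
    gene_disease: tuple[GeneDisease, ...] = ()
    dbsnp_ids: tuple[str, ...] = ()
    freq: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    scores: InSilicoScores = field(default_factory=InSilicoScores)

    def __post_init__(self) -> None:
        if not self.chrom or not self.ref or not self.alt:
            raise ValueError("chrom, ref and alt must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.variant_type is None:
            object.__setattr__(self, "variant_type", infer_variant_type(self.ref, self.alt))

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact-match variant key (chr prefix stripped, no indel normalisation)."""
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_inframe(self) -> bool:
        return self.indel_length % 3 == 0


# ---------------------------------------------------------------------------
# Evidence calls and classification results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvidenceCall:
    """One ACMG code applied at an effective strength with a rationale."""

    code: AcmgCode
    strength: StrengthLevel
    rationale: str
    source: str = "auto"  # auto | manual
    details: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if int(self.strength) < 1:
            raise ValueError("an applied evidence call must have strength >= 1")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")
        if self.source not in ("auto", "manual"):
            raise ValueError(f"source must be auto or manual, got {self.source!r}")


class Category(str, enum.Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    UNCERTAIN = "Uncertain"
    LIKELY_BENIGN = "LikelyBenign"
    BENIGN = "Benign"

    @property
    def display(self) -> str:
        return _CATEGORY_DISPLAY[self]

    @property
    def bucket(self) -> str:
        """Collapse to the benchmark buckets P/LP, B/LB, VUS."""
        return _CATEGORY_BUCKET[self]


_CATEGORY_DISPLAY = {
    Category.PATHOGENIC: "Pathogenic",
    Category.LIKELY_PATHOGENIC: "Likely pathogenic",
    Category.UNCERTAIN: "Uncertain significance",
    Category.LIKELY_BENIGN: "Likely benign",
    Category.BENIGN: "Benign",
}

_CATEGORY_BUCKET = {
    Category.PATHOGENIC: "P/LP",
    Category.LIKELY_PATHOGENIC: "P/LP",
    Category.UNCERTAIN: "VUS",
    Category.LIKELY_BENIGN: "B/LB",
    Category.BENIGN: "B/LB",
}

#: truth-set tokens -> category
CATEGORY_TOKENS = {
    "p": Category.PATHOGENIC,
    "pathogenic": Category.PATHOGENIC,
    "lp": Category.LIKELY_PATHOGENIC,
    "likely pathogenic": Category.LIKELY_PATHOGENIC,
    "likelypathogenic": Category.LIKELY_PATHOGENIC,
    "likely_pathogenic": Category.LIKELY_PATHOGENIC,
    "vus": Category.UNCERTAIN,
    "uncertain": Category.UNCERTAIN,
    "uncertain significance": Category.UNCERTAIN,
    "lb": Category.LIKELY_BENIGN,
    "likely benign": Category.LIKELY_BENIGN,
    "likelybenign": Category.LIKELY_BENIGN,
    "likely_benign": Category.LIKELY_BENIGN,
    "b": Category.BENIGN,
    "benign": Category.BENIGN,
}


class ConflictStage(str, enum.Enum):
    NONE = "none"
    HIGH = "high"
    LOW = "low"


@dataclass(frozen=True)
class ClassificationResult:
    variant_key: tuple[str, int, str, str]
    gene: Optional[str]
    category: Category
    evidence: tuple[EvidenceCall, ...]
    conflict_stage: ConflictStage
    pathogenic_score_sum: int
    benign_score_sum: int
    #: set when a per-variant failure degraded the result to Uncertain
    error: Optional[str] = None


# ---------------------------------------------------------------------------
# ClinVar review-status weights
# ---------------------------------------------------------------------------


DEFAULT_REVIEW_WEIGHTS: dict[str, int] = {
    "practice guidelines": 5,
    "reviewed by expert panel": 5,
    "criteria provided, multiple submitters, no conflicts": 3,
    "criteria provided, single submitter": 2,
    "criteria provided, conflicting interpretations": 1,
    "no assertion criteria provided": 0,
}


@dataclass(frozen=True)
class ReviewWeightMap:
    """ClinVar review status -> evidence strength; statuses weighted 0 are
    excluded from all evidence."""

    weights: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REVIEW_WEIGHTS)
    )

    def weight(self, status: Optional[str]) -> StrengthLevel:
        if status is None:
            return StrengthLevel.NOT_APPLIED
        key = status.strip().lower()
        if key not in self.weights:
            logger.debug("unknown ClinVar review status %r -> weight 0", status)
            return StrengthLevel.NOT_APPLIED
        return StrengthLevel(self.weights[key])


def strength_from_review_status(status: str, review_map: ReviewWeightMap) -> StrengthLevel:
    """Map a ClinVar review-status string to its evidence strength (unknown -> 0)."""
    return review_map.weight(status)


# ---------------------------------------------------------------------------
# LOEUF-stratified population frequency cutoffs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoeufBinTable:
    """Five LOEUF constraint bins, each carrying allele-frequency cutoffs.

    Bin 0 holds the most LoF-constrained genes (lowest LOEUF) and gets the
    strictest cutoffs; cutoffs relax monotonically towards bin 4.  The last
    upper bound is ``None`` (unbounded).
    """

    upper_bounds: tuple[Optional[float], ...] = (0.35, 0.6, 1.0, 1.5, None)
    pm2_standard: tuple[float, ...] = (1e-6, 2e-6, 5e-6, 1e-5, 2e-5)
    pm2_supporting: tuple[float, ...] = (5e-6, 1e-5, 2.5e-5, 5e-5, 1e-4)
    bs1_supporting: tuple[float, ...] = (5e-4, 1e-3, 2e-3, 5e-3, 1e-2)
    bs1_standard: tuple[float, ...] = (2.5e-3, 5e-3, 1e-2, 2.5e-2, 5e-2)
    ba1: tuple[float, ...] = (5e-3, 1e-2, 2e-2, 5e-2, 5e-2)
    bs2_recessive_hom: tuple[int, ...] = (2, 2, 2, 2, 2)
    bs2_dominant_allele: tuple[int, ...] = (5, 5, 5, 5, 5)
    bs2_x_linked: tuple[int, ...] = (2, 2, 2, 2, 2)
    bs2_af: tuple[float, ...] = (0.05, 0.05, 0.05, 0.05, 0.05)
    default_bin: int = 2

    def __post_init__(self) -> None:
        n = len(self.upper_bounds)
        for name in (
            "pm2_standard", "pm2_supporting", "bs1_supporting", "bs1_standard",
            "ba1", "bs2_recessive_hom", "bs2_dominant_allele", "bs2_x_linked",
            "bs2_af",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have {n} entries")
        if not (0 <= self.default_bin < n):
            raise ValueError("default_bin out of range")
        for i in range(n):
            if not (
                self.pm2_standard[i] < self.pm2_supporting[i]
                <= self.bs1_supporting[i] < self.bs1_standard[i] <= self.ba1[i]
            ):
                raise ValueError(f"cutoff ordering violated in bin {i}")
        for name in ("pm2_standard", "pm2_supporting", "bs1_supporting", "bs1_standard", "ba1"):
            vals = getattr(self, name)
            if any(vals[i] > vals[i + 1] for i in range(n - 1)):
                raise ValueError(f"{name} must be non-decreasing across bins")

    def bin_index(self, loeuf: Optional[float]) -> int:
        """Index of the first bin whose upper bound >= loeuf (inclusive edges);
        genes without a LOEUF score fall in the configured default bin."""
        if loeuf is None:
            return self.default_bin
        for i, bound in enumerate(self.upper_bounds):
            if bound is None or loeuf <= bound:
                return i
        return len(self.upper_bounds) - 1


def loeuf_bin(loeuf: Optional[float], table: LoeufBinTable) -> int:
    return table.bin_index(loeuf)


# ---------------------------------------------------------------------------
# In-silico tool cutoff ladders (PP3 / BP4)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToolLadder:
    """Per-tool score thresholds for computational evidence.

    ``pathogenic`` holds thresholds at (supporting, moderate, strong,
    very_strong): a score >= threshold contributes pathogenic evidence at
    that level (None = the tool never reaches that level).  ``benign`` holds
    the mirror thresholds: a score <= threshold contributes benign
    evidence.  All supported tools score higher = more deleterious.
    """

    pathogenic: tuple[Optional[float], Optional[float], Optional[float], Optional[float]]
    benign: tuple[Optional[float], Optional[float], Optional[float], Optional[float]]

    def pathogenic_level(self, score: float) -> StrengthLevel:
        level = 0
        for i, thr in enumerate(self.pathogenic):
            if thr is not None and score >= thr:
                level = i + 1
        return StrengthLevel(level)

    def benign_level(self, score: float) -> StrengthLevel:
        level = 0
        for i, thr in enumerate(self.benign):
            if thr is not None and score <= thr:
                level = i + 1
        return StrengthLevel(level)

    @property
    def strong_benign(self) -> Optional[float]:
        return self.benign[2]

    @property
    def strong_pathogenic(self) -> Optional[float]:
        return self.pathogenic[2]


#: Default calibration ladders.  REVEL follows the ClinGen-recommended
#: interval calibration; PhyloP's pathogenic-supporting bound is the
#: calibrated 7.367; ABSplice tiers follow its authors' high/medium/low
#: cutoffs; DANN and GERP use conservative community defaults.
DEFAULT_TOOL_LADDERS: dict[str, ToolLadder] = {
    "revel": ToolLadder(
        pathogenic=(0.644, 0.773, 0.932, None),
        benign=(0.290, 0.183, 0.016, 0.003),
    ),
    "dann": ToolLadder(
        pathogenic=(0.99, 0.999, None, None),
        benign=(0.3, 0.1, 0.01, None),
    ),
    "phylop": ToolLadder(
        pathogenic=(7.367, 9.741, None, None),
        benign=(-1.04, -3.0, -4.5, None),
    ),
    "gerp": ToolLadder(
        pathogenic=(4.5, None, None, None),
        benign=(-2.0, -4.54, None, None),
    ),
    "absplice": ToolLadder(
        pathogenic=(0.05, 0.2, None, None),
        benign=(0.01, None, None, None),
    ),
}


# ---------------------------------------------------------------------------
# Engine configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EngineConfig:
    """Every numeric threshold the engine consumes, in one flat namespace.

    Engine behaviour is a pure function of (inputs, config); the defaults
    below reproduce the published rule set.
    """

    loeuf_bins: LoeufBinTable = field(default_factory=LoeufBinTable)
    review_weights: ReviewWeightMap = field(default_factory=ReviewWeightMap)
    tool_ladders: Mapping[str, ToolLadder] = field(
        default_factory=lambda: dict(DEFAULT_TOOL_LADDERS)
    )

    # PVS1
    pvs1_loeuf_full_strength: float = 1.0
    pvs1_final_exon_window: int = 50
    pvs1_splice_low_impact: float = 0.2
    pvs1_splice_minimal_impact: float = 0.05

    # PS1 / PM5 strength caps
    ps1_max_strength: int = 3
    pm5_max_strength: int = 2

    # PS3 publication-count tiers
    ps3_moderate_min_pubs: int = 2
    ps3_strong_min_pubs: int = 5

    # PS4 GWAS tiers and TOPMed proxy
    ps4_genome_wide_p: float = 5e-8
    ps4_strong_or: float = 3.0
    ps4_moderate_or: float = 1.5
    ps4_supporting_p: float = 1e-5
    ps4_supporting_or: float = 1.0
    ps4_topmed_max_ac: int = 5
    ps4_topmed_hom_min: int = 3
    ps4_topmed_hom_max: int = 9

    # PM1 domain-composition tiers
    pm1_strong_path_frac: float = 0.90
    pm1_strong_benign_frac: float = 0.10
    pm1_supporting_path_frac: float = 0.75
    pm1_supporting_benign_frac: float = 0.15

    # PM4 indel-length tiers (amino acids)
    pm4_moderate_min_aa: int = 4
    pm4_strong_min_aa: int = 11

    # PP2
    pp2_oe_exclude: float = 0.4
    pp2_oe_moderate: float = 0.10

    # BS2
    bs2_dominant_loeuf_max: float = 0.5

    # BP3 repeat-region indel tiers (nucleotides)
    bp3_min_nt: int = 3
    bp3_strong_max_nt: int = 15
    bp3_supporting_max_nt: int = 60

    # BP7
    bp7_phylop_eligible: float = 7.367
    bp7_absplice_eligible: float = 0.05
    bp7_absplice_strong: float = 0.01
    bp7_phylop_strong: float = 0.21

    # combining / conflict thresholds
    conflict_high: int = 4
    conflict_low: int = 2

    # ------------------------------------------------------------------
    # flat (de)serialisation
    # ------------------------------------------------------------------

    _SCALARS = (
        ("pvs1.loeuf_full_strength", "pvs1_loeuf_full_strength", float),
        ("pvs1.final_exon_window", "pvs1_final_exon_window", int),
        ("pvs1.splice_low_impact", "pvs1_splice_low_impact", float),
        ("pvs1.splice_minimal_impact", "pvs1_splice_minimal_impact", float),
        ("ps1.max_strength", "ps1_max_strength", int),
        ("pm5.max_strength", "pm5_max_strength", int),
        ("ps3.moderate_min_pubs", "ps3_moderate_min_pubs", int),
        ("ps3.strong_min_pubs", "ps3_strong_min_pubs", int),
        ("ps4.genome_wide_p", "ps4_genome_wide_p", float),
        ("ps4.strong_or", "ps4_strong_or", float),
        ("ps4.moderate_or", "ps4_moderate_or", float),
        ("ps4.supporting_p", "ps4_supporting_p", float),
        ("ps4.supporting_or", "ps4_supporting_or", float),
        ("ps4.topmed_max_ac", "ps4_topmed_max_ac", int),
        ("ps4.topmed_hom_min", "ps4_topmed_hom_min", int),
        ("ps4.topmed_hom_max", "ps4_topmed_hom_max", int),
        ("pm1.strong_path_frac", "pm1_strong_path_frac", float),
        ("pm1.strong_benign_frac", "pm1_strong_benign_frac", float),
        ("pm1.supporting_path_frac", "pm1_supporting_path_frac", float),
        ("pm1.supporting_benign_frac", "pm1_supporting_benign_frac", float),
        ("pm4.moderate_min_aa", "pm4_moderate_min_aa", int),
        ("pm4.strong_min_aa", "pm4_strong_min_aa", int),
        ("pp2.oe_exclude", "pp2_oe_exclude", float),
        ("pp2.oe_moderate", "pp2_oe_moderate", float),
        ("bs2.dominant_loeuf_max", "bs2_dominant_loeuf_max", float),
        ("bp3.min_nt", "bp3_min_nt", int),
        ("bp3.strong_max_nt", "bp3_strong_max_nt", int),
        ("bp3.supporting_max_nt", "bp3_supporting_max_nt", int),
        ("bp7.phylop_eligible", "bp7_phylop_eligible", float),
        ("bp7.absplice_eligible", "bp7_absplice_eligible", float),
        ("bp7.absplice_strong", "bp7_absplice_strong", float),
        ("bp7.phylop_strong", "bp7_phylop_strong", float),
        ("combine.conflict_high", "conflict_high", int),
        ("combine.conflict_low", "conflict_low", int),
    )

    _BIN_ARRAYS = (
        ("loeuf.upper_bounds", "upper_bounds"),
        ("pm2.standard", "pm2_standard"),
        ("pm2.supporting", "pm2_supporting"),
        ("bs1.supporting", "bs1_supporting"),
        ("bs1.standard", "bs1_standard"),
        ("ba1.cutoff", "ba1"),
        ("bs2.recessive_hom", "bs2_recessive_hom"),
        ("bs2.dominant_allele", "bs2_dominant_allele"),
        ("bs2.x_linked", "bs2_x_linked"),
        ("bs2.af", "bs2_af"),
    )

    def to_flat_dict(self) -> dict[str, Any]:
        flat: dict[str, Any] = {}
        for key, attr, _ in self._SCALARS:
            flat[key] = getattr(self, attr)
        for key, attr in self._BIN_ARRAYS:
            flat[key] = list(getattr(self.loeuf_bins, attr))
        flat["loeuf.default_bin"] = self.loeuf_bins.default_bin
        for status, w in self.review_weights.weights.items():
            flat[f"review_weight.{status}"] = w
        for tool, ladder in self.tool_ladders.items():
            flat[f"insilico.{tool}.pathogenic"] = list(ladder.pathogenic)
            flat[f"insilico.{tool}.benign"] = list(ladder.benign)
        return flat

    @classmethod
    def from_flat_dict(cls, flat: Mapping[str, Any]) -> "EngineConfig":
        scalars: dict[str, Any] = {}
        for key, attr, typ in cls._SCALARS:
            if key in flat:
                scalars[attr] = typ(flat[key])
        bins: dict[str, Any] = {}
        for key, attr in cls._BIN_ARRAYS:
            if key in flat:
                bins[attr] = tuple(flat[key])
        if "loeuf.default_bin" in flat:
            bins["default_bin"] = int(flat["loeuf.default_bin"])
        weights = {
            key[len("review_weight."):]: int(v)
            for key, v in flat.items()
            if key.startswith("review_weight.")
        }
        tools: dict[str, dict[str, Any]] = {}
        for key, v in flat.items():
            if key.startswith("insilico."):
                _, tool, side = key.split(".", 2)
                tools.setdefault(tool, {})[side] = tuple(v)
        ladders = {
            tool: ToolLadder(
                pathogenic=sides.get("pathogenic", (None,) * 4),
                benign=sides.get("benign", (None,) * 4),
            )
            for tool, sides in tools.items()
        }
        defaults = cls()
        return cls(
            loeuf_bins=LoeufBinTable(**bins) if bins else defaults.loeuf_bins,
            review_weights=ReviewWeightMap(weights) if weights else defaults.review_weights,
            tool_ladders=ladders if ladders else dict(DEFAULT_TOOL_LADDERS),
            **scalars,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_flat_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "EngineConfig":
        with open(path) as fh:
            return cls.from_flat_dict(json.load(fh))
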
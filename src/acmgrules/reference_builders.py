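"""Deterministic builders that turn generic local tables into the runtime
reference bundle.

The builders reproduce the preprocessing filters the classifier depends
on: the pathogenic amino-acid index behind PS1/PM5, mutational-hotspot
domains for PM1, the missense-constrained (PP2) and truncating-mechanism
(BP1) gene lists, repeat∩coding intervals for PM4/BP3, the literature
index for PS3 and the GWAS table for PS4.  Everything runs on local
files; no network access.

All builders are pure: identical inputs produce a byte-identical
serialized bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import Interval, IntervalTree

from . import __version__ as _pkg_version
from .annotation_io import AnnotationIOError, read_bed_intervals, read_tsv_rows
from .core_model import (
    AminoAcidChange,
    ReviewWeightMap,
    StrengthLevel,
    normalize_chrom,
)

logger = logging.getLogger("acmgrules")

BUNDLE_FORMAT_VERSION = 1

#: consequence terms treated as protein-truncating for the BP1 gene filter
TRUNCATING_CONSEQUENCES = frozenset({"frameshift variant", "stop gained"})

_PATHOGENIC_SIG = frozenset({"P", "LP"})
_BENIGN_SIG = frozenset({"B", "LB"})


# ---------------------------------------------------------------------------
# input record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinvarLikeRecord:
    """One row of a ClinVar-like variant table."""

    variant_key: tuple[str, int, str, str]
    gene: Optional[str]
    significance: str  # P, LP, B, LB, VUS, conflicting
    review_status: str
    consequences: frozenset[str] = frozenset()
    amino_acid_change: Optional[AminoAcidChange] = None
    clinvar_id: str = ""

    def __post_init__(self) -> None:
        if not self.significance or not self.review_status:
            raise ValueError("significance and review_status must be non-empty")

    @property
    def is_missense(self) -> bool:
        return any("missense" in c for c in self.consequences)

    @property
    def is_truncating(self) -> bool:
        return bool(self.consequences & TRUNCATING_CONSEQUENCES)


@dataclass(frozen=True)
class HotspotDomain:
    """A protein domain enriched for pathogenic variation (0-based
    half-open genomic interval)."""

    domain_id: str
    chrom: str
    start: int
    end: int
    n_path: int
    n_benign: int
    n_vus: int

    def __post_init__(self) -> None:
        if self.n_total < 5:
            raise ValueError(f"domain {self.domain_id}: fewer than five variants")
        if self.path_frac < 0.5:
            raise ValueError(f"domain {self.domain_id}: pathogenic fraction < 50%")
        if self.benign_frac > 0.25:
            raise ValueError(f"domain {self.domain_id}: benign fraction > 25%")
        if self.vus_frac > 0.5:
            raise ValueError(f"domain {self.domain_id}: VUS fraction > 50%")

    @property
    def n_total(self) -> int:
        return self.n_path + self.n_benign + self.n_vus

    @property
    def path_frac(self) -> float:
        return self.n_path / self.n_total

    @property
    def benign_frac(self) -> float:
        return self.n_benign / self.n_total

    @property
    def vus_frac(self) -> float:
        return self.n_vus / self.n_total


@dataclass(frozen=True)
class PathogenicAaEntry:
    """One known-pathogenic amino-acid substitution, with provenance."""

    ref_aa: str
    alt_aa: str
    nucleotide_key: tuple[str, int, str, str]
    review_weight: int
    clinvar_id: str


# ---------------------------------------------------------------------------
# the runtime bundle
# ---------------------------------------------------------------------------


def _tree_dict() -> dict[str, IntervalTree]:
    return {}


@dataclass
class ReferenceBundle:
    """All preprocessed lookup structures, loaded once at startup.

    Interval indexes answer point/range overlap queries; the bundle is
    treated as immutable after load.
    """

    pathogenic_aa_index: dict[tuple[str, int], tuple[PathogenicAaEntry, ...]] = field(
        default_factory=dict
    )
    clinvar_assertion_index: dict[tuple[str, int, str, str], tuple[str, int, str]] = field(
        default_factory=dict
    )
    hotspot_domains: dict[str, IntervalTree] = field(default_factory=_tree_dict)
    literature_genomic: dict[tuple[str, int, str, str], frozenset[str]] = field(
        default_factory=dict
    )
    literature_protein: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    gwas_index: dict[tuple[str, int], tuple[float, float]] = field(default_factory=dict)
    repeat_coding: dict[str, IntervalTree] = field(default_factory=_tree_dict)
    pp2_genes: dict[str, Optional[float]] = field(default_factory=dict)
    bp1_genes: frozenset[str] = frozenset()
    gene_constraint: dict[str, tuple[Optional[float], Optional[float]]] = field(
        default_factory=dict
    )
    final_coding_exons: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    # -- query helpers ---------------------------------------------------

    def loeuf(self, gene: Optional[str]) -> Optional[float]:
        if gene is None:
            return None
        entry = self.gene_constraint.get(gene)
        return entry[0] if entry else None

    def missense_oe(self, gene: Optional[str]) -> Optional[float]:
        if gene is None:
            return None
        entry = self.gene_constraint.get(gene)
        return entry[1] if entry else None

    def hotspots_at(self, chrom: str, pos: int) -> list[HotspotDomain]:
        """Domains overlapping a 1-based position, deterministically ordered
        (highest pathogenic fraction first)."""
        tree = self.hotspot_domains.get(normalize_chrom(chrom))
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos - 1)]
        return sorted(hits, key=lambda d: (-d.path_frac, d.domain_id))

    def repeat_overlap(self, chrom: str, start0: int, end0: int) -> list[tuple[int, int]]:
        """Repeat∩coding intervals overlapping [start0, end0) (0-based)."""
        tree = self.repeat_coding.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree.overlap(start0, end0))

    def in_final_exon_window(self, chrom: str, pos: int, window: int) -> bool:
        """True if the 1-based position lies within the last ``window`` bases
        of any transcript's final coding exon."""
        chrom = normalize_chrom(chrom)
        p0 = pos - 1
        for exon_chrom, start, end in self.final_coding_exons.values():
            if exon_chrom != chrom:
                continue
            if max(start, end - window) <= p0 < end:
                return True
        return False

    # -- (de)serialisation ----------------------------------------------

    def save(self, directory) -> None:
        out = Path(directory)
        out.mkdir(parents=True, exist_ok=True)
        files: dict[str, str] = {}

        def emit(name: str, text: str) -> None:
            (out / name).write_text(text)
            files[name] = hashlib.sha256(text.encode()).hexdigest()

        lines = ["gene\tposition\tref_aa\talt_aa\tchrom\tpos\tref\talt\tweight\tclinvar_id"]
        for (gene, position), entries in sorted(self.pathogenic_aa_index.items()):
            for e in entries:
                c, p, r, a = e.nucleotide_key
                lines.append(
                    f"{gene}\t{position}\t{e.ref_aa}\t{e.alt_aa}\t{c}\t{p}\t{r}\t{a}"
                    f"\t{e.review_weight}\t{e.clinvar_id}"
                )
        emit("pathogenic_aa.tsv", "\n".join(lines) + "\n")

        lines = ["chrom\tpos\tref\talt\tsignificance\tweight\tclinvar_id"]
        for key, (sig, weight, cid) in sorted(self.clinvar_assertion_index.items()):
            lines.append(f"{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t{sig}\t{weight}\t{cid}")
        emit("clinvar_assertions.tsv", "\n".join(lines) + "\n")

        lines = ["domain_id\tchrom\tstart\tend\tn_path\tn_benign\tn_vus"]
        for chrom in sorted(self.hotspot_domains):
            for iv in sorted(self.hotspot_domains[chrom]):
                d = iv.data
                lines.append(
                    f"{d.domain_id}\t{d.chrom}\t{d.start}\t{d.end}"
                    f"\t{d.n_path}\t{d.n_benign}\t{d.n_vus}"
                )
        emit("hotspot_domains.tsv", "\n".join(lines) + "\n")

        lines = ["type\tchrom\tpos\tref\talt\tgene\tprotein_change\tpmids"]
        for key, pmids in sorted(self.literature_genomic.items()):
            lines.append(
                f"genomic\t{key[0]}\t{key[1]}\t{key[2]}\t{key[3]}\t\t\t"
                + ",".join(sorted(pmids))
            )
        for (gene, change), pmids in sorted(self.literature_protein.items()):
            lines.append(f"protein\t\t\t\t\t{gene}\t{change}\t" + ",".join(sorted(pmids)))
        emit("literature.tsv", "\n".join(lines) + "\n")

        lines = ["chrom\tpos\tor\tpvalue"]
        for (chrom, pos), (odds, pval) in sorted(self.gwas_index.items()):
            lines.append(f"{chrom}\t{pos}\t{odds!r}\t{pval!r}")
        emit("gwas.tsv", "\n".join(lines) + "\n")

        lines = []
        for chrom in sorted(self.repeat_coding):
            for iv in sorted(self.repeat_coding[chrom]):
                lines.append(f"{chrom}\t{iv.begin}\t{iv.end}")
        emit("repeat_coding.bed", "\n".join(lines) + ("\n" if lines else ""))

        lines = ["gene\tmis_oe"]
        for gene, oe in sorted(self.pp2_genes.items()):
            lines.append(f"{gene}\t{'' if oe is None else repr(oe)}")
        emit("pp2_genes.tsv", "\n".join(lines) + "\n")

        emit("bp1_genes.txt", "\n".join(sorted(self.bp1_genes)) + ("\n" if self.bp1_genes else ""))

        lines = ["gene\tloeuf\tmis_oe"]
        for gene, (loeuf, mis_oe) in sorted(self.gene_constraint.items()):
            lines.append(
                f"{gene}\t{'' if loeuf is None else repr(loeuf)}"
                f"\t{'' if mis_oe is None else repr(mis_oe)}"
            )
        emit("gene_constraint.tsv", "\n".join(lines) + "\n")

        lines = ["transcript\tchrom\tstart\tend"]
        for tx, (chrom, start, end) in sorted(self.final_coding_exons.items()):
            lines.append(f"{tx}\t{chrom}\t{start}\t{end}")
        emit("final_coding_exons.tsv", "\n".join(lines) + "\n")

        manifest = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "builder": f"acmgrules {_pkg_version}",
            "files": files,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, directory) -> "ReferenceBundle":
        src = Path(directory)
        manifest_path = src / "manifest.json"
        if not manifest_path.exists():
            raise AnnotationIOError(f"no bundle manifest at {manifest_path}")
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise AnnotationIOError(
                f"unsupported bundle format {manifest.get('format_version')!r}"
            )

        bundle = cls()

        for row in read_tsv_rows(src / "pathogenic_aa.tsv",
                                 ("gene", "position", "ref_aa", "alt_aa",
                                  "chrom", "pos", "ref", "alt", "weight", "clinvar_id")):
            key = (row["gene"], int(row["position"]))
            entry = PathogenicAaEntry(
                ref_aa=row["ref_aa"],
                alt_aa=row["alt_aa"],
                nucleotide_key=(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                review_weight=int(row["weight"]),
                clinvar_id=row["clinvar_id"],
            )
            bundle.pathogenic_aa_index[key] = bundle.pathogenic_aa_index.get(key, ()) + (entry,)

        for row in read_tsv_rows(src / "clinvar_assertions.tsv",
                                 ("chrom", "pos", "ref", "alt", "significance",
                                  "weight", "clinvar_id")):
            bundle.clinvar_assertion_index[
                (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            ] = (row["significance"], int(row["weight"]), row["clinvar_id"])

        for row in read_tsv_rows(src / "hotspot_domains.tsv",
                                 ("domain_id", "chrom", "start", "end",
                                  "n_path", "n_benign", "n_vus")):
            domain = HotspotDomain(
                domain_id=row["domain_id"], chrom=row["chrom"],
                start=int(row["start"]), end=int(row["end"]),
                n_path=int(row["n_path"]), n_benign=int(row["n_benign"]),
                n_vus=int(row["n_vus"]),
            )  # count invariants re-checked in the constructor
            bundle.hotspot_domains.setdefault(domain.chrom, IntervalTree()).add(
                Interval(domain.start, domain.end, domain)
            )

        for row in read_tsv_rows(src / "literature.tsv",
                                 ("type", "chrom", "pos", "ref", "alt",
                                  "gene", "protein_change", "pmids")):
            pmids = frozenset(p for p in row["pmids"].split(",") if p)
            if row["type"] == "genomic":
                bundle.literature_genomic[
                    (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                ] = pmids
            else:
                bundle.literature_protein[(row["gene"], row["protein_change"])] = pmids

        for row in read_tsv_rows(src / "gwas.tsv", ("chrom", "pos", "or", "pvalue")):
            bundle.gwas_index[(row["chrom"], int(row["pos"]))] = (
                float(row["or"]), float(row["pvalue"]),
            )

        for chrom, start, end in read_bed_intervals(src / "repeat_coding.bed"):
            bundle.repeat_coding.setdefault(chrom, IntervalTree()).add(Interval(start, end))

        for row in read_tsv_rows(src / "pp2_genes.tsv", ("gene", "mis_oe")):
            bundle.pp2_genes[row["gene"]] = float(row["mis_oe"]) if row["mis_oe"] else None

        bp1_path = src / "bp1_genes.txt"
        bundle.bp1_genes = frozenset(
            g for g in bp1_path.read_text().splitlines() if g.strip()
        )

        for row in read_tsv_rows(src / "gene_constraint.tsv", ("gene", "loeuf", "mis_oe")):
            bundle.gene_constraint[row["gene"]] = (
                float(row["loeuf"]) if row["loeuf"] else None,
                float(row["mis_oe"]) if row["mis_oe"] else None,
            )

        for row in read_tsv_rows(src / "final_coding_exons.tsv",
                                 ("transcript", "chrom", "start", "end")):
            bundle.final_coding_exons[row["transcript"]] = (
                row["chrom"], int(row["start"]), int(row["end"]),
            )

        return bundle


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_pathogenic_aa_index(
    records: Iterable[ClinvarLikeRecord], review_map: ReviewWeightMap
) -> dict[tuple[str, int], tuple[PathogenicAaEntry, ...]]:
    """Index known-pathogenic amino-acid substitutions by (gene, residue).

    Only P/LP records with a positive review weight (at least supporting
    strength) and a protein-level change are retained.
    """
    index: dict[tuple[str, int], list[PathogenicAaEntry]] = {}
    for rec in records:
        if rec.significance not in _PATHOGENIC_SIG:
            continue
        weight = review_map.weight(rec.review_status)
        if weight < 1:
            continue
        if rec.amino_acid_change is None or rec.gene is None:
            continue
        aa = rec.amino_acid_change
        index.setdefault((rec.gene, aa.position), []).append(
            PathogenicAaEntry(
                ref_aa=aa.ref_aa,
                alt_aa=aa.alt_aa,
                nucleotide_key=rec.variant_key,
                review_weight=int(weight),
                clinvar_id=rec.clinvar_id,
            )
        )
    return {k: tuple(sorted(v, key=lambda e: e.nucleotide_key)) for k, v in index.items()}


def build_clinvar_assertion_index(
    records: Iterable[ClinvarLikeRecord], review_map: ReviewWeightMap
) -> dict[tuple[str, int, str, str], tuple[str, int, str]]:
    """Variant key -> (significance, review weight, ClinVar id); weight-0
    records are excluded from all evidence."""
    index: dict[tuple[str, int, str, str], tuple[str, int, str]] = {}
    for rec in records:
        weight = review_map.weight(rec.review_status)
        if weight < 1:
            continue
        index[rec.variant_key] = (rec.significance, int(weight), rec.clinvar_id)
    return index


def build_hotspot_domains(
    records: Iterable[ClinvarLikeRecord],
    domains: Sequence[tuple[str, str, int, int]],
    review_map: ReviewWeightMap,
) -> list[HotspotDomain]:
    """Retain domains enriched for pathogenic variation.

    Records with review weight 0 are dropped first, as are records with
    conflicting significance (neither pathogenic, benign nor VUS).  A
    domain survives only if it has at least five variants, at least 50%
    pathogenic, at most 25% benign and at most 50% VUS (printed
    comparators applied literally: ">50% VUS" and ">25% benign" exclude,
    exactly 50% pathogenic keeps).
    """
    usable = [
        r
        for r in records
        if review_map.weight(r.review_status) >= 1
        and r.significance in _PATHOGENIC_SIG | _BENIGN_SIG | {"VUS"}
    ]
    kept: list[HotspotDomain] = []
    for domain_id, chrom, start, end in domains:
        chrom = normalize_chrom(chrom)
        n_path = n_benign = n_vus = 0
        for rec in usable:
            rchrom, pos, _, _ = rec.variant_key
            if rchrom != chrom or not (start <= pos - 1 < end):
                continue
            if rec.significance in _PATHOGENIC_SIG:
                n_path += 1
            elif rec.significance in _BENIGN_SIG:
                n_benign += 1
            else:
                n_vus += 1
        total = n_path + n_benign + n_vus
        if total < 5:
            continue
        if n_vus / total > 0.5:
            continue
        if n_path / total < 0.5:
            continue
        if n_benign / total > 0.25:
            continue
        kept.append(
            HotspotDomain(
                domain_id=domain_id, chrom=chrom, start=start, end=end,
                n_path=n_path, n_benign=n_benign, n_vus=n_vus,
            )
        )
    return kept


def build_pp2_gene_list(
    records: Iterable[ClinvarLikeRecord],
    constraint: Mapping[str, tuple[Optional[float], Optional[float]]],
) -> dict[str, Optional[float]]:
    """Genes where missense change is the dominant pathogenic mechanism.

    A gene with missense O/E constraint data is kept iff O/E <= 0.4.  A
    gene without constraint data is kept iff its ClinVar-like evidence
    shows: >= 1 benign and >= 1 pathogenic missense variant, >= 5 variants
    in total, <= 50% VUS, benign missense <= 25% of missense and
    pathogenic missense >= 50% of missense.
    """
    by_gene: dict[str, list[ClinvarLikeRecord]] = {}
    for rec in records:
        if rec.gene is not None:
            by_gene.setdefault(rec.gene, []).append(rec)

    result: dict[str, Optional[float]] = {}
    genes = set(by_gene) | {g for g, (_, oe) in constraint.items() if oe is not None}
    for gene in sorted(genes):
        mis_oe = constraint.get(gene, (None, None))[1]
        if mis_oe is not None:
            if mis_oe <= 0.4:
                result[gene] = mis_oe
            continue
        recs = by_gene.get(gene, [])
        total = len(recs)
        if total < 5:
            continue
        n_vus = sum(1 for r in recs if r.significance == "VUS")
        if n_vus > 0.5 * total:
            continue
        missense = [r for r in recs if r.is_missense]
        path_mis = sum(1 for r in missense if r.significance in _PATHOGENIC_SIG)
        benign_mis = sum(1 for r in missense if r.significance in _BENIGN_SIG)
        if path_mis < 1 or benign_mis < 1:
            continue
        if benign_mis > 0.25 * len(missense):
            continue
        if path_mis < 0.5 * len(missense):
            continue
        result[gene] = None
    return result


def build_bp1_gene_list(records: Iterable[ClinvarLikeRecord]) -> frozenset[str]:
    """Genes where truncating variants are the dominant pathogenic mechanism.

    A gene is discarded if it has no pathogenic truncating variant, if more
    than 50% of its variants are VUS, if fewer than 75% of its pathogenic
    variants are truncating, or if more than 25% of its truncating variants
    are benign.
    """
    by_gene: dict[str, list[ClinvarLikeRecord]] = {}
    for rec in records:
        if rec.gene is not None:
            by_gene.setdefault(rec.gene, []).append(rec)

    kept: set[str] = set()
    for gene, recs in by_gene.items():
        path = [r for r in recs if r.significance in _PATHOGENIC_SIG]
        trunc = [r for r in recs if r.is_truncating]
        path_trunc = sum(1 for r in path if r.is_truncating)
        if path_trunc < 1:
            continue
        n_vus = sum(1 for r in recs if r.significance == "VUS")
        if n_vus > 0.5 * len(recs):
            continue
        if path_trunc < 0.75 * len(path):
            continue
        benign_trunc = sum(1 for r in trunc if r.significance in _BENIGN_SIG)
        if trunc and benign_trunc > 0.25 * len(trunc):
            continue
        kept.add(gene)
    return frozenset(kept)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def build_repeat_coding_intervals(
    repeats: Iterable[tuple[str, int, int]],
    coding: Iterable[tuple[str, int, int]],
) -> dict[str, IntervalTree]:
    """Pairwise intersection of repeat and coding BED intervals, merged
    into disjoint sorted intervals per chromosome (0-based half-open)."""
    by_chrom_r: dict[str, list[tuple[int, int]]] = {}
    by_chrom_c: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in repeats:
        by_chrom_r.setdefault(normalize_chrom(chrom), []).append((start, end))
    for chrom, start, end in coding:
        by_chrom_c.setdefault(normalize_chrom(chrom), []).append((start, end))

    result: dict[str, IntervalTree] = {}
    for chrom in sorted(set(by_chrom_r) & set(by_chrom_c)):
        r_iv = _merge_intervals(by_chrom_r[chrom])
        c_iv = _merge_intervals(by_chrom_c[chrom])
        pieces: list[tuple[int, int]] = []
        i = j = 0
        while i < len(r_iv) and j < len(c_iv):
            lo = max(r_iv[i][0], c_iv[j][0])
            hi = min(r_iv[i][1], c_iv[j][1])
            if lo < hi:
                pieces.append((lo, hi))
            if r_iv[i][1] <= c_iv[j][1]:
                i += 1
            else:
                j += 1
        if pieces:
            tree = IntervalTree(Interval(s, e) for s, e in _merge_intervals(pieces))
            result[chrom] = tree
    return result


def build_literature_index(
    rows: Iterable[Mapping[str, str]],
) -> tuple[
    dict[tuple[str, int, str, str], frozenset[str]],
    dict[tuple[str, str], frozenset[str]],
]:
    """Literature-variant table -> (genomic index, protein index).

    Rows are typed ``genomic`` (chrom/pos/ref/alt/pmid) or ``protein``
    (gene/protein_change/pmid); PubMed sets are deduplicated.
    """
    genomic: dict[tuple[str, int, str, str], set[str]] = {}
    protein: dict[tuple[str, str], set[str]] = {}
    for row in rows:
        pmid = str(row["pmid"]).strip()
        if not pmid:
            continue
        if row["type"] == "genomic":
            key = (normalize_chrom(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
            genomic.setdefault(key, set()).add(pmid)
        elif row["type"] == "protein":
            change = row["protein_change"].strip()
            if change.startswith("p."):
                change = change[2:]
            protein.setdefault((row["gene"], change), set()).add(pmid)
        else:
            raise AnnotationIOError(f"unknown literature row type {row['type']!r}")
    return (
        {k: frozenset(v) for k, v in genomic.items()},
        {k: frozenset(v) for k, v in protein.items()},
    )


def build_gwas_index(
    rows: Iterable[Mapping[str, str]],
) -> dict[tuple[str, int], tuple[float, float]]:
    """GWAS table (chrom, pos, or, pvalue) -> position-keyed lookup."""
    index: dict[tuple[str, int], tuple[float, float]] = {}
    for row in rows:
        index[(normalize_chrom(row["chrom"]), int(row["pos"]))] = (
            float(row["or"]), float(row["pvalue"]),
        )
    return index


# ---------------------------------------------------------------------------
# file-level drivers
# ---------------------------------------------------------------------------


_SIGNIFICANCE_TOKENS = {
    "p": "P", "pathogenic": "P",
    "lp": "LP", "likely pathogenic": "LP", "likely_pathogenic": "LP",
    "b": "B", "benign": "B",
    "lb": "LB", "likely benign": "LB", "likely_benign": "LB",
    "vus": "VUS", "uncertain significance": "VUS", "uncertain_significance": "VUS",
    "conflicting": "conflicting",
    "conflicting interpretations of pathogenicity": "conflicting",
    "conflicting_interpretations_of_pathogenicity": "conflicting",
}


def read_clinvar_table(path) -> list[ClinvarLikeRecord]:
    """Read a ClinVar-like TSV (chrom, pos, ref, alt, gene, significance,
    review_status, consequences, aa_change, clinvar_id)."""
    records: list[ClinvarLikeRecord] = []
    rows = read_tsv_rows(
        path,
        ("chrom", "pos", "ref", "alt", "gene", "significance",
         "review_status", "consequences", "aa_change", "clinvar_id"),
    )
    for i, row in enumerate(rows, start=1):
        sig = _SIGNIFICANCE_TOKENS.get(row["significance"].strip().lower())
        if sig is None:
            raise AnnotationIOError(
                f"{path} row {i}: unknown significance {row['significance']!r}"
            )
        aa = None
        token = row["aa_change"].strip()
        if token:
            if token.startswith("p."):
                token = token[2:]
            ref_aa, digits, alt_aa = "", "", ""
            k = 0
            while k < len(token) and not token[k].isdigit():
                ref_aa += token[k]
                k += 1
            while k < len(token) and token[k].isdigit():
                digits += token[k]
                k += 1
            alt_aa = token[k:]
            if not (ref_aa and digits and alt_aa):
                raise AnnotationIOError(f"{path} row {i}: bad aa_change {row['aa_change']!r}")
            aa = AminoAcidChange(position=int(digits), ref_aa=ref_aa, alt_aa=alt_aa)
        records.append(
            ClinvarLikeRecord(
                variant_key=(
                    normalize_chrom(row["chrom"]), int(row["pos"]),
                    row["ref"], row["alt"],
                ),
                gene=row["gene"] or None,
                significance=sig,
                review_status=row["review_status"],
                consequences=frozenset(
                    c.strip() for c in row["consequences"].split(",") if c.strip()
                ),
                amino_acid_change=aa,
                clinvar_id=row["clinvar_id"],
            )
        )
    return records


def read_gene_constraint(path) -> dict[str, tuple[Optional[float], Optional[float]]]:
    """Gene constraint TSV (gene, loeuf, mis_oe; blank = unavailable)."""
    table: dict[str, tuple[Optional[float], Optional[float]]] = {}
    for row in read_tsv_rows(path, ("gene", "loeuf", "mis_oe")):
        table[row["gene"]] = (
            float(row["loeuf"]) if row["loeuf"].strip() else None,
            float(row["mis_oe"]) if row["mis_oe"].strip() else None,
        )
    return table


def read_domain_bed(path) -> list[tuple[str, str, int, int]]:
    """Domain BED with a name column -> (id, chrom, start, end) tuples."""
    domains: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise AnnotationIOError(f"{path} row {i}: domain BED needs 4 columns")
            domains.append(
                (parts[3], normalize_chrom(parts[0]), int(parts[1]), int(parts[2]))
            )
    return domains


def read_final_exons(path) -> dict[str, tuple[str, int, int]]:
    """Final-coding-exon TSV (transcript, chrom, start, end; 0-based
    half-open) taken as a direct input."""
    exons: dict[str, tuple[str, int, int]] = {}
    for row in read_tsv_rows(path, ("transcript", "chrom", "start", "end")):
        exons[row["transcript"]] = (
            normalize_chrom(row["chrom"]), int(row["start"]), int(row["end"]),
        )
    return exons


def build_reference_bundle(
    *,
    clinvar: Optional[str] = None,
    domains: Optional[str] = None,
    repeats: Optional[str] = None,
    coding: Optional[str] = None,
    constraint: Optional[str] = None,
    gwas: Optional[str] = None,
    literature: Optional[str] = None,
    final_exons: Optional[str] = None,
    review_map: Optional[ReviewWeightMap] = None,
) -> ReferenceBundle:
    """Run every builder on the provided local files (any subset)."""
    review_map = review_map or ReviewWeightMap()
    bundle = ReferenceBundle()

    records: list[ClinvarLikeRecord] = []
    if clinvar:
        records = read_clinvar_table(clinvar)
        bundle.pathogenic_aa_index = build_pathogenic_aa_index(records, review_map)
        bundle.clinvar_assertion_index = build_clinvar_assertion_index(records, review_map)
        bundle.bp1_genes = build_bp1_gene_list(records)

    if constraint:
        bundle.gene_constraint = read_gene_constraint(constraint)

    if clinvar or constraint:
        bundle.pp2_genes = build_pp2_gene_list(records, bundle.gene_constraint)

    if clinvar and domains:
        kept = build_hotspot_domains(records, read_domain_bed(domains), review_map)
        for d in kept:
            bundle.hotspot_domains.setdefault(d.chrom, IntervalTree()).add(
                Interval(d.start, d.end, d)
            )

    if repeats and coding:
        bundle.repeat_coding = build_repeat_coding_intervals(
            read_bed_intervals(repeats), read_bed_intervals(coding)
        )

    if gwas:
        bundle.gwas_index = build_gwas_index(read_tsv_rows(gwas, ("chrom", "pos", "or", "pvalue")))

    if literature:
        rows = read_tsv_rows(
            literature,
            ("type", "chrom", "pos", "ref", "alt", "gene", "protein_change", "pmid"),
        )
        bundle.literature_genomic, bundle.literature_protein = build_literature_index(rows)

    if final_exons:
        bundle.final_coding_exons = read_final_exons(final_exons)

    return bundle
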
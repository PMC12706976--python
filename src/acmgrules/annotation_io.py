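"""Readers and writers for the engine's file formats.

Formats handled here:

* annotated-variant JSON — a documented dialect with a top-level
  ``"variants"`` array; read incrementally so memory stays bounded by one
  record regardless of file size,
* external call TSV — manual code assignments / overrides,
* truth-set TSV — expert categories and code sets for validation,
* classification TSV — the engine's one-row-per-variant output,
* small BED / TSV readers used by the reference builders.

Variant records are 1-based (VCF convention); all interval files are
0-based half-open (BED convention).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from typing import IO, Any, Iterable, Iterator, Optional

from .core_model import (
    AcmgCode,
    AminoAcidChange,
    AnnotatedVariant,
    CATEGORY_TOKENS,
    Category,
    ClassificationResult,
    ClinVarEntry,
    ConflictStage,
    EvidenceCall,
    GeneDisease,
    InheritanceMode,
    InSilicoScores,
    PopulationFrequencies,
    StrengthLevel,
    TranscriptConsequence,
    VariantType,
    normalize_chrom,
    strength_from_label,
)

logger = logging.getLogger("acmgrules")


class AnnotationIOError(Exception):
    """Fatal, file-level parse error."""


class RecordError(AnnotationIOError):
    """Record-level validation error; carries the offending record index/row."""

    def __init__(self, index: int, message: str):
        super().__init__(f"record {index}: {message}")
        self.index = index


# ---------------------------------------------------------------------------
# annotated-variant JSON dialect
# ---------------------------------------------------------------------------


def _parse_aa_change(obj: Any) -> Optional[AminoAcidChange]:
    if obj is None:
        return None
    return AminoAcidChange(
        position=int(obj["position"]),
        ref_aa=str(obj["ref_aa"]),
        alt_aa=str(obj["alt_aa"]),
    )


def parse_variant_record(rec: dict, index: int = 0) -> AnnotatedVariant:
    """Build an :class:`AnnotatedVariant` from one JSON record.

    Optional fields default to null/empty; unknown fields are ignored.
    Missing chrom/pos/ref/alt (or invariant violations) raise
    :class:`RecordError` carrying the record index.
    """
    try:
        for req in ("chrom", "pos", "ref", "alt"):
            if req not in rec or rec[req] in (None, ""):
                raise ValueError(f"missing required field {req!r}")

        freq = PopulationFrequencies(**{
            k: rec.get("freq", {}).get(k)
            for k in PopulationFrequencies.__dataclass_fields__
        }) if rec.get("freq") else PopulationFrequencies()

        scores = InSilicoScores(**{
            k: rec.get("scores", {}).get(k)
            for k in InSilicoScores.__dataclass_fields__
        }) if rec.get("scores") else InSilicoScores()

        txs = tuple(
            TranscriptConsequence(
                transcript_id=str(t["transcript_id"]),
                consequences=frozenset(t.get("consequences", ())),
                amino_acid_change=_parse_aa_change(t.get("amino_acid_change")),
                is_canonical=bool(t.get("is_canonical", False)),
            )
            for t in rec.get("transcript_consequences", ())
        )

        clinvar = rec.get("clinvar_top")
        clinvar_top = (
            ClinVarEntry(
                significance=str(clinvar["significance"]),
                review_status=str(clinvar["review_status"]),
                clinvar_id=str(clinvar.get("clinvar_id", "")),
            )
            if clinvar
            else None
        )

        gene_disease = tuple(
            GeneDisease(
                disease=str(g.get("disease", "")),
                inheritance=InheritanceMode(g.get("inheritance", "other")),
            )
            for g in rec.get("gene_disease", ())
        )

        vtype = rec.get("variant_type")
        return AnnotatedVariant(
            chrom=str(rec["chrom"]),
            pos=int(rec["pos"]),
            ref=str(rec["ref"]),
            alt=str(rec["alt"]),
            variant_type=VariantType(vtype) if vtype else None,
            gene=rec.get("gene"),
            consequences=frozenset(rec.get("consequences", ())),
            transcript_consequences=txs,
            amino_acid_change=_parse_aa_change(rec.get("amino_acid_change")),
            clinvar_top=clinvar_top,
            pubmed_ids=tuple(str(p) for p in rec.get("pubmed_ids", ())),
            gene_disease=gene_disease,
            dbsnp_ids=tuple(str(d) for d in rec.get("dbsnp_ids", ())),
            freq=freq,
            scores=scores,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise RecordError(index, str(exc)) from exc


def _iter_json_array(fh: IO[str], key: str, chunk: int = 1 << 16) -> Iterator[Any]:
    """Incrementally decode the items of the top-level ``key`` array.

    Only the current buffer tail is kept in memory, so arbitrarily long
    files stream in bounded memory.
    """
    decoder = json.JSONDecoder()
    buf = ""
    needle = f'"{key}"'

    def refill() -> bool:
        nonlocal buf
        data = fh.read(chunk)
        if not data:
            return False
        buf += data
        return True

    # locate the array opening bracket after the key
    while True:
        i = buf.find(needle)
        if i >= 0:
            j = buf.find("[", i + len(needle))
            if j >= 0:
                buf = buf[j + 1:]
                break
        # keep enough tail to not split the needle across chunks
        if len(buf) > len(needle):
            buf = buf[-(len(needle) + 8):]
        if not refill():
            raise AnnotationIOError(f"no top-level {key!r} array found")

    while True:
        buf = buf.lstrip(" \t\r\n,")
        if not buf:
            if not refill():
                raise AnnotationIOError("unterminated variants array")
            continue
        if buf[0] == "]":
            return
        try:
            obj, end = decoder.raw_decode(buf)
        except ValueError:
            if not refill():
                raise AnnotationIOError("malformed JSON in variants array")
            continue
        yield obj
        buf = buf[end:]


def read_annotated_variants(path) -> Iterator[AnnotatedVariant]:
    """Stream :class:`AnnotatedVariant` records from an annotated-variant
    JSON file in file order."""
    with open(path) as fh:
        for i, rec in enumerate(_iter_json_array(fh, "variants")):
            if not isinstance(rec, dict):
                raise RecordError(i, "variant record must be a JSON object")
            yield parse_variant_record(rec, i)


def write_annotated_variants(records: Iterable[dict], path) -> None:
    """Write raw variant record dicts in the annotated-variant JSON dialect."""
    with open(path, "w") as fh:
        json.dump({"variants": list(records)}, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# external call file
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExternalCall:
    """A manual code assignment for one variant.

    Strength 0 disables the code for that variant; otherwise manual codes
    are added and automated codes overridden at the given strength.
    """

    variant_key: tuple[str, int, str, str]
    code: AcmgCode
    strength: int
    rationale: str

    def __post_init__(self) -> None:
        if not (0 <= self.strength <= 5):
            raise ValueError(f"strength must be in 0..5, got {self.strength}")


EXTERNAL_CALL_COLUMNS = ("chrom", "pos", "ref", "alt", "code", "strength", "rationale")


def read_external_calls(path) -> list[ExternalCall]:
    calls: list[ExternalCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(EXTERNAL_CALL_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationIOError(
                f"external call file missing columns: {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=1):
            try:
                code = AcmgCode(row["code"].strip().upper())
            except ValueError:
                raise RecordError(i, f"unknown ACMG code {row['code']!r}") from None
            try:
                strength = int(row["strength"])
            except ValueError:
                raise RecordError(i, f"non-integer strength {row['strength']!r}") from None
            if not (0 <= strength <= 5):
                raise RecordError(i, f"strength {strength} outside 0..5")
            calls.append(
                ExternalCall(
                    variant_key=(
                        normalize_chrom(row["chrom"]),
                        int(row["pos"]),
                        row["ref"],
                        row["alt"],
                    ),
                    code=code,
                    strength=strength,
                    rationale=row.get("rationale", "") or "manual call",
                )
            )
    return calls


def write_external_calls(calls: Iterable[ExternalCall], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EXTERNAL_CALL_COLUMNS)
        for c in calls:
            chrom, pos, ref, alt = c.variant_key
            writer.writerow([chrom, pos, ref, alt, c.code.value, c.strength, c.rationale])


# ---------------------------------------------------------------------------
# truth-set TSV
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthRecord:
    variant_key: tuple[str, int, str, str]
    expert_category: Category
    expert_codes: frozenset[tuple[AcmgCode, Optional[StrengthLevel]]]


TRUTH_COLUMNS = ("chrom", "pos", "ref", "alt", "category", "codes")


def _parse_code_token(token: str, row: int) -> tuple[AcmgCode, Optional[StrengthLevel]]:
    name, _, strength = token.partition(":")
    try:
        code = AcmgCode(name.strip().upper())
    except ValueError:
        raise RecordError(row, f"unknown ACMG code {name!r}") from None
    if not strength:
        return code, None
    return code, strength_from_label(strength)


def read_truth_tsv(path) -> list[TruthRecord]:
    records: list[TruthRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TRUTH_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationIOError(f"truth file missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            token = row["category"].strip().lower()
            if token not in CATEGORY_TOKENS:
                raise RecordError(i, f"unknown category {row['category']!r}")
            codes = frozenset(
                _parse_code_token(t, i)
                for t in (row.get("codes") or "").split("|")
                if t.strip()
            )
            records.append(
                TruthRecord(
                    variant_key=(
                        normalize_chrom(row["chrom"]),
                        int(row["pos"]),
                        row["ref"],
                        row["alt"],
                    ),
                    expert_category=CATEGORY_TOKENS[token],
                    expert_codes=codes,
                )
            )
    return records


def write_truth_tsv(records: Iterable[TruthRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for r in records:
            chrom, pos, ref, alt = r.variant_key
            codes = "|".join(
                f"{c.value}:{s.label}" if s is not None else c.value
                for c, s in sorted(
                    r.expert_codes, key=lambda cs: (cs[0].value, cs[1] or 0)
                )
            )
            writer.writerow([chrom, pos, ref, alt, r.expert_category.value, codes])


# ---------------------------------------------------------------------------
# classification TSV output
# ---------------------------------------------------------------------------


CLASSIFICATION_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "classification", "codes",
    "pathogenic_score", "benign_score", "conflict_stage", "rationales",
)


def _sanitize(text: str) -> str:
    """Keep TSV cells one-line and delimiter-free."""
    return text.replace("\t", " ").replace("\n", " ").replace(";", ",")


def write_classifications(results: Iterable[ClassificationResult], path) -> None:
    """Write the one-row-per-variant classification TSV.

    Byte output is deterministic for identical inputs: fixed column order,
    fixed strength vocabulary and evidence listed in engine order.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CLASSIFICATION_COLUMNS)
        for r in results:
            chrom, pos, ref, alt = r.variant_key
            codes = ",".join(f"{e.code.value}:{e.strength.label}" for e in r.evidence)
            rationale_parts = [
                f"{e.code.value}={_sanitize(e.rationale)}" for e in r.evidence
            ]
            if r.error:
                rationale_parts.append(f"ERROR={_sanitize(r.error)}")
            rationales = ";".join(rationale_parts)
            writer.writerow([
                chrom, pos, ref, alt,
                r.gene or "",
                r.category.display,
                codes,
                r.pathogenic_score_sum,
                r.benign_score_sum,
                r.conflict_stage.value,
                rationales,
            ])


_DISPLAY_TO_CATEGORY = {c.display: c for c in Category}


def read_classifications(path) -> list[ClassificationResult]:
    """Re-parse a classification TSV (round-trip of category, codes,
    strengths and scores; rationales are recovered as written)."""
    results: list[ClassificationResult] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(CLASSIFICATION_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationIOError(
                f"classification file missing columns: {sorted(missing)}"
            )
        for i, row in enumerate(reader, start=1):
            rationales = dict(
                part.split("=", 1)
                for part in (row["rationales"] or "").split(";")
                if "=" in part
            )
            evidence = []
            for token in (row["codes"] or "").split(","):
                if not token.strip():
                    continue
                name, _, strength = token.partition(":")
                evidence.append(
                    EvidenceCall(
                        code=AcmgCode(name),
                        strength=strength_from_label(strength),
                        rationale=rationales.get(name, "(not recorded)"),
                    )
                )
            display = row["classification"]
            if display not in _DISPLAY_TO_CATEGORY:
                raise RecordError(i, f"unknown classification {display!r}")
            results.append(
                ClassificationResult(
                    variant_key=(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                    gene=row["gene"] or None,
                    category=_DISPLAY_TO_CATEGORY[display],
                    evidence=tuple(evidence),
                    conflict_stage=ConflictStage(row["conflict_stage"]),
                    pathogenic_score_sum=int(row["pathogenic_score"]),
                    benign_score_sum=int(row["benign_score"]),
                    error=rationales.get("ERROR"),
                )
            )
    return results


# ---------------------------------------------------------------------------
# small builder-side readers (BED and generic TSV tables)
# ---------------------------------------------------------------------------


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) from a BED file (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise RecordError(i, f"BED line has {len(parts)} columns, need >= 3")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise RecordError(i, "non-integer BED coordinates") from None
            if start < 0 or end < start:
                raise RecordError(i, f"invalid BED interval [{start}, {end})")
            intervals.append((normalize_chrom(parts[0]), start, end))
    return intervals


def read_tsv_rows(path, required: tuple[str, ...]) -> list[dict[str, str]]:
    """Read a header-ed TSV into dict rows, checking required columns."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(required) - set(reader.fieldnames or ())
        if missing:
            raise AnnotationIOError(f"{path}: missing columns {sorted(missing)}")
        return list(reader)
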
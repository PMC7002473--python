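"""Protein sequence I/O: FASTA reading/writing, validation, and class labels.

A dataset is a list of :class:`ProteinRecord` objects with unique ids.  Class
labels (positive = pattern recognition receptor, negative = other protein) come
either from a two-column id,label table or from a pair of FASTA files, one per
class.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, fixed in alphabetical order.  Every feature
#: vector in the package is ordered by this alphabet.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)


class Label(enum.Enum):
    """Binary class label of a protein record."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class Policy(enum.Enum):
    """How :func:`validate_sequence` treats non-canonical residues."""

    STRICT = "strict"
    SANITIZE = "sanitize"


class FastaParseError(ValueError):
    """Malformed FASTA input (carries a 1-based line number)."""


class ValidationError(ValueError):
    """A sequence violates the canonical-alphabet contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with an optional class label."""

    id: str
    sequence: str
    label: Label = Label.UNKNOWN

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, label: Label = Label.UNKNOWN) -> list[ProteinRecord]:
    """Read a FASTA file into a list of records.

    The record id is the first whitespace-delimited token of the header.
    Ids must be unique within the file.  Sequences may be wrapped over
    multiple lines.

    Raises
    ------
    FastaParseError
        If the file is empty, contains sequence data before any header,
        or contains duplicate ids.
    """
    path = Path(path)
    with path.open() as handle:
        # reject leading sequence-before-header data, which SimpleFastaParser
        # silently skips
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first '>' header"
                )
            break
        handle.seek(0)
        records = []
        seen: set[str] = set()
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else header
            if rec_id in seen:
                raise FastaParseError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            records.append(ProteinRecord(id=rec_id, sequence=seq.replace(" ", ""), label=label))
    if not records:
        raise FastaParseError(f"{path}: empty FASTA file (no records)")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def validate_sequence(record: ProteinRecord, policy: Policy = Policy.SANITIZE) -> ProteinRecord:
    """Canonicalize a record's sequence.

    Both policies uppercase the sequence.  STRICT raises on any character
    outside the 20-letter canonical alphabet; SANITIZE drops such characters
    (ambiguity codes B/J/Z/X, non-standard O/U, stop ``*`` and gap symbols)
    and logs a warning with counts.

    Raises
    ------
    ValidationError
        Under STRICT for any non-canonical character (listing characters and
        1-based positions), or under SANITIZE if nothing canonical remains.
    """
    seq = record.sequence.upper()
    bad = [(i + 1, ch) for i, ch in enumerate(seq) if ch not in _CANONICAL_SET]
    if not bad:
        if seq == record.sequence:
            return record
        return replace(record, sequence=seq)
    if policy is Policy.STRICT:
        detail = ", ".join(f"{ch!r}@{pos}" for pos, ch in bad[:10])
        raise ValidationError(
            f"record {record.id!r}: {len(bad)} non-canonical character(s): {detail}"
        )
    cleaned = "".join(ch for ch in seq if ch in _CANONICAL_SET)
    if not cleaned:
        raise ValidationError(f"record {record.id!r}: empty sequence after sanitization")
    counts: dict[str, int] = {}
    for _, ch in bad:
        counts[ch] = counts.get(ch, 0) + 1
    logger.warning(
        "record %s: removed %d non-canonical residue(s): %s",
        record.id,
        len(bad),
        dict(sorted(counts.items())),
    )
    return replace(record, sequence=cleaned)


def validate_dataset(
    records: Sequence[ProteinRecord], policy: Policy = Policy.SANITIZE
) -> list[ProteinRecord]:
    """Validate every record and enforce id uniqueness."""
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(validate_sequence(rec, policy))
    return out


def read_labels(path: str | Path) -> dict[str, Label]:
    """Read a headered CSV/TSV label table with columns ``id`` and ``label``.

    Label values are matched case-insensitively against
    positive/negative/unknown (``pos``/``neg``/``1``/``0`` also accepted).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: label table missing column(s) {sorted(missing)}")
    aliases = {
        "positive": Label.POSITIVE, "pos": Label.POSITIVE, "1": Label.POSITIVE,
        "negative": Label.NEGATIVE, "neg": Label.NEGATIVE, "0": Label.NEGATIVE,
        "unknown": Label.UNKNOWN,
    }
    labels: dict[str, Label] = {}
    for rec_id, raw in zip(df["id"], df["label"]):
        key = str(raw).strip().lower()
        if key not in aliases:
            raise ValueError(f"{path}: unrecognized label {raw!r} for id {rec_id!r}")
        labels[str(rec_id)] = aliases[key]
    return labels


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write an id,label CSV for a labeled dataset."""
    df = pd.DataFrame(
        [(rec.id, rec.label.value) for rec in records], columns=["id", "label"]
    )
    df.to_csv(path, index=False)


def apply_labels(
    records: Sequence[ProteinRecord], labels: dict[str, Label]
) -> list[ProteinRecord]:
    """Return records re-labeled from an id → label map (missing ids keep UNKNOWN)."""
    return [replace(r, label=labels.get(r.id, r.label)) for r in records]


def load_two_class_fasta(
    positive: str | Path, negative: str | Path, policy: Policy = Policy.SANITIZE
) -> list[ProteinRecord]:
    """Load a labeled dataset from a positive and a negative FASTA file."""
    pos = read_fasta(positive, label=Label.POSITIVE)
    neg = read_fasta(negative, label=Label.NEGATIVE)
    return validate_dataset(pos + neg, policy)
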
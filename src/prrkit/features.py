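"""Fixed-length feature encodings for protein sequences and PSSM profiles.

Three encodings are provided, all on a percent scale so that a sequence of any
length maps to a comparable fixed-length vector:

* **AAC** (amino acid composition) — 20 values, ``100 * count(r) / L``.
* **DPC** (dipeptide composition) — 400 values, ``100 * count(rs) / (L - 1)``
  over the overlapping adjacent pairs.
* **PSSM-400** (profile composition) — a 20x20 = 400-value summary of a
  PSI-BLAST position-specific scoring matrix: the log-odds scores are squashed
  through a logistic map into (0, 1), then for each residue type *r* and each
  matrix column *c* the squashed scores of the positions where the query
  sequence has residue *r* are summed and scaled by ``100 / L``.

The AAC block concatenated with the PSSM-400 block gives the 420-length
combined encoding.  All vectors are ordered by the canonical alphabet
(ACDEFGHIKLMNPQRSTVWY); PSSM files written by PSI-BLAST use a different column
order, which the parser remaps on load.

Scikit-learn style transformers (:class:`CompositionEncoder`,
:class:`ProfileCompositionEncoder`) wrap the per-record functions so feature
extraction composes with pipelines and model selection.
"""

from __future__ import annotations

import enum
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .seqio import CANONICAL_ALPHABET, ProteinRecord, write_fasta

_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}

#: Dipeptide names in row-major canonical order: AA, AC, ..., YY.
DIPEPTIDES = [a + b for a in CANONICAL_ALPHABET for b in CANONICAL_ALPHABET]


class Schema(enum.Enum):
    """Feature-vector layout tags with their fixed lengths."""

    AAC20 = 20
    DPC400 = 400
    PSSM400 = 400
    COMBO420 = 420


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length real vector tied to a source record and a schema."""

    id: str
    schema: Schema
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schema.value,):
            raise ValueError(
                f"{self.schema.name} vector must have length {self.schema.value}, "
                f"got shape {values.shape}"
            )


@dataclass(frozen=True)
class PssmProfile:
    """A per-position 20-column log-odds profile for one query sequence.

    ``scores`` has one row per sequence position; columns are re-ordered to
    the canonical alphabet on load regardless of the order in the source file
    (kept in ``source_column_order``).
    """

    id: str
    sequence: str
    scores: np.ndarray
    source_column_order: str = CANONICAL_ALPHABET

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"profile {self.id!r}: scores shape {scores.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )


class PssmParseError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM file (carries a line number)."""


def compute_aac(record: ProteinRecord) -> FeatureVector:
    """Amino acid composition in percent, ordered by the canonical alphabet."""
    if not record.sequence:
        raise ValueError(f"record {record.id!r}: empty sequence")
    counts = np.zeros(20)
    for ch in record.sequence:
        counts[_INDEX[ch]] += 1
    return FeatureVector(record.id, Schema.AAC20, 100.0 * counts / len(record.sequence))


def compute_dpc(record: ProteinRecord) -> FeatureVector:
    """Dipeptide composition in percent over the L-1 overlapping pairs."""
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError(
            f"record {record.id!r}: dipeptide composition requires length >= 2, got {len(seq)}"
        )
    counts = np.zeros((20, 20))
    for a, b in zip(seq, seq[1:]):
        counts[_INDEX[a], _INDEX[b]] += 1
    return FeatureVector(record.id, Schema.DPC400, 100.0 * counts.ravel() / (len(seq) - 1))


def mean_composition(records: Sequence[ProteinRecord]) -> FeatureVector:
    """Arithmetic mean of per-record AAC vectors (class composition profiles)."""
    if not records:
        raise ValueError("mean_composition requires at least one record")
    stack = np.stack([compute_aac(r).values for r in records])
    return FeatureVector("mean", Schema.AAC20, stack.mean(axis=0))


def parse_pssm(path: str | Path, record_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file (``-out_ascii_pssm`` output).

    Captures the first 20 numeric columns (position-specific log-odds) of each
    row and remaps them from the file's residue column order to the canonical
    alphabet.  The query sequence is rebuilt from the per-row residue column.

    Raises
    ------
    PssmParseError
        On a truncated file, a malformed header, non-integer log-odds, or
        out-of-order position indices; the message carries the line number.
    """
    path = Path(path)
    if record_id is None:
        record_id = path.stem.removesuffix(".pssm")
    column_order: str | None = None
    residues: list[str] = []
    rows: list[list[int]] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            tokens = line.split()
            if column_order is None:
                # header row: 40 residue letters (log-odds then percentage blocks)
                if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens):
                    order = "".join(tokens[:20])
                    if sorted(order) != sorted(CANONICAL_ALPHABET):
                        raise PssmParseError(
                            f"{path}: line {lineno}: column header is not a "
                            f"20-residue alphabet: {order!r}"
                        )
                    column_order = order
                continue
            if not tokens:
                break  # blank line after the matrix body
            if not tokens[0].isdigit():
                break  # footer (K/Lambda statistics)
            if len(tokens) < 22 or len(tokens[1]) != 1 or not tokens[1].isalpha():
                raise PssmParseError(f"{path}: line {lineno}: malformed matrix row")
            if int(tokens[0]) != len(rows) + 1:
                raise PssmParseError(
                    f"{path}: line {lineno}: expected position {len(rows) + 1}, "
                    f"got {tokens[0]}"
                )
            try:
                rows.append([int(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise PssmParseError(
                    f"{path}: line {lineno}: non-integer log-odds score ({exc})"
                ) from None
            residues.append(tokens[1].upper())
    if column_order is None:
        raise PssmParseError(f"{path}: no column-order header found (truncated file?)")
    if not rows:
        raise PssmParseError(f"{path}: no matrix rows found")
    scores = np.array(rows, dtype=float)
    # remap file column order -> canonical alphabet
    perm = [column_order.index(aa) for aa in CANONICAL_ALPHABET]
    return PssmProfile(
        id=record_id,
        sequence="".join(residues),
        scores=scores[:, perm],
        source_column_order=column_order,
    )


def normalize_pssm(profile: PssmProfile) -> PssmProfile:
    """Squash log-odds scores into (0, 1) with the logistic map 1/(1+e^-x).

    The map is bounded, strictly monotone and parameter-free, so relative
    preferences within a column are preserved while extreme scores saturate.
    """
    return PssmProfile(
        id=profile.id,
        sequence=profile.sequence,
        scores=1.0 / (1.0 + np.exp(-profile.scores)),
        source_column_order=profile.source_column_order,
    )


def compute_pssm400(profile: PssmProfile) -> FeatureVector:
    """PSSM composition: per residue-type sums of normalized scores, / L, x100.

    Block for residue type *r* (20 consecutive entries, one per matrix column)
    is ``100 * sum over positions i with seq[i] == r of norm_scores[i, :] / L``.
    Residue types absent from the sequence contribute an all-zero block.
    The profile must already be normalized (all cells in [0, 1]).
    """
    scores = profile.scores
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError(
            f"profile {profile.id!r}: scores outside [0, 1]; call normalize_pssm first"
        )
    length = len(profile.sequence)
    blocks = np.zeros((20, 20))
    for i, aa in enumerate(profile.sequence):
        blocks[_INDEX[aa]] += scores[i]
    return FeatureVector(profile.id, Schema.PSSM400, 100.0 * blocks.ravel() / length)


def concat_features(aac: FeatureVector, pssm: FeatureVector) -> FeatureVector:
    """Concatenate an AAC block and a PSSM-400 block into the 420-length vector."""
    if aac.schema is not Schema.AAC20 or pssm.schema is not Schema.PSSM400:
        raise ValueError(
            f"expected (AAC20, PSSM400), got ({aac.schema.name}, {pssm.schema.name})"
        )
    if aac.id != pssm.id:
        raise ValueError(f"id mismatch: {aac.id!r} vs {pssm.id!r}")
    return FeatureVector(aac.id, Schema.COMBO420, np.concatenate([aac.values, pssm.values]))


def feature_names(schema: Schema) -> list[str]:
    """Column names for a schema, in vector order."""
    if schema is Schema.AAC20:
        return list(CANONICAL_ALPHABET)
    if schema is Schema.DPC400:
        return list(DIPEPTIDES)
    if schema is Schema.PSSM400:
        return [f"{r}_{c}" for r in CANONICAL_ALPHABET for c in CANONICAL_ALPHABET]
    return list(CANONICAL_ALPHABET) + [
        f"{r}_{c}" for r in CANONICAL_ALPHABET for c in CANONICAL_ALPHABET
    ]


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors of one schema into a DataFrame indexed by id."""
    if not vectors:
        raise ValueError("no feature vectors given")
    schema = vectors[0].schema
    if any(v.schema is not schema for v in vectors):
        raise ValueError("mixed schemas in feature_frame")
    df = pd.DataFrame(
        np.stack([v.values for v in vectors]),
        index=pd.Index([v.id for v in vectors], name="id"),
        columns=feature_names(schema),
    )
    df.attrs["schema"] = schema.name
    return df


def write_features(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    """Write a feature matrix as headered CSV, id column first."""
    feature_frame(vectors).to_csv(path)


class CompositionEncoder(TransformerMixin, BaseEstimator):
    """Sequence-composition transformer (AAC or DPC) over protein records.

    Parameters
    ----------
    schema : {"aac", "dpc"}
        Which composition to compute; output has 20 or 400 columns.
    """

    def __init__(self, schema: str = "aac"):
        self.schema = schema

    def fit(self, X: Sequence[ProteinRecord], y=None) -> "CompositionEncoder":
        if self.schema not in ("aac", "dpc"):
            raise ValueError(f"schema must be 'aac' or 'dpc', got {self.schema!r}")
        self.schema_ = Schema.AAC20 if self.schema == "aac" else Schema.DPC400
        self.n_features_out_ = self.schema_.value
        return self

    def transform(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        if not hasattr(self, "schema_"):
            self.fit(X)
        fn = compute_aac if self.schema_ is Schema.AAC20 else compute_dpc
        return np.stack([fn(rec).values for rec in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.schema_))


class ProfileCompositionEncoder(TransformerMixin, BaseEstimator):
    """PSSM-400 transformer over :class:`PssmProfile` objects.

    Accepts raw (integer log-odds) profiles and normalizes them internally
    unless ``assume_normalized`` is set.  With ``with_aac=True`` the query
    sequence's AAC block is prepended, yielding the 420-length combination.
    """

    def __init__(self, with_aac: bool = False, assume_normalized: bool = False):
        self.with_aac = with_aac
        self.assume_normalized = assume_normalized

    def fit(self, X: Sequence[PssmProfile], y=None) -> "ProfileCompositionEncoder":
        self.schema_ = Schema.COMBO420 if self.with_aac else Schema.PSSM400
        self.n_features_out_ = self.schema_.value
        return self

    def transform(self, X: Sequence[PssmProfile]) -> np.ndarray:
        if not hasattr(self, "schema_"):
            self.fit(X)
        rows = []
        for prof in X:
            norm = prof if self.assume_normalized else normalize_pssm(prof)
            vec = compute_pssm400(norm)
            if self.with_aac:
                aac = compute_aac(ProteinRecord(prof.id, prof.sequence))
                vec = concat_features(aac, vec)
            rows.append(vec.values)
        return np.stack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.schema_))


def run_psiblast(
    record: ProteinRecord,
    database: str | Path,
    out_pssm: str | Path,
    iterations: int = 3,
    evalue: float = 1e-3,
) -> PssmProfile:
    """Generate an ASCII PSSM for one sequence by shelling out to psiblast.

    Optional helper for users with a local protein database; nothing else in
    the package depends on it.  Profiles are produced with ``iterations``
    rounds (default 3) and read back through :func:`parse_pssm`.
    """
    out_pssm = Path(out_pssm)
    with tempfile.TemporaryDirectory() as tmp:
        query = Path(tmp) / "query.fa"
        write_fasta([record], query)
        proc = subprocess.run(
            [
                "psiblast", "-query", str(query), "-db", str(database),
                "-num_iterations", str(iterations), "-evalue", str(evalue),
                "-out_ascii_pssm", str(out_pssm), "-out", str(Path(tmp) / "hits.txt"),
            ],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0 or not out_pssm.exists():
        raise RuntimeError(f"psiblast failed for {record.id!r}: {proc.stderr.strip()}")
    return parse_pssm(out_pssm, record_id=record.id)
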
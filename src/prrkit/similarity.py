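"""Similarity-based classification of proteins against a labeled reference set.

A query is searched against a database built from labeled training sequences;
any hit to a positive subject at the e-value cutoff calls the query positive
(positives take preference over negatives when both classes hit, because a
positive similarity hit is treated as near-certain evidence), otherwise any
hit calls it negative, and a query with no hit at all is left undecided
(``NO_HIT``) for a downstream model to classify.

Two engines implement the search: NCBI BLAST+ (``makeblastdb``/``blastp``,
used whenever the binaries are on PATH) and an in-process Smith–Waterman
aligner with BLOSUM62 and BLAST's protein gap costs (open 11, extend 1).  The
fallback is not BLAST — its e-values come from the classical Karlin–Altschul
formula with BLAST's default gapped parameters and no edge corrections — but
the two engines agree on the call for closely similar queries, and every
result records which engine produced it.
"""

from __future__ import annotations

import enum
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .seqio import Label, ProteinRecord, write_fasta

# Karlin-Altschul parameters for gapped BLOSUM62, gap open 11 / extend 1
# (BLAST+ protein defaults); used by the in-process engine only.
_GAPPED_LAMBDA = 0.267
_GAPPED_K = 0.041
_LN2 = log(2.0)


class Call(enum.Enum):
    """Decision of the similarity stage."""

    POS = "POS"
    NEG = "NEG"
    NO_HIT = "NO_HIT"


@dataclass(frozen=True)
class BlastHit:
    """One database hit with its subject's class label resolved."""

    query_id: str
    subject_id: str
    e_value: float
    bit_score: float
    subject_label: Label
    identity_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value}")


@dataclass(frozen=True)
class SimilarityCall:
    """The per-query decision plus the hit that decided it (absent for NO_HIT)."""

    query_id: str
    call: Call
    best_hit: BlastHit | None = None

    def __post_init__(self) -> None:
        if (self.call is Call.NO_HIT) != (self.best_hit is None):
            raise ValueError("best_hit must be present exactly when a hit was found")


@dataclass
class SimilarityReference:
    """A searchable labeled reference: sequences, id → label map, and engine."""

    records: list[ProteinRecord]
    labels: dict[str, Label]
    engine: str  # "blast" or "python"
    _db_dir: tempfile.TemporaryDirectory | None = field(default=None, repr=False)

    @property
    def db_path(self) -> str:
        if self._db_dir is None:
            raise RuntimeError("reference has no on-disk BLAST database")
        return str(Path(self._db_dir.name) / "reference")


def blast_available() -> bool:
    """Whether the BLAST+ binaries this module shells out to are on PATH."""
    return shutil.which("makeblastdb") is not None and shutil.which("blastp") is not None


def build_reference(
    records: Sequence[ProteinRecord], engine: str = "auto"
) -> SimilarityReference:
    """Build a searchable reference from labeled records.

    engine="auto" uses BLAST+ when available, otherwise the in-process
    aligner; "blast" and "python" force one engine.

    Raises
    ------
    ValueError
        If any record is unlabeled or a class is missing entirely.
    RuntimeError
        If makeblastdb fails (its stderr is included).
    """
    records = list(records)
    unlabeled = [r.id for r in records if r.label is Label.UNKNOWN]
    if unlabeled:
        raise ValueError(f"reference records must be labeled; unlabeled: {unlabeled[:5]}")
    labels = {r.id: r.label for r in records}
    present = set(labels.values())
    if present != {Label.POSITIVE, Label.NEGATIVE}:
        raise ValueError("reference needs at least one positive and one negative record")
    if engine == "auto":
        engine = "blast" if blast_available() else "python"
    if engine not in ("blast", "python"):
        raise ValueError(f"unknown engine {engine!r}")
    ref = SimilarityReference(records=records, labels=labels, engine=engine)
    if engine == "blast":
        db_dir = tempfile.TemporaryDirectory(prefix="prrkit_blastdb_")
        fasta = Path(db_dir.name) / "reference.fa"
        write_fasta(records, fasta)
        proc = subprocess.run(
            [
                "makeblastdb", "-in", str(fasta), "-dbtype", "prot",
                "-out", str(Path(db_dir.name) / "reference"),
            ],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"makeblastdb failed: {proc.stderr.strip()}")
        ref._db_dir = db_dir
    return ref


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_SW_ALIGNER = _local_aligner()


def _python_hits(
    queries: Sequence[ProteinRecord], ref: SimilarityReference, e_cutoff: float
) -> dict[str, list[BlastHit]]:
    db_residues = sum(len(r.sequence) for r in ref.records)
    hits: dict[str, list[BlastHit]] = {q.id: [] for q in queries}
    for query in queries:
        for subject in ref.records:
            if subject.id == query.id:
                continue  # self-hit exclusion
            raw = _SW_ALIGNER.score(query.sequence, subject.sequence)
            bits = (_GAPPED_LAMBDA * raw - log(_GAPPED_K)) / _LN2
            e_value = len(query.sequence) * db_residues * 2.0 ** (-bits)
            if e_value <= e_cutoff:
                hits[query.id].append(
                    BlastHit(
                        query_id=query.id,
                        subject_id=subject.id,
                        e_value=e_value,
                        bit_score=bits,
                        subject_label=ref.labels[subject.id],
                    )
                )
    return hits


def _blast_hits(
    queries: Sequence[ProteinRecord], ref: SimilarityReference, e_cutoff: float
) -> dict[str, list[BlastHit]]:
    hits: dict[str, list[BlastHit]] = {q.id: [] for q in queries}
    with tempfile.TemporaryDirectory(prefix="prrkit_blastq_") as tmp:
        query_fa = Path(tmp) / "queries.fa"
        write_fasta(queries, query_fa)
        proc = subprocess.run(
            [
                "blastp", "-query", str(query_fa), "-db", ref.db_path,
                "-evalue", repr(e_cutoff),
                "-outfmt", "6 qseqid sseqid pident length evalue bitscore",
            ],
            capture_output=True,
            text=True,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"blastp failed: {proc.stderr.strip()}")
    for line in proc.stdout.splitlines():
        qid, sid, pident, _length, evalue, bits = line.split("\t")
        if qid == sid:
            continue  # self-hit exclusion
        if qid not in hits:
            continue
        hits[qid].append(
            BlastHit(
                query_id=qid,
                subject_id=sid,
                e_value=float(evalue),
                bit_score=float(bits),
                subject_label=ref.labels[sid],
                identity_pct=float(pident),
            )
        )
    return hits


def _sort_hits(hit_list: list[BlastHit]) -> list[BlastHit]:
    return sorted(hit_list, key=lambda h: (h.e_value, -h.bit_score))


def search_many(
    queries: Sequence[ProteinRecord], ref: SimilarityReference, e_cutoff: float = 1e-3
) -> dict[str, list[BlastHit]]:
    """Search queries against the reference in one batch.

    Returns per-query hit lists with e-value <= ``e_cutoff``, self-hits
    (matching ids) removed, sorted by ascending e-value then descending bit
    score.
    """
    engine = _python_hits if ref.engine == "python" else _blast_hits
    return {qid: _sort_hits(h) for qid, h in engine(queries, ref, e_cutoff).items()}


def search(
    query: ProteinRecord, ref: SimilarityReference, e_cutoff: float = 1e-3
) -> list[BlastHit]:
    """Search a single query (see :func:`search_many`)."""
    return search_many([query], ref, e_cutoff)[query.id]


def classify_by_similarity(
    hits: Iterable[BlastHit], query_id: str | None = None, prefer_positive: bool = True
) -> SimilarityCall:
    """Turn a (pre-filtered) hit list into a POS / NEG / NO_HIT decision.

    With ``prefer_positive`` (default) any positive-labeled hit decides POS
    even when negative hits score better; otherwise the single best hit wins.
    The decision is invariant to the order of the input list.
    """
    hit_list = _sort_hits(list(hits))
    if not hit_list:
        return SimilarityCall(query_id=query_id or "", call=Call.NO_HIT)
    if prefer_positive:
        positives = [h for h in hit_list if h.subject_label is Label.POSITIVE]
        if positives:
            return SimilarityCall(positives[0].query_id, Call.POS, positives[0])
        return SimilarityCall(hit_list[0].query_id, Call.NEG, hit_list[0])
    best = hit_list[0]
    call = Call.POS if best.subject_label is Label.POSITIVE else Call.NEG
    return SimilarityCall(best.query_id, call, best)


def evalue_sweep(
    records: Sequence[ProteinRecord],
    folds: Sequence[tuple[Sequence[str], Sequence[str]]],
    e_values: Sequence[float],
    engine: str = "auto",
    prefer_positive: bool = True,
) -> pd.DataFrame:
    """Tally similarity calls per class at each e-value cutoff, pooled over folds.

    For every fold a reference is built from the training ids only and each
    test query is searched once at the loosest cutoff; tighter cutoffs are
    then applied by filtering the same hit lists, so the counts are nested by
    construction.  The output has one row per e-value with, per class, the
    correct-call count/percent, the wrong-call count/percent and the no-hit
    count/percent (correct + error + no-hit = 100 within each class).
    """
    e_values = sorted(e_values)
    by_id = {r.id: r for r in records}
    all_hits: dict[str, list[BlastHit]] = {}
    for train_ids, test_ids in folds:
        ref = build_reference([by_id[i] for i in train_ids], engine=engine)
        all_hits.update(search_many([by_id[i] for i in test_ids], ref, max(e_values)))
    test_records = [by_id[qid] for qid in all_hits]
    n_pos = sum(r.label is Label.POSITIVE for r in test_records)
    n_neg = sum(r.label is Label.NEGATIVE for r in test_records)
    rows = []
    for e_cutoff in e_values:
        tally = {
            (Label.POSITIVE, Call.POS): 0, (Label.POSITIVE, Call.NEG): 0,
            (Label.POSITIVE, Call.NO_HIT): 0, (Label.NEGATIVE, Call.POS): 0,
            (Label.NEGATIVE, Call.NEG): 0, (Label.NEGATIVE, Call.NO_HIT): 0,
        }
        for rec in test_records:
            kept = [h for h in all_hits[rec.id] if h.e_value <= e_cutoff]
            decision = classify_by_similarity(kept, rec.id, prefer_positive)
            tally[(rec.label, decision.call)] += 1
        rows.append(
            {
                "e_value": e_cutoff,
                "pos_correct": tally[(Label.POSITIVE, Call.POS)],
                "pos_error": tally[(Label.POSITIVE, Call.NEG)],
                "pos_nohit": tally[(Label.POSITIVE, Call.NO_HIT)],
                "neg_correct": tally[(Label.NEGATIVE, Call.NEG)],
                "neg_error": tally[(Label.NEGATIVE, Call.POS)],
                "neg_nohit": tally[(Label.NEGATIVE, Call.NO_HIT)],
            }
        )
    table = pd.DataFrame(rows)
    for col, total in [
        ("pos_correct", n_pos), ("pos_error", n_pos), ("pos_nohit", n_pos),
        ("neg_correct", n_neg), ("neg_error", n_neg), ("neg_nohit", n_neg),
    ]:
        table[col + "_pct"] = 100.0 * table[col] / total if total else np.nan
    return table


class BlastSimilarityClassifier(ClassifierMixin, BaseEstimator):
    """Similarity-search classifier over protein records.

    Fitting stores the labeled training sequences as the search reference;
    prediction searches each query and applies the POS/NEG/NO_HIT rule.
    Queries with no hit are assigned ``no_hit_label`` (default 0, the
    negative class) by :meth:`predict`; use :meth:`similarity_calls` to keep
    the three-way decision for hybrid fusion.

    Parameters
    ----------
    e_value : float
        Hit-significance cutoff (default 1e-3, the operating point at which
        a positive hit is near-certain evidence).
    engine : {"auto", "blast", "python"}
        Search backend; "auto" prefers BLAST+ when installed.
    prefer_positive : bool
        Whether any positive hit outranks better-scoring negative hits.
    """

    def __init__(
        self,
        e_value: float = 1e-3,
        engine: str = "auto",
        prefer_positive: bool = True,
        no_hit_label: int = 0,
    ):
        self.e_value = e_value
        self.engine = engine
        self.prefer_positive = prefer_positive
        self.no_hit_label = no_hit_label

    def fit(self, X: Sequence[ProteinRecord], y=None) -> "BlastSimilarityClassifier":
        records = list(X)
        if y is not None:
            y = np.asarray(y)
            records = [
                ProteinRecord(r.id, r.sequence, Label.POSITIVE if yi else Label.NEGATIVE)
                for r, yi in zip(records, y)
            ]
        self.reference_ = build_reference(records, engine=self.engine)
        self.classes_ = np.array([0, 1])
        return self

    def similarity_calls(self, X: Sequence[ProteinRecord]) -> list[SimilarityCall]:
        check_is_fitted(self, "reference_")
        hits = search_many(list(X), self.reference_, self.e_value)
        return [
            classify_by_similarity(hits[rec.id], rec.id, self.prefer_positive)
            for rec in X
        ]

    def predict(self, X: Sequence[ProteinRecord]) -> np.ndarray:
        out = []
        for decision in self.similarity_calls(X):
            if decision.call is Call.POS:
                out.append(1)
            elif decision.call is Call.NEG:
                out.append(0)
            else:
                out.append(self.no_hit_label)
        return np.asarray(out)
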
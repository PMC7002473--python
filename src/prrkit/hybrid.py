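"""Score fusion of similarity calls with classifier probabilities, and the
cross-validated evaluation that reports it.

The hybrid rule adds a fixed offset to the machine-learning positive-class
probability according to the similarity stage's decision: +0.5 for a positive
call, -0.5 for a negative call, 0 when the query had no hit.  The fused score
therefore lives in [-0.5, 1.5]; a query with a positive similarity hit is
pushed above almost any threshold (similarity evidence takes precedence) while
no-hit queries are classified by the model alone.

:func:`run_cv` orchestrates the full protocol: per fold, optional grid search
on the training subsets only, model fitting, a similarity reference built from
that fold's training sequences only, score fusion on the test fold, and
metrics at a threshold chosen on the training fold (or fixed by the caller).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .metrics import (
    ConfusionCounts,
    MetricsReport,
    compute_auroc,
    compute_metrics,
    confusion_at_threshold,
    matthews_cc,
)
from .models import ModelSpec, grid_search, train_classifier
from .seqio import Label, ProteinRecord
from .similarity import BlastSimilarityClassifier, Call, SimilarityCall

#: Offset added to the ML probability per similarity decision.
OFFSETS = {Call.POS: 0.5, Call.NEG: -0.5, Call.NO_HIT: 0.0}


@dataclass(frozen=True)
class HybridScore:
    """One query's fused prediction score."""

    id: str
    ml_probability: float
    blast_offset: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ml_probability <= 1.0:
            raise ValueError(
                f"ml_probability must be in [0, 1], got {self.ml_probability}"
            )
        if self.blast_offset not in (0.5, -0.5, 0.0):
            raise ValueError(f"blast_offset must be +0.5, -0.5 or 0, got {self.blast_offset}")

    @property
    def score(self) -> float:
        return self.ml_probability + self.blast_offset


def hybrid_score(p: float, call: SimilarityCall | Call) -> HybridScore:
    """Fuse an ML probability with a similarity decision.

    POS adds +0.5, NEG adds -0.5, NO_HIT leaves the probability unchanged.
    """
    decision = call.call if isinstance(call, SimilarityCall) else call
    query_id = call.query_id if isinstance(call, SimilarityCall) else ""
    return HybridScore(id=query_id, ml_probability=float(p), blast_offset=OFFSETS[decision])


def select_threshold(
    scores: Sequence[float], labels: Sequence[int], include: Sequence[float] = (0.5,)
) -> float:
    """Threshold maximizing MCC of the rule score >= t.

    Candidates are every distinct score (each reachable confusion matrix) plus
    the values in ``include`` (0.5 by default, so the selected threshold never
    scores below the conventional midpoint on the data it was tuned on).  Ties
    go to the smallest candidate, making selection deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    candidates = np.unique(np.concatenate([scores, np.asarray(include, dtype=float)]))
    best_t, best_mcc = None, -np.inf
    for t in candidates:
        mcc = matthews_cc(confusion_at_threshold(scores, labels, t))
        if mcc > best_mcc:
            best_t, best_mcc = float(t), mcc
    return best_t


@dataclass
class CVReport:
    """Per-fold and averaged metrics from a cross-validated run."""

    per_fold: list[MetricsReport]
    mean: MetricsReport
    pooled: MetricsReport
    predictions: pd.DataFrame  # id, fold, label, ml_probability, blast_offset, score
    sweep: pd.DataFrame  # pooled metrics over a grid of thresholds
    specs: list[ModelSpec]
    fingerprints: list[str] = field(default_factory=list)  # per-fold training-data hashes

    def to_frame(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.per_fold]
        df = pd.DataFrame(rows, index=[f"fold{i + 1}" for i in range(len(rows))])
        df.loc["mean"] = self.mean.as_dict()
        return df

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "per_fold": [m.as_dict() for m in self.per_fold],
                "mean": self.mean.as_dict(),
                "pooled": self.pooled.as_dict(),
                "specs": [
                    {"algorithm": s.algorithm, "hyperparameters": s.hyperparameters,
                     "seed": s.seed}
                    for s in self.specs
                ],
                "sweep": self.sweep.to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _inner_folds(
    train_ids: list[str],
    all_folds: Sequence[tuple[Sequence[str], Sequence[str]]],
    fold_index: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subset-out folds within a training set, as row indices."""
    pos_of = {seq_id: i for i, seq_id in enumerate(train_ids)}
    inner = []
    for s, (_, test_ids) in enumerate(all_folds):
        if s == fold_index:
            continue
        test_rows = np.asarray([pos_of[i] for i in test_ids if i in pos_of], dtype=int)
        train_rows = np.asarray(
            sorted(set(range(len(train_ids))) - set(test_rows.tolist())), dtype=int
        )
        if len(test_rows) and len(train_rows):
            inner.append((train_rows, test_rows))
    return inner


def _fold_scores(records, probabilities, calls) -> list[HybridScore]:
    if calls is None:
        return [
            HybridScore(rec.id, float(p), 0.0) for rec, p in zip(records, probabilities)
        ]
    return [
        HybridScore(rec.id, float(p), OFFSETS[c.call])
        for rec, p, c in zip(records, probabilities, calls)
    ]


def run_cv(
    records: Sequence[ProteinRecord],
    X: np.ndarray,
    y: Sequence[int],
    folds: Sequence[tuple[Sequence[str], Sequence[str]]],
    *,
    algorithm: str = "RF",
    hyperparameters: Mapping | None = None,
    grid: Mapping[str, Sequence] | None = None,
    hybrid: bool = False,
    e_value: float = 1e-3,
    engine: str = "auto",
    threshold: float | str = "train-mcc",
    schema: str = "unspecified",
    seed: int = 42,
    sweep_step: float = 0.05,
) -> CVReport:
    """Cross-validated evaluation of a (optionally hybrid) classifier.

    ``records``, ``X`` and ``y`` are row-aligned; ``folds`` are (train ids,
    test ids) pairs from the homology-aware partition.  With ``grid`` set,
    each fold runs a grid search on leave-one-subset-out folds inside its own
    training set; with ``hyperparameters`` set, that fixed spec is used.  With
    ``hybrid=True`` a similarity reference is rebuilt per fold from training
    sequences only and the +0.5/-0.5/0 offsets are added to the test-fold
    probabilities.  ``threshold`` is either a number applied to every fold or
    "train-mcc" (pick the MCC-maximizing threshold on the training fold's own
    fused scores, then apply it unchanged to the test fold).
    """
    records = list(records)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    row_of = {rec.id: i for i, rec in enumerate(records)}
    per_fold: list[MetricsReport] = []
    specs: list[ModelSpec] = []
    fingerprints: list[str] = []
    pred_rows = []
    for j, (train_ids, test_ids) in enumerate(folds):
        overlap = set(train_ids) & set(test_ids)
        if overlap:
            raise ValueError(f"fold {j + 1}: id(s) in both train and test: {sorted(overlap)[:5]}")
        train_ids, test_ids = list(train_ids), list(test_ids)
        tr = np.asarray([row_of[i] for i in train_ids], dtype=int)
        te = np.asarray([row_of[i] for i in test_ids], dtype=int)
        if grid is not None:
            spec = grid_search(
                X[tr], y[tr], algorithm, grid, _inner_folds(train_ids, folds, j), seed
            )
        else:
            spec = ModelSpec(algorithm, dict(hyperparameters or {}), seed)
        specs.append(spec)
        model = train_classifier(X[tr], y[tr], spec, schema)
        fingerprints.append(model.fingerprint)
        train_records = [records[i] for i in tr]
        test_records = [records[i] for i in te]
        if hybrid:
            blast = BlastSimilarityClassifier(e_value=e_value, engine=engine)
            blast.fit(train_records, y[tr])
            test_calls = blast.similarity_calls(test_records)
            train_calls = blast.similarity_calls(train_records)
        else:
            test_calls = train_calls = None
        test_scores = _fold_scores(test_records, model.predict_proba(X[te]), test_calls)
        if threshold == "train-mcc":
            train_scores = _fold_scores(
                train_records, model.predict_proba(X[tr]), train_calls
            )
            t = select_threshold([s.score for s in train_scores], y[tr])
        else:
            t = float(threshold)
        values = np.asarray([s.score for s in test_scores])
        auroc = compute_auroc(values, y[te])
        per_fold.append(
            compute_metrics(confusion_at_threshold(values, y[te], t), auroc, t)
        )
        for rec, s in zip(test_records, test_scores):
            pred_rows.append(
                {
                    "id": rec.id,
                    "fold": j + 1,
                    "label": int(y[row_of[rec.id]]),
                    "ml_probability": s.ml_probability,
                    "blast_offset": s.blast_offset,
                    "score": s.score,
                    "threshold": t,
                }
            )
    predictions = pd.DataFrame(pred_rows)
    mean = MetricsReport(
        sens=float(np.mean([m.sens for m in per_fold])),
        spec=float(np.mean([m.spec for m in per_fold])),
        acc=float(np.mean([m.acc for m in per_fold])),
        mcc=float(np.mean([m.mcc for m in per_fold])),
        auroc=float(np.mean([m.auroc for m in per_fold])),
        threshold=float(np.mean([m.threshold for m in per_fold])),
    )
    # pooled aggregation: one confusion matrix over all folds' test predictions,
    # each at its own fold's threshold
    pooled_scores = predictions["score"].to_numpy()
    pooled_labels = predictions["label"].to_numpy()
    pooled_pred = (predictions["score"] >= predictions["threshold"]).to_numpy()
    pooled_counts = ConfusionCounts(
        TP=int(np.sum(pooled_pred & (pooled_labels == 1))),
        TN=int(np.sum(~pooled_pred & (pooled_labels == 0))),
        FP=int(np.sum(pooled_pred & (pooled_labels == 0))),
        FN=int(np.sum(~pooled_pred & (pooled_labels == 1))),
    )
    pooled = compute_metrics(
        pooled_counts, compute_auroc(pooled_scores, pooled_labels), None
    )
    lo = min(-0.5 if hybrid else 0.0, float(pooled_scores.min()))
    hi = max(1.5 if hybrid else 1.0, float(pooled_scores.max()))
    sweep_rows = []
    for t_sweep in np.arange(lo, hi + sweep_step / 2, sweep_step):
        m = compute_metrics(
            confusion_at_threshold(pooled_scores, pooled_labels, t_sweep),
            threshold=float(t_sweep),
        )
        row = m.as_dict()
        row.pop("auroc")
        sweep_rows.append(row)
    return CVReport(
        per_fold=per_fold,
        mean=mean,
        pooled=pooled,
        predictions=predictions,
        sweep=pd.DataFrame(sweep_rows),
        specs=specs,
        fingerprints=fingerprints,
    )


class HybridClassifier(ClassifierMixin, BaseEstimator):
    """Similarity-plus-model classifier over (features, sequences) pairs.

    Wraps any probabilistic scikit-learn classifier fitted on a feature
    matrix, and a :class:`BlastSimilarityClassifier` fitted on the raw
    sequences; :meth:`decision_function` returns the fused score
    ``p + offset`` and :meth:`predict` thresholds it.

    The protein records travel through the ``records`` keyword of ``fit`` /
    ``decision_function`` / ``predict``; without them (or with
    ``use_similarity=False``) the classifier degrades exactly to its wrapped
    model, since a 0 offset is the identity on scores.
    """

    def __init__(
        self,
        estimator=None,
        e_value: float = 1e-3,
        engine: str = "auto",
        use_similarity: bool = True,
        threshold: float = 0.5,
    ):
        self.estimator = estimator
        self.e_value = e_value
        self.engine = engine
        self.use_similarity = use_similarity
        self.threshold = threshold

    def fit(self, X, y, records: Sequence[ProteinRecord] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        base = self.estimator
        if base is None:
            base = RandomForestClassifier(n_estimators=100, random_state=42)
        self.estimator_ = clone(base)
        self.estimator_.fit(X, y)
        self.similarity_ = None
        if self.use_similarity and records is not None:
            self.similarity_ = BlastSimilarityClassifier(
                e_value=self.e_value, engine=self.engine
            )
            self.similarity_.fit(list(records), y)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(
        self, X, records: Sequence[ProteinRecord] | None = None
    ) -> np.ndarray:
        check_is_fitted(self, "estimator_")
        X = np.asarray(X, dtype=float)
        proba = self.estimator_.predict_proba(X)
        p = proba[:, list(self.estimator_.classes_).index(1)]
        if self.similarity_ is None or records is None:
            return p
        calls = self.similarity_.similarity_calls(list(records))
        return p + np.asarray([OFFSETS[c.call] for c in calls])

    def predict(self, X, records: Sequence[ProteinRecord] | None = None) -> np.ndarray:
        return (self.decision_function(X, records) >= self.threshold).astype(int)
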
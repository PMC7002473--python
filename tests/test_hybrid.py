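import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prrkit.features import CompositionEncoder
from prrkit.hybrid import (
    OFFSETS,
    HybridClassifier,
    HybridScore,
    hybrid_score,
    run_cv,
    select_threshold,
)
from prrkit.metrics import confusion_at_threshold, matthews_cc
from prrkit.partition import Cluster, ClusterSet, make_cv_folds, round_robin_split
from prrkit.seqio import Label, ProteinRecord
from prrkit.similarity import Call, SimilarityCall
from prrkit.synthetic import SyntheticConfig, family_cluster_sets, generate_families
from tests.conftest import labels_of


class TestScoreFusion:
    @pytest.mark.parametrize(
        "call,expected",
        [(Call.POS, 1.2), (Call.NEG, 0.2), (Call.NO_HIT, 0.7)],
    )
    def test_offsets(self, call, expected):
        assert hybrid_score(0.7, call).score == pytest.approx(expected)

    def test_accepts_similarity_call_objects(self):
        call = SimilarityCall("q1", Call.NO_HIT)
        fused = hybrid_score(0.3, call)
        assert fused.id == "q1" and fused.score == 0.3

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            hybrid_score(1.2, Call.POS)

    @given(
        st.floats(0, 1, allow_nan=False),
        st.sampled_from([Call.POS, Call.NEG, Call.NO_HIT]),
    )
    def test_score_range_and_offset_semantics(self, p, call):
        fused = hybrid_score(p, call)
        assert -0.5 <= fused.score <= 1.5
        assert (fused.blast_offset == 0.0) == (call is Call.NO_HIT)

    def test_invalid_offset_rejected(self):
        with pytest.raises(ValueError, match="blast_offset"):
            HybridScore("q", 0.5, 0.25)


class TestThresholdSelection:
    def test_chosen_threshold_never_worse_than_midpoint(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, size=30)
            labels[:2] = [0, 1]
            t = select_threshold(scores, labels)
            mcc_at = lambda thr: matthews_cc(confusion_at_threshold(scores, labels, thr))
            assert mcc_at(t) >= mcc_at(0.5)

    def test_separable_scores_find_separating_threshold(self):
        t = select_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert 0.2 < t <= 0.8
        c = confusion_at_threshold([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], t)
        assert matthews_cc(c) == 1.0


@pytest.fixture(scope="module")
def cv_setup():
    cfg = SyntheticConfig(seed=42)
    records, family_of = generate_families(cfg)
    pos, neg = family_cluster_sets(records, family_of)
    folds = make_cv_folds(round_robin_split(pos, 5), round_robin_split(neg, 5))
    X = CompositionEncoder("aac").fit_transform(records)
    return records, X, labels_of(records), folds


class TestRunCv:
    def test_five_folds_give_five_metric_rows(self, cv_setup):
        records, X, y, folds = cv_setup
        report = run_cv(records, X, y, folds, algorithm="RF",
                        hyperparameters={"ne": 60}, threshold=0.5)
        assert len(report.per_fold) == 5
        assert len(report.to_frame()) == 6  # five folds + mean

    def test_leakage_is_an_error(self, cv_setup):
        records, X, y, folds = cv_setup
        train, test = folds[0]
        bad = [(list(train) + [test[0]], list(test))] + list(folds[1:])
        with pytest.raises(ValueError, match="both train and test"):
            run_cv(records, X, y, bad, algorithm="RF", hyperparameters={"ne": 60})

    def test_hybrid_off_equals_all_zero_offsets(self, cv_setup):
        records, X, y, folds = cv_setup
        pure = run_cv(records, X, y, folds, algorithm="RF",
                      hyperparameters={"ne": 60}, hybrid=False, threshold=0.5)
        assert (pure.predictions["blast_offset"] == 0.0).all()
        assert np.array_equal(
            pure.predictions["score"], pure.predictions["ml_probability"]
        )

    def test_train_mcc_threshold_reported_per_fold(self, cv_setup):
        records, X, y, folds = cv_setup
        report = run_cv(records, X, y, folds, algorithm="RF",
                        hyperparameters={"ne": 60}, threshold="train-mcc")
        assert all(m.threshold is not None for m in report.per_fold)

    def test_report_json_round_trips(self, cv_setup, tmp_path):
        import json

        records, X, y, folds = cv_setup
        report = run_cv(records, X, y, folds, algorithm="RF",
                        hyperparameters={"ne": 60}, threshold=0.5)
        payload = json.loads(report.to_json(tmp_path / "report.json"))
        assert len(payload["per_fold"]) == 5
        assert payload["mean"]["acc"] == pytest.approx(report.mean.acc)


def _singleton_folds(records):
    def singleton(recs):
        return ClusterSet(tuple(Cluster(i + 1, (r.id,)) for i, r in enumerate(recs)))

    pos = [r for r in records if r.label is Label.POSITIVE]
    neg = [r for r in records if r.label is Label.NEGATIVE]
    return make_cv_folds(
        round_robin_split(singleton(pos), 5), round_robin_split(singleton(neg), 5)
    )


def test_hybrid_fusion_helps_when_test_has_train_homologs():
    cfg = SyntheticConfig(n_pos_families=8, n_neg_families=8, seed=13)
    records, _ = generate_families(cfg)
    X = CompositionEncoder("aac").fit_transform(records)
    y = labels_of(records)
    folds = _singleton_folds(records)
    pure = run_cv(records, X, y, folds, algorithm="RF",
                  hyperparameters={"ne": 60}, hybrid=False, threshold=0.5)
    fused = run_cv(records, X, y, folds, algorithm="RF",
                   hyperparameters={"ne": 60}, hybrid=True, threshold=0.5)
    assert set(fused.predictions["blast_offset"]) == {0.5, -0.5}
    assert fused.mean.acc >= pure.mean.acc


def test_hybrid_with_no_hit_reference_reproduces_pure_ml_exactly():
    """All-NO_HIT similarity stage must be a bit-for-bit no-op on metrics."""
    cfg = SyntheticConfig(n_pos_families=5, n_neg_families=5,
                          members_per_family=3, seed=21)
    records, family_of = generate_families(cfg)
    X = CompositionEncoder("aac").fit_transform(records)
    y = labels_of(records)
    pos, neg = family_cluster_sets(records, family_of)
    folds = make_cv_folds(round_robin_split(pos, 5), round_robin_split(neg, 5))
    pure = run_cv(records, X, y, folds, algorithm="RF",
                  hyperparameters={"ne": 60}, hybrid=False, threshold=0.5)
    fused = run_cv(records, X, y, folds, algorithm="RF",
                   hyperparameters={"ne": 60}, hybrid=True, threshold=0.5)
    # homology-aware folds leave no cross-family homologs: every call is NO_HIT
    assert (fused.predictions["blast_offset"] == 0.0).all()
    for a, b in zip(pure.per_fold, fused.per_fold):
        assert a == b
    assert pure.mean == fused.mean


class TestHybridClassifierEstimator:
    def test_degrades_to_wrapped_model_without_records(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(2, 1, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        from sklearn.ensemble import RandomForestClassifier

        base = RandomForestClassifier(n_estimators=30, random_state=0)
        clf = HybridClassifier(estimator=base).fit(X, y)
        base.fit(X, y)
        assert np.allclose(clf.decision_function(X), base.predict_proba(X)[:, 1])

    def test_fused_scores_shift_by_offsets(self):
        cfg = SyntheticConfig(n_pos_families=4, n_neg_families=4,
                              members_per_family=3, length_range=(80, 120), seed=2)
        records, _ = generate_families(cfg)
        X = CompositionEncoder("aac").fit_transform(records)
        y = labels_of(records)
        clf = HybridClassifier().fit(X, y, records=records)
        plain = clf.decision_function(X)
        fused = clf.decision_function(X, records=records)
        diffs = np.round(fused - plain, 10)
        assert set(diffs).issubset({0.5, -0.5, 0.0})
        # exact training copies must be re-found by similarity (self-hits are
        # excluded, but family members remain)
        assert (clf.predict(X, records=records) == y).mean() > 0.9

    def test_sklearn_params_round_trip(self):
        clf = HybridClassifier(e_value=1e-5, use_similarity=False)
        assert clf.get_params()["e_value"] == 1e-5
        clf.set_params(threshold=0.7)
        assert clf.threshold == 0.7
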
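from dataclasses import replace

import numpy as np
import pytest

from hetlink.config import NegativesConfig, PipelineConfig, WalkConfig
from hetlink.heteronet import split_dataset
from hetlink.io_formats import ValidationError
from hetlink.model_eval import (
    PipelineResources,
    compute_metrics,
    cross_repeat_evaluate,
    decision_scores,
    roc_auc,
    train_classifier,
)
from hetlink.walks_embedding import PairFeatureSet


def u_statistic_auc(labels, scores):
    """Exhaustive pairwise-comparison oracle: P(random positive outranks random negative)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_confusion(labels, predictions):
    tp = fp = tn = fn = 0
    for y, yhat in zip(labels, predictions):
        if y == 1 and yhat == 1:
            tp += 1
        elif y == 0 and yhat == 1:
            fp += 1
        elif y == 0 and yhat == 0:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


class TestComputeMetrics:
    def test_hand_arithmetic_example(self):
        # TP=50, FP=10, TN=40, FN=0
        labels = [1] * 50 + [0] * 10 + [0] * 40
        preds = [1] * 50 + [1] * 10 + [0] * 40
        rep = compute_metrics(labels, preds)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (50, 10, 40, 0)
        assert rep.metrics["PRE"] == pytest.approx(0.8333, abs=1e-4)
        assert rep.metrics["REC"] == 1.0
        assert rep.metrics["SPE"] == pytest.approx(0.8)
        assert rep.metrics["ACC"] == pytest.approx(0.9)
        assert rep.metrics["F1"] == pytest.approx(0.9091, abs=1e-4)
        assert rep.metrics["MCC"] == pytest.approx(2000 / np.sqrt(60 * 50 * 50 * 40))

    def test_perfect_predictions(self):
        rep = compute_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert rep.metrics["ACC"] == 1.0
        assert rep.metrics["MCC"] == 1.0
        assert rep.metrics["F1"] == 1.0
        assert rep.undefined == ()

    def test_all_positive_predictor_on_balanced_labels(self):
        rep = compute_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert rep.metrics["SPE"] == 0.0
        assert rep.metrics["REC"] == 1.0
        assert rep.metrics["MCC"] == 0.0  # zero denominator convention
        assert "MCC" in rep.undefined

    def test_undefined_metrics_surface_as_none(self):
        rep = compute_metrics([1, 1, 0, 0], [0, 0, 0, 0])  # never predicts positive
        assert rep.metrics["PRE"] is None
        assert rep.metrics["F1"] is None
        assert {"PRE", "F1"} <= set(rep.undefined)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics([1, 0], [1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            n = int(rng.integers(2, 60))
            labels = rng.integers(0, 2, size=n)
            preds = rng.integers(0, 2, size=n)
            rep = compute_metrics(labels, preds)
            assert (rep.tp, rep.fp, rep.tn, rep.fn) == brute_force_confusion(labels, preds)
            assert rep.n_pairs == n

    def test_acc_identity_with_rec_and_spe(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            labels = rng.integers(0, 2, size=40)
            if len(np.unique(labels)) < 2:
                continue
            preds = rng.integers(0, 2, size=40)
            rep = compute_metrics(labels, preds)
            npos, nneg = labels.sum(), (1 - labels).sum()
            expected = (rep.metrics["REC"] * npos + rep.metrics["SPE"] * nneg) / (npos + nneg)
            assert rep.metrics["ACC"] == pytest.approx(expected)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_matches_u_statistic_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = 24
            labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            _, auc = roc_auc(labels, scores)
            assert auc == pytest.approx(u_statistic_auc(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)
        _, base = roc_auc(labels, scores)
        for f in (np.exp, lambda s: 3 * s + 7, lambda s: s**3):
            _, transformed = roc_auc(labels, f(scores))
            assert transformed == pytest.approx(base, abs=1e-12)

    def test_label_independent_scores_give_half(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(0, 2, size=2000)
        scores = rng.normal(size=2000)
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


def _feature_set(X, y):
    pairs = tuple((f"L{i}", f"P{i}") for i in range(len(X)))
    return PairFeatureSet(pairs=pairs, features=np.asarray(X, dtype=float), labels=np.asarray(y))


class TestClassifier:
    def test_linearly_separable_toy_reaches_training_accuracy_one(self):
        X = [[0, 0], [0.2, 0.1], [5, 5], [5.1, 4.8]]
        y = [0, 0, 1, 1]
        clf = train_classifier(_feature_set(X, y))
        assert (clf.predict(np.asarray(X)) == y).all()

    def test_contradictory_duplicates_cap_accuracy_at_half(self):
        X = [[1.0, 1.0]] * 4
        y = [0, 1, 0, 1]
        clf = train_classifier(_feature_set(X, y))
        acc = (clf.predict(np.asarray(X)) == y).mean()
        assert acc == 0.5

    def test_single_class_training_set_rejected(self):
        with pytest.raises(ValidationError, match="both classes"):
            train_classifier(_feature_set([[0, 0], [1, 1]], [1, 1]))

    def test_planted_clusters_held_out_accuracy(self):
        rng = np.random.default_rng(0)
        n = 200
        X = np.r_[rng.normal(0, 1, (n // 2, 8)), rng.normal(3, 1, (n // 2, 8))]
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        order = rng.permutation(n)
        X, y = X[order], y[order]
        clf = train_classifier(_feature_set(X[:150], y[:150]), seed=0)
        held_out = (clf.predict(X[150:]) == y[150:]).mean()
        assert held_out > 0.95
        assert decision_scores(clf, X[150:]).shape == (50,)


@pytest.fixture(scope="module")
def quick_config():
    """Smaller walk/embedding budget for fast end-to-end checks."""
    return replace(
        PipelineConfig().with_seed(5),
        walk=WalkConfig(num_walks=3, length=30),
        negatives=NegativesConfig(strategy="random", seed=5),
    )


class TestCrossRepeatEvaluate:
    def test_single_repeat_mean_equals_repeat_metrics(self, small_planted, quick_config):
        resources = PipelineResources(
            small_planted.lncRNAs, small_planted.proteins,
            small_planted.lnc_hits, small_planted.prot_hits, small_planted.localization,
        )
        ds = split_dataset(small_planted.positive_pairs, ratio=0.9, repeats=1, seed=5)
        report = cross_repeat_evaluate(ds, quick_config, resources)
        assert len(report.per_repeat) == 1
        rep = report.per_repeat[0]
        for name, value in report.mean.items():
            expected = rep.auc if name == "AUC" else rep.metrics[name]
            assert value == expected
        assert rep.n_pairs == len(rep.roc_points) - 1 or rep.n_pairs >= 1

    def test_report_serialization(self, small_planted, quick_config, tmp_path):
        resources = PipelineResources(
            small_planted.lncRNAs, small_planted.proteins,
            small_planted.lnc_hits, small_planted.prot_hits, small_planted.localization,
        )
        ds = split_dataset(small_planted.positive_pairs, ratio=0.9, repeats=1, seed=5)
        report = cross_repeat_evaluate(ds, quick_config, resources, artifacts_dir=tmp_path)
        assert (tmp_path / "report.json").exists()
        assert (tmp_path / "report.tsv").read_text().startswith("repeat\tTP\tFP")
        assert (tmp_path / "repeat0_test_features.tsv").exists()
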
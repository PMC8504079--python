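"""Metrics against brute-force oracles; CV plans; the shift diagnostic."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import aiocnn as ac
from aiocnn.errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    StratificationError,
    ValidationError,
)
from aiocnn.evaluation import ConfusionCounts, binary_report


def auc_by_pair_counting(labels, scores):
    """Exhaustive positive-negative pair comparison (ties count 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0
               for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestBinaryMetrics:
    def test_hand_worked_example(self):
        m = ac.binary_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_perfect_classifier(self):
        m = ac.binary_metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_zero_denominator_is_undefined_not_zero(self):
        m = ac.binary_metrics(ConfusionCounts(tp=0, fp=0, tn=4, fn=2))
        assert m.precision is None
        assert m.recall == 0.0

    def test_empty_counts_error(self):
        with pytest.raises(ValidationError):
            ac.binary_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_random_counts_match_direct_formulas(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, tn, fn = rng.integers(0, 30, size=4)
            if tp + fp + tn + fn == 0:
                continue
            m = ac.binary_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m.accuracy == (tp + tn) / (tp + fp + tn + fn)
            if tp + fp:
                assert m.precision == tp / (tp + fp)
            if tp + fn:
                assert m.recall == tp / (tp + fn)


class TestRocAuc:
    def test_perfect_separation(self):
        assert ac.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_tied_scores(self):
        assert ac.roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_single_class_error(self):
        with pytest.raises(DegenerateLabelsError):
            ac.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_matches_pair_counting_oracle_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = rng.integers(4, 31)
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            ours = ac.roc_auc(y, s)
            assert ours == pytest.approx(auc_by_pair_counting(y, s), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestOneVsRest:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y]
        rep = ac.one_vs_rest_report(y, probs)
        assert rep.overall["accuracy"] == 1.0
        for c in range(3):
            assert rep.per_class[c]["recall"] == 1.0
            assert rep.per_class[c]["auc"] == 1.0

    def test_uniform_probabilities_tie_break_to_class_zero(self):
        y = np.array([0, 1, 2, 1])
        probs = np.full((4, 3), 1 / 3)
        rep = ac.one_vs_rest_report(y, probs)
        assert rep.per_class[0]["recall"] == 1.0
        assert rep.per_class[1]["recall"] == 0.0
        assert rep.per_class[2]["recall"] == 0.0

    def test_per_class_auc_matches_pair_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 3, size=30)
        raw = rng.random((30, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        rep = ac.one_vs_rest_report(y, probs)
        for c in range(3):
            oracle = auc_by_pair_counting((y == c).astype(int), probs[:, c])
            assert rep.per_class[c]["auc"] == pytest.approx(oracle, abs=1e-12)

    def test_off_simplex_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            ac.one_vs_rest_report(np.array([0, 1]), np.array([[0.9, 0.9], [0.1, 0.1]]))

    def test_per_class_accuracy_is_class_recall(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 3, size=60)
        raw = rng.random((60, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        rep = ac.one_vs_rest_report(y, probs)
        calls = np.argmax(probs, axis=1)
        for c in range(3):
            expected = np.mean(calls[y == c] == c)
            assert rep.per_class[c]["accuracy"] == pytest.approx(expected)


class TestWeightedAverage:
    def test_equal_metrics_return_themselves(self):
        assert ac.weighted_average([0.8, 0.8, 0.8], [0.2, 0.5, 0.3]) == pytest.approx(0.8)

    def test_direct_arithmetic(self):
        assert ac.weighted_average([1.0, 0.5, 0.0], [0.5, 0.3, 0.2]) == pytest.approx(0.65)

    def test_one_hot_frequencies_select_the_class_metric(self):
        assert ac.weighted_average([0.3, 0.7, 0.9], [0.0, 1.0, 0.0]) == pytest.approx(0.7)

    def test_weighted_recall_equals_categorical_accuracy(self):
        # per-class recall weighted by class frequency telescopes to the
        # overall fraction correct, for any confusion structure
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.integers(0, 3, size=50)
            calls = rng.integers(0, 3, size=50)
            recalls = [np.mean(calls[y == c] == c) if np.any(y == c) else 0.0
                       for c in range(3)]
            freqs = [np.mean(y == c) for c in range(3)]
            assert ac.weighted_average(recalls, freqs) == pytest.approx(
                np.mean(calls == y))

    def test_binary_weighted_equals_overall(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=80)
        p = rng.random(80)
        rep = binary_report(y, p)
        assert rep.weighted["accuracy"] == pytest.approx(rep.overall["accuracy"])
        assert rep.weighted["recall"] == pytest.approx(rep.overall["accuracy"])


class TestStratifiedKFold:
    def test_equal_fold_sizes(self):
        y = np.repeat([0, 1], 50)
        plan = ac.stratified_kfold(y, k=5, seed=0)
        sizes = [plan.test_indices(j).size for j in range(5)]
        assert sizes == [20] * 5

    def test_class_balance_preserved(self):
        y = np.repeat([1, 0], [60, 40])
        plan = ac.stratified_kfold(y, k=5, seed=1)
        for j in range(5):
            pos = int(y[plan.test_indices(j)].sum())
            assert abs(pos - 12) <= 1

    def test_partition_property(self):
        y = np.tile([0, 1, 2], 21)
        plan = ac.stratified_kfold(y, k=5, seed=2)
        all_idx = np.concatenate([plan.test_indices(j) for j in range(5)])
        assert sorted(all_idx) == list(range(len(y)))

    def test_small_class_rejected(self):
        with pytest.raises(StratificationError):
            ac.stratified_kfold(np.array([0, 0, 0, 1, 1, 1, 0, 0]), k=5)

    def test_seed_determinism(self):
        y = np.repeat([0, 1], 30)
        a = ac.stratified_kfold(y, k=5, seed=9)
        b = ac.stratified_kfold(y, k=5, seed=9)
        np.testing.assert_array_equal(a.fold, b.fold)


class TestDiagnoseConsistency:
    def _mat(self, vals, genes=None):
        vals = np.asarray(vals, dtype=float)
        genes = genes or [f"g{j}" for j in range(vals.shape[1])]
        return ac.ExpressionMatrix(
            [f"s{i}" for i in range(vals.shape[0])], genes, vals, scale="log2"
        )

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(6)
        mat = self._mat(rng.normal(5, 2, size=(10, 50)))
        assert ac.diagnose_consistency(mat, mat) == pytest.approx(1.0)

    def test_anticorrelated_construction(self):
        rng = np.random.default_rng(7)
        a = rng.normal(5, 2, size=(10, 50))
        mat_a = self._mat(a)
        mat_b = self._mat(10 - a)  # per-gene means reflected
        assert ac.diagnose_consistency(mat_a, mat_b) < 0

    def test_calibrated_noise_hits_target(self):
        rng = np.random.default_rng(8)
        means = rng.normal(5, 2, size=2000)
        a = self._mat(means[None, :].repeat(3, axis=0))
        target = 0.8
        noise_sd = means.std() * np.sqrt(1 / target**2 - 1)
        b = self._mat((means + rng.normal(0, noise_sd, 2000))[None, :].repeat(3, 0))
        r = ac.diagnose_consistency(a, b)
        assert 0.75 <= r <= 0.85

    def test_too_few_shared_genes(self):
        a = self._mat(np.ones((2, 2)), genes=["x", "y"])
        b = self._mat(np.ones((2, 2)), genes=["y", "z"])
        with pytest.raises(InsufficientDataError):
            ac.diagnose_consistency(a, b)


class TestCrossValidationProtocol:
    def test_pooled_predictions_cover_every_sample_once(self, tiny_spec_2d):
        rng = np.random.default_rng(9)
        n = 60
        aios = rng.integers(0, 256, size=(n, 1, 8, 8)).astype(np.uint8)
        y = np.tile([0, 1], n // 2)
        builder = lambda s: ac.build_2d_classifier(tiny_spec_2d, s)  # noqa: E731
        cfg = ac.TrainConfig(epochs=2, seed=0, validation_fraction=0.0, patience=0)
        report = ac.cross_validate(aios, y, builder, cfg, k=5, seed=0)
        assert report.n == n
        assert sum(f["n_test"] for f in report.per_fold) == n

    def test_gene_order_mismatch_fails_before_training(self, tiny_spec_2d):
        aios = np.zeros((4, 1, 8, 8), dtype=np.uint8)
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValidationError):
            ac.external_test(
                aios, y, aios, y,
                builder=lambda s: ac.build_2d_classifier(tiny_spec_2d, s),
                train_gene_order=["a", "b"], test_gene_order=["b", "a"],
            )


class TestExternalTestDiagnostic:
    def test_consistency_r_attached_when_expression_given(self, tiny_spec_2d):
        rng = np.random.default_rng(10)
        aios = rng.integers(0, 256, size=(40, 1, 8, 8)).astype(np.uint8)
        y = np.tile([0, 1], 20)
        expr = ac.ExpressionMatrix(
            [f"s{i}" for i in range(4)], [f"g{j}" for j in range(10)],
            rng.gamma(1, 5, size=(4, 10)))
        report = ac.external_test(
            aios, y, aios, y,
            builder=lambda s: ac.build_2d_classifier(tiny_spec_2d, s),
            cfg=ac.TrainConfig(epochs=1, seed=0, validation_fraction=0.0,
                               patience=0),
            train_expression=expr, test_expression=expr,
        )
        assert report.consistency_r == pytest.approx(1.0)
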
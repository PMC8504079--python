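"""Classifier construction, training behavior and repeated runs."""

import numpy as np
import pytest

import aiocnn as ac
from aiocnn.errors import ConfigError, DegenerateLabelsError, ShapeError


def random_aios(n, shape=(1, 8, 8), seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(0, 256, size=(n, *shape)).astype(np.uint8)


def separable_aios(n, shape=(1, 8, 8), seed=0, lo=60, hi=180, spread=30):
    """Two classes distinguished by mean pixel intensity."""
    rng = np.random.default_rng(seed)
    y = np.tile([0, 1], n // 2)
    base = np.where(y == 0, lo, hi)[:, None, None, None]
    vals = base + rng.normal(0, spread, size=(n, *shape))
    return np.clip(vals, 0, 255).astype(np.uint8), y


class TestBuilders:
    def test_binary_output_is_a_probability(self, tiny_spec_2d):
        m = ac.build_2d_classifier(tiny_spec_2d, seed=0)
        p = ac.predict_proba(m, random_aios(10)).probs
        assert p.shape == (10,)
        assert np.all((p >= 0) & (p <= 1))

    def test_multiclass_output_on_simplex(self, tiny_spec_2d):
        from dataclasses import replace

        spec = replace(tiny_spec_2d, n_classes=3)
        m = ac.build_2d_classifier(spec, seed=0)
        p = ac.predict_proba(m, random_aios(7)).probs
        assert p.shape == (7, 3)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_architecture_summary_counts_stages(self, tiny_spec_2d):
        m = ac.build_2d_classifier(tiny_spec_2d, seed=0)
        summary = m.summary()
        assert summary.count("Conv2D") == 7       # six 3x3 + one 1x1
        assert summary.count("Dense") == 4        # four fully connected
        assert "HistogramEmbedding" in summary

    def test_seed_fixes_initial_parameters(self, tiny_spec_2d):
        a = ac.build_2d_classifier(tiny_spec_2d, seed=5)
        b = ac.build_2d_classifier(tiny_spec_2d, seed=5)
        for wa, wb in zip(a.get_weights(), b.get_weights()):
            for k in wa:
                np.testing.assert_array_equal(wa[k], wb[k])

    def test_shape_mismatch_is_reported(self, tiny_spec_2d):
        m = ac.build_2d_classifier(tiny_spec_2d, seed=0)
        with pytest.raises(ShapeError, match="expects"):
            ac.predict_proba(m, random_aios(3, shape=(1, 16, 16)))

    def test_1d_accepts_the_same_genes_as_a_sequence(self):
        spec1d = ac.ModelSpec(
            input_shape=(64, 1), n_classes=2,
            conv_filters=(2, 2, 3, 3, 4, 4), conv1x1_filters=4,
            dense_widths=(8, 6, 4), embedding_dim=3,
            global_pool=False, batch_norm=False, dropout=0.0,
        )
        m = ac.build_1d_classifier(spec1d, seed=0)
        p = ac.predict_proba(m, random_aios(5, shape=(1, 8, 8))).probs
        assert p.shape == (5,)
        assert np.all((p >= 0) & (p <= 1))

    def test_wrong_stage_count_rejected(self):
        with pytest.raises(ConfigError):
            ac.ModelSpec(input_shape=(1, 8, 8), conv_filters=(2, 2, 3))

    def test_untrained_accuracy_is_chance_level(self, tiny_spec_2d):
        for seed in range(3):
            aios = random_aios(200, seed=seed)
            y = np.tile([0, 1], 100)
            m = ac.build_2d_classifier(tiny_spec_2d, seed=seed)
            calls = ac.predict_proba(m, aios).calls()
            acc = np.mean(calls == y)
            assert 0.35 <= acc <= 0.65


class TestTraining:
    def test_separable_toy_loss_decreases_and_fits(self, tiny_spec_2d):
        aios, y = separable_aios(80)
        m = ac.build_2d_classifier(tiny_spec_2d, seed=0)
        hist = ac.train_model(
            m, aios, y,
            ac.TrainConfig(learning_rate=1e-2, lr_decay=1.0, epochs=15, seed=0,
                           validation_fraction=0.0, patience=0),
        )
        assert hist["loss"][-1] < hist["loss"][0]
        calls = ac.predict_proba(m, aios).calls()
        assert np.mean(calls == y) >= 0.95

    def test_training_is_reproducible_for_fixed_seed(self, tiny_spec_2d):
        aios, y = separable_aios(40)
        weights = []
        for _ in range(2):
            m = ac.build_2d_classifier(tiny_spec_2d, seed=3)
            ac.train_model(m, aios, y, ac.TrainConfig(epochs=3, seed=3))
            weights.append(m.get_weights())
        for wa, wb in zip(*weights):
            for k in wa:
                np.testing.assert_array_equal(wa[k], wb[k])

    def test_single_class_labels_rejected(self, tiny_spec_2d):
        aios = random_aios(10)
        m = ac.build_2d_classifier(tiny_spec_2d, seed=0)
        with pytest.raises(DegenerateLabelsError):
            ac.train_model(m, aios, np.ones(10, dtype=int))

    def test_1d_learns_the_separable_toy(self):
        spec = ac.ModelSpec(
            input_shape=(64, 1), n_classes=2,
            conv_filters=(2, 2, 3, 3, 4, 4), conv1x1_filters=4,
            dense_widths=(8, 6, 4), embedding_dim=3,
            global_pool=False, batch_norm=False, dropout=0.0,
        )
        aios, y = separable_aios(80)
        m = ac.build_1d_classifier(spec, seed=0)
        ac.train_model(m, aios, y, ac.TrainConfig(
            learning_rate=1e-2, lr_decay=1.0, epochs=15, seed=0,
            validation_fraction=0.0, patience=0))
        calls = ac.predict_proba(m, aios).calls()
        assert np.mean(calls == y) >= 0.95


class TestPredictionCalls:
    def test_binary_threshold_is_strict(self):
        ps = ac.PredictionSet(["a", "b", "c"], np.array([0.5, 0.5001, 0.4999]))
        assert ps.calls().tolist() == [0, 1, 0]

    def test_multiclass_tie_breaks_to_lowest_index(self):
        ps = ac.PredictionSet(["a"], np.array([[0.4, 0.4, 0.2]]))
        assert ps.calls().tolist() == [0]


class TestRepeatedRuns:
    def test_distinct_seeds_and_summary_bookkeeping(self):
        calls = []

        def run(cfg):
            calls.append(cfg.seed)
            return {"accuracy": 0.8 + 0.01 * cfg.seed}

        ens = ac.repeated_runs(run, ac.TrainConfig(seed=0), n_runs=5)
        assert len(ens.runs) == 5
        assert len(set(calls)) == 5
        mean, sd = ens.summary()["accuracy"]
        vals = [r.metrics["accuracy"] for r in ens.runs]
        assert mean == pytest.approx(np.mean(vals))
        assert sd == pytest.approx(np.std(vals))

    def test_identical_runs_have_zero_sd_and_warn(self):
        def run(cfg):
            return {"auc": 0.9}

        with pytest.warns(UserWarning, match="identical"):
            ens = ac.repeated_runs(run, ac.TrainConfig(seed=1), n_runs=3,
                                   perturbations=[{}, {}, {}])
        assert ens.summary()["auc"] == (0.9, 0.0)

    def test_explicit_hyperparameter_perturbations_apply(self):
        seen = []

        def run(cfg):
            seen.append((cfg.learning_rate, cfg.seed))
            return {"f1": 0.5}

        ac.repeated_runs(
            run, ac.TrainConfig(seed=0), n_runs=2,
            perturbations=[{"learning_rate": 2e-3, "seed": 10},
                           {"learning_rate": 5e-4, "seed": 11}],
        )
        assert seen == [(2e-3, 10), (5e-4, 11)]


class TestModelPersistence:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path,
                                                        tiny_spec_2d):
        aios, y = separable_aios(40)
        m = ac.build_2d_classifier(tiny_spec_2d, seed=0)
        ac.train_model(m, aios, y, ac.TrainConfig(epochs=3, seed=0))
        path = tmp_path / "model.npz"
        ac.save_model(m, path)
        loaded = ac.load_model(path)
        np.testing.assert_array_equal(
            ac.predict_proba(m, aios).probs,
            ac.predict_proba(loaded, aios).probs,
        )
        assert loaded.train_config == m.train_config

    def test_save_load_with_batch_norm(self, tmp_path):
        from dataclasses import replace

        spec = replace(ac.ModelSpec(input_shape=(1, 8, 8), n_classes=2,
                                    conv_filters=(2, 2, 3, 3, 4, 4),
                                    conv1x1_filters=4, dense_widths=(8, 6, 4),
                                    embedding_dim=3))
        aios, y = separable_aios(40)
        m = ac.build_2d_classifier(spec, seed=1)
        ac.train_model(m, aios, y, ac.TrainConfig(epochs=2, seed=1))
        ac.save_model(m, tmp_path / "bn.npz")
        loaded = ac.load_model(tmp_path / "bn.npz")
        np.testing.assert_array_equal(
            ac.predict_proba(m, aios).probs,
            ac.predict_proba(loaded, aios).probs,
        )
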
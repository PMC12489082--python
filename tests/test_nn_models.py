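"""Learners: CNN engine correctness, XGBoost wrappers, persistence,
fine-tuning mechanics."""

import numpy as np
import pytest

from beltscan import models as M
from beltscan import nn
from beltscan.errors import DimensionError, ValidationError
from beltscan.resampling import LabeledTable


def feature_table(n0, n1, sep=5.0, dim=128, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(size=(n0, dim)),
                   rng.normal(loc=sep, size=(n1, dim))])
    y = np.array([0] * n0 + [1] * n1)
    return LabeledTable(X, y, [f"c{i}" for i in range(n0 + n1)])


def tiny_images(n, size=16, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, size, size, 3)).astype(np.float32)
    y = X.mean(axis=(1, 2, 3)) * 10.0
    return LabeledTable(X, y, [f"img{i}" for i in range(n)])


class TestCnnEngine:
    def test_parameter_count_is_well_below_100k(self):
        model = nn.SmallCNN()
        assert model.n_parameters < 100_000

    def test_gradients_match_numerical_differentiation(self):
        """Backprop through the full stack agrees with finite differences."""
        rng = np.random.default_rng(0)
        model = nn.SmallCNN(channels=(2, 3), dense_units=4, seed=1)
        X = rng.uniform(size=(2, 8, 8, 3)).astype(np.float32)
        y = np.array([1.0, 3.0], dtype=np.float32)

        def loss_value():
            out = model.forward(X, train=True)
            val, dout = nn.mse_loss(out, y)
            return val, dout

        val, dout = loss_value()
        model.backward(dout)
        analytic = [g.copy() for g in model.grads]
        eps = 1e-3
        for pi in (0, 2, 5):  # a conv kernel, a bias, a dense weight
            p = model.params[pi]
            flat_idx = p.size // 2
            idx = np.unravel_index(flat_idx, p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up, _ = loss_value()
            p[idx] = orig - eps
            down, _ = loss_value()
            p[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert analytic[pi][idx] == pytest.approx(numeric, rel=2e-2, abs=1e-4)

    def test_training_loss_decreases_on_a_smoke_set(self):
        t = tiny_images(20)
        model = nn.SmallCNN(seed=0)
        history = nn.fit(model, t.X, t.y, epochs=5, batch_size=8, seed=0)
        assert history[1] < history[0]
        assert history[2] < history[1]

    def test_single_image_is_memorized(self):
        t = tiny_images(1, seed=2)
        X = np.repeat(t.X, 8, axis=0)
        y = np.repeat(t.y, 8)
        model = nn.SmallCNN(seed=0)
        nn.fit(model, X, y, epochs=60, batch_size=8, lr=3e-3, seed=0)
        pred = nn.predict(model, X[:1])
        assert abs(pred[0] - y[0]) < 0.3 * max(abs(y[0]), 1.0)

    def test_works_at_any_input_resolution(self):
        model = nn.SmallCNN(seed=0)
        for size in (16, 32):
            out = model.forward(np.zeros((2, size, size, 3), np.float32))
            assert out.shape == (2,)


class TestXgbModels:
    def test_separated_classes_reach_perfect_training_accuracy(self):
        t = feature_table(40, 40)
        bundle = M.train_xgb_detector(t, seed=0)
        pred = M.predict(bundle, t)
        assert np.mean(pred.labels == t.y) == 1.0
        assert np.all((pred.proba > 0) & (pred.proba < 1))

    def test_detector_config_defaults_echoed_in_manifest(self):
        bundle = M.train_xgb_detector(feature_table(20, 20), seed=0)
        assert bundle.manifest["config"] == {
            "n_estimators": 10, "max_depth": 3, "eta": 0.3, "subsample": 0.5
        }

    def test_size_config_defaults(self):
        assert (M.XGB_SIZE_CONFIG.n_estimators, M.XGB_SIZE_CONFIG.max_depth) == (
            1000, 4)

    def test_wrong_feature_length_is_a_dimension_error(self):
        t = feature_table(10, 10, dim=64)
        with pytest.raises(DimensionError):
            M.train_xgb_detector(t)

    def test_constant_targets_are_recovered(self):
        rng = np.random.default_rng(0)
        t = LabeledTable(rng.normal(size=(30, 128)), np.full(30, 7.5),
                         [f"c{i}" for i in range(30)])
        bundle = M.train_xgb_size(t, M.DetectorConfig(50, 3, 0.3, 1.0), seed=0)
        pred = M.predict(bundle, t)
        np.testing.assert_allclose(pred.sizes_mm, 7.5, atol=0.1)

    def test_negative_targets_rejected(self):
        t = LabeledTable(np.zeros((10, 128)), np.full(10, -1.0),
                         [f"c{i}" for i in range(10)])
        with pytest.raises(ValidationError):
            M.train_xgb_size(t)

    def test_prediction_is_batch_order_invariant(self):
        t = feature_table(15, 15)
        bundle = M.train_xgb_detector(t, seed=0)
        perm = np.random.default_rng(1).permutation(len(t))
        p_full = M.predict(bundle, t).proba
        p_perm = M.predict(bundle, t.subset(perm)).proba
        np.testing.assert_array_equal(p_perm, p_full[perm])


class TestCnnModels:
    def test_detector_outputs_probabilities_and_labels(self):
        bundle = M.build_cnn("detector", M.CnnConfig(input_size=(16, 16, 3)))
        X = np.random.default_rng(0).uniform(size=(4, 16, 16, 3)).astype(np.float32)
        pred = M.predict(bundle, X)
        assert np.all((pred.proba > 0) & (pred.proba < 1))
        assert set(pred.labels) <= {0, 1}

    def test_size_head_is_unconstrained(self):
        bundle = M.build_cnn("size", M.CnnConfig(input_size=(16, 16, 3)))
        X = np.random.default_rng(0).uniform(size=(4, 16, 16, 3)).astype(np.float32)
        pred = M.predict(bundle, X)
        assert pred.sizes_mm.shape == (4,)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            M.build_cnn("segmenter")


class TestPersistence:
    def test_xgb_round_trip_preserves_predictions(self, tmp_path):
        t = feature_table(25, 25)
        bundle = M.train_xgb_detector(t, seed=0)
        hold = feature_table(25, 25, seed=9)
        M.save_bundle(bundle, tmp_path / "det")
        back = M.load_bundle(tmp_path / "det")
        np.testing.assert_array_equal(M.predict(back, hold).proba,
                                      M.predict(bundle, hold).proba)

    def test_cnn_round_trip_preserves_predictions(self, tmp_path):
        cfg = M.CnnConfig(input_size=(16, 16, 3), epochs=2)
        bundle = M.build_cnn("size", cfg, seed=3)
        t = tiny_images(6)
        M.train_cnn(bundle, t, cfg, seed=0)
        M.save_bundle(bundle, tmp_path / "cnn")
        back = M.load_bundle(tmp_path / "cnn")
        np.testing.assert_array_equal(M.predict(back, t).sizes_mm,
                                      M.predict(bundle, t).sizes_mm)


class TestFinetuning:
    @staticmethod
    def processed_cases(grid, n=12):
        import beltscan as bs
        from conftest import make_tumor_scenario

        cases = []
        for i, d in enumerate(np.linspace(4, 40, n)):
            scen = make_tumor_scenario(float(d))
            body, empty = bs.simulate_sweep(scen, grid=grid)
            sweep = bs.preprocess_case(body, empty)
            cases.append(M.ProcessedCase(f"p{i}", sweep, float(d),
                                         int(d > 8.0)))
        return cases

    def test_zero_noise_finetune_barely_moves_predictions(self, grid64):
        cases = self.processed_cases(grid64)
        X = np.array([M.default_featurizer(c.sweep) for c in cases])
        y = np.array([c.diameter_mm / 2 for c in cases])
        t = LabeledTable(X, y, [c.case_id for c in cases])
        bundle = M.train_xgb_size(t, M.DetectorConfig(200, 4, 0.3, 1.0), seed=0)
        tuned = M.finetune_with_noise(bundle, cases, noise_levels=(0.0,),
                                      fraction=1.0, seed=0)
        before = M.predict(bundle, t).sizes_mm
        after = M.predict(tuned, t).sizes_mm
        assert np.max(np.abs(after - before)) < 0.5

    def test_bad_fraction_rejected(self, grid64):
        cases = self.processed_cases(grid64, n=4)
        t = LabeledTable(
            np.array([M.default_featurizer(c.sweep) for c in cases]),
            np.array([c.label for c in cases]), [c.case_id for c in cases],
        )
        bundle = M.train_xgb_detector(t, seed=0)
        with pytest.raises(ValidationError):
            M.finetune_with_noise(bundle, cases, fraction=1.5)

    def test_perturbation_level_zero_is_identity(self):
        x = np.arange(10.0)
        out = M.perturb_values(x, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)
        out10 = M.perturb_values(x, 0.10, np.random.default_rng(0))
        assert np.all(np.abs(out10 - x) <= 0.10 * np.abs(x) + 1e-12)
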
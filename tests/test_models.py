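"""Network construction, training contracts, and the classical baselines."""

import numpy as np
import pytest

from wristgait import _nn
from wristgait.features import FeatureVectorSet
from wristgait.models import (ArchitectureConfig, ConvBlockSpec,
                              DegenerateTrainingError, TrainingConfig,
                              build_network, channel_groups, train_classical,
                              train_dnn, train_model)
from wristgait.preprocessing import WindowSet

TINY_ARCH = dict(conv_blocks=(ConvBlockSpec(4, 3), ConvBlockSpec(4, 3)),
                 pool_size=2, lstm_units=(6, 4), per_channel_dense=8,
                 shared_dense=12)


def _window_set(rng, n=40, t=32, c=3, separation=3.0):
    """Binary-labeled windows where the classes differ in amplitude."""
    labels = rng.integers(0, 2, n)
    scale = np.where(labels == 1, 1.0, separation)
    x = rng.standard_normal((n, t, c)).astype(np.float32) * scale[:, None, None]
    subjects = np.array([f"S{i % 4}" for i in range(n)], dtype=object)
    return WindowSet(windows=x, labels=labels, subject_ids=subjects,
                     trial_ids=np.array([f"{s}/t{i % 5}" for i, s in
                                         enumerate(subjects)], dtype=object),
                     wrists=np.full(n, "right", dtype=object),
                     augmented=np.zeros(n, bool),
                     channels=[f"ch{i}" for i in range(c)], rate=50.0)


class TestBuildNetwork:
    def test_per_axis_branch_count_and_output(self):
        cfg = ArchitectureConfig(sensors="AGR", **TINY_ARCH)
        net = build_network(cfg, window_len=32, n_channels=9)
        assert len(net.groups) == 9
        logits = net.forward(np.zeros((5, 32, 9), np.float32), training=False)
        assert logits.shape == (5, 2)

    def test_single_sensor_three_branches(self):
        cfg = ArchitectureConfig(sensors="A", **TINY_ARCH)
        assert len(channel_groups(cfg, 3)) == 3

    def test_data_level_single_branch(self):
        cfg = ArchitectureConfig(fusion_level="data", sensors="AGMR", **TINY_ARCH)
        groups = channel_groups(cfg, 12)
        assert len(groups) == 1 and len(groups[0]) == 12

    def test_kernel_larger_than_window_rejected(self):
        cfg = ArchitectureConfig(conv_blocks=(ConvBlockSpec(4, 50),
                                              ConvBlockSpec(4, 3)),
                                 pool_size=2, lstm_units=(6, 4))
        with pytest.raises(ValueError):
            build_network(cfg, window_len=32, n_channels=3)

    def test_parameter_count_independent_of_batch(self):
        cfg = ArchitectureConfig(**TINY_ARCH)
        net = build_network(cfg, 32, 3, rng=np.random.default_rng(0))
        n0 = net.n_params()
        net.forward(np.zeros((2, 32, 3), np.float32), training=False)
        net.forward(np.zeros((7, 32, 3), np.float32), training=False)
        assert net.n_params() == n0

    def test_feature_and_decision_share_branch_parameters(self):
        rng_a = np.random.default_rng(0)
        rng_b = np.random.default_rng(0)
        feat = build_network(ArchitectureConfig(fusion_level="feature",
                                                **TINY_ARCH), 32, 3, rng=rng_a)
        dec = build_network(ArchitectureConfig(fusion_level="decision",
                                               **TINY_ARCH), 32, 3, rng=rng_b)
        assert feat.branch_n_params() == dec.branch_n_params()
        assert feat.n_params() != dec.n_params()  # they differ after the concat


class TestGradients:
    def test_full_network_matches_finite_differences(self):
        """End-to-end analytic gradients vs central differences (float64)."""
        rng = np.random.default_rng(3)
        cfg = ArchitectureConfig(conv_blocks=(ConvBlockSpec(3, 3),
                                              ConvBlockSpec(3, 3)),
                                 pool_size=2, lstm_units=(4, 3),
                                 dropout_rate=0.0, per_channel_dense=5,
                                 shared_dense=6)
        net = build_network(cfg, window_len=12, n_channels=2, rng=rng,
                            dtype=np.float64)
        x = rng.standard_normal((4, 12, 2))
        y = np.eye(2)[rng.integers(0, 2, 4)]

        def loss():
            return _nn.softmax_cross_entropy(net.forward(x, training=True), y)

        _, d0 = loss()
        net.backward(d0)
        snapshot = [(p, g.copy()) for p, g in net.iter_params()]
        eps = 1e-5
        for pi, (p, g) in enumerate(snapshot):
            if pi in (1, 5):
                # conv biases are absorbed by the following batch norm;
                # their gradient is identically ~0 and the relative error
                # on numerical noise is meaningless
                continue
            for fi in rng.integers(0, p.size, 4):
                sl = np.unravel_index(fi, p.shape)
                old = p[sl]
                p[sl] = old + eps
                lp, _ = loss()
                p[sl] = old - eps
                lm, _ = loss()
                p[sl] = old
                num = (lp - lm) / (2 * eps)
                err = abs(num - g[sl]) / max(1e-7, abs(num) + abs(g[sl]))
                assert err < 1e-4, f"param {pi} {p.shape}: {err}"


class TestTraining:
    def test_loss_decreases_on_separable_data(self, rng):
        ws = _window_set(rng, n=64)
        tc = TrainingConfig(max_epochs=6, batch_size=32, early_stopping=False,
                            seed=0)
        cfg = ArchitectureConfig(**TINY_ARCH)
        net = build_network(cfg, ws.window_len, 3, rng=np.random.default_rng(0))
        model = train_model(net, ws, tc)
        hist = model.history["loss"]
        assert np.isfinite(hist).all()
        assert hist[-1] < hist[0]

    def test_max_epochs_one(self, rng):
        ws = _window_set(rng, n=24)
        tc = TrainingConfig(max_epochs=1, batch_size=24, early_stopping=False)
        net = build_network(ArchitectureConfig(**TINY_ARCH), ws.window_len, 3)
        model = train_model(net, ws, tc)
        assert len(model.history["loss"]) == 1

    def test_single_class_labels_rejected(self, rng):
        ws = _window_set(rng, n=24)
        ws.labels[:] = 1
        net = build_network(ArchitectureConfig(**TINY_ARCH), ws.window_len, 3)
        with pytest.raises(DegenerateTrainingError):
            train_model(net, ws, TrainingConfig())

    def test_same_seed_reproducible(self, rng):
        ws = _window_set(rng, n=32)
        arch = ArchitectureConfig(**TINY_ARCH)
        tc = TrainingConfig(max_epochs=2, batch_size=16, seed=7,
                            early_stopping=False)
        p1 = train_dnn("proposed", ws, arch, tc).predict_proba(ws.windows)
        p2 = train_dnn("proposed", ws, arch, tc).predict_proba(ws.windows)
        np.testing.assert_array_equal(p1, p2)


class TestPredictProba:
    @pytest.fixture()
    def model(self, rng):
        ws = _window_set(rng, n=32)
        tc = TrainingConfig(max_epochs=1, batch_size=32, early_stopping=False)
        return train_dnn("proposed", ws, ArchitectureConfig(**TINY_ARCH), tc), ws

    def test_rows_sum_to_one(self, model, rng):
        m, ws = model
        probs = m.predict_proba(ws.windows)
        assert probs.shape == (len(ws), 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_duplicated_windows_identical_probs(self, model):
        m, ws = model
        dup = np.repeat(ws.windows[:3], 2, axis=0)
        probs = m.predict_proba(dup)
        np.testing.assert_array_equal(probs[0::2], probs[1::2])

    def test_shape_mismatch_rejected(self, model):
        m, ws = model
        with pytest.raises(ValueError):
            m.predict_proba(np.zeros((2, 16, 3), np.float32))


class TestClassicalBaselines:
    def _feature_set(self, rng, n=60, leak_label=False):
        labels = rng.integers(0, 2, n)
        values = rng.standard_normal((n, 5))
        if leak_label:
            values[:, 0] = labels
        return FeatureVectorSet(values, [f"f{i}" for i in range(5)], labels,
                                np.full(n, "S1", object), np.full(n, "t", object),
                                np.full(n, "right", object), np.zeros(n, bool))

    def test_rf_config_and_perfect_fit(self, rng):
        fv = self._feature_set(rng, leak_label=True)
        model = train_classical("rf", fv)
        assert model.net.n_estimators == 100
        assert model.net.criterion == "gini"
        pred = (model.predict_proba(fv.values)[:, 1] > 0.5).astype(int)
        assert (pred == fv.labels).mean() == 1.0

    def test_svm_config(self, rng):
        fv = self._feature_set(rng)
        model = train_classical("svm", fv)
        assert model.net.kernel == "rbf"
        assert model.net.C == 1.0

    def test_nan_features_rejected(self, rng):
        fv = self._feature_set(rng)
        fv.values[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_classical("rf", fv)


class TestModelPersistence:
    def test_dnn_roundtrip_preserves_predictions(self, rng, tmp_path):
        from wristgait.models import load_model, save_model
        ws = _window_set(rng, n=24)
        tc = TrainingConfig(max_epochs=1, batch_size=24, early_stopping=False)
        arch = ArchitectureConfig(**TINY_ARCH)
        model = train_dnn("proposed", ws, arch, tc)
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        np.testing.assert_allclose(back.predict_proba(ws.windows),
                                   model.predict_proba(ws.windows), atol=1e-6)
        assert back.kind == "proposed"
        assert (tmp_path / "m" / "history.csv").exists()

    def test_classical_roundtrip(self, rng, tmp_path):
        from wristgait.models import load_model, save_model
        labels = rng.integers(0, 2, 30)
        values = rng.standard_normal((30, 4))
        from wristgait.features import FeatureVectorSet
        fv = FeatureVectorSet(values, list("abcd"), labels,
                              np.full(30, "S", object), np.full(30, "t", object),
                              np.full(30, "right", object), np.zeros(30, bool))
        model = train_classical("rf", fv)
        save_model(model, tmp_path / "rf")
        back = load_model(tmp_path / "rf")
        np.testing.assert_allclose(back.predict_proba(values),
                                   model.predict_proba(values))
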
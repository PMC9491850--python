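"""DRSN building blocks: shrinkage, thresholds, residual units, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from emgforce.autodiff import Tensor
from emgforce.drsn import (DrsnConfig, RsbuUnit, learn_threshold, load_drsn,
                           predict_force, residual_block_forward, save_drsn,
                           senet_squeeze, soft_threshold, soft_threshold_grad,
                           train_drsn)
from emgforce.windows import WindowedDataset


class TestSoftThreshold:
    @pytest.mark.parametrize("x,tau,expected", [
        (2.0, 0.5, 1.5),
        (0.3, 0.5, 0.0),
        (-2.0, 0.5, -1.5),
        (0.5, 0.5, 0.0),       # boundary in the dead zone
    ])
    def test_piecewise_values(self, x, tau, expected):
        assert soft_threshold(x, tau) == pytest.approx(expected)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)
        with pytest.raises(ValueError):
            soft_threshold_grad(1.0, -0.1)

    @pytest.mark.parametrize("x,tau,expected", [
        (2.0, 0.5, 1.0), (0.1, 0.5, 0.0), (-3.0, 1.0, 1.0), (0.5, 0.5, 0.0),
    ])
    def test_grad_is_zero_or_one(self, x, tau, expected):
        assert soft_threshold_grad(x, tau) == expected

    def test_grad_matches_finite_differences_away_from_kinks(self, rng):
        tau = 0.7
        x = rng.uniform(-3, 3, 500)
        x = x[np.abs(np.abs(x) - tau) > 1e-3]
        eps = 1e-5
        fd = (soft_threshold(x + eps, tau) - soft_threshold(x - eps, tau)) / (2 * eps)
        np.testing.assert_allclose(soft_threshold_grad(x, tau), fd, atol=1e-9)

    @given(v=arrays(float, st.integers(1, 30),
                    elements=st.floats(-50, 50, allow_nan=False)),
           tau=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_shrinkage_is_elementwise_contraction(self, v, tau):
        y = soft_threshold(v, tau)
        assert np.all(np.abs(y) <= np.abs(v) + 1e-15)


class TestSqueezeAndThreshold:
    def test_squeeze_constant_and_length_one(self):
        fm = np.full((3, 7), 3.0)
        np.testing.assert_allclose(senet_squeeze(fm), [3.0, 3.0, 3.0])
        fm1 = np.array([[1.0], [2.0]])
        np.testing.assert_allclose(senet_squeeze(fm1), [1.0, 2.0])

    def test_squeeze_matches_loop_oracle(self, rng):
        fm = rng.standard_normal((4, 5, 9))
        oracle = np.array([[fm[n, c].sum() / 9 for c in range(5)] for n in range(4)])
        np.testing.assert_allclose(senet_squeeze(fm), oracle)

    def _unit(self, c=4, seed=0, **kw):
        return RsbuUnit(np.random.default_rng(seed), c, c, 3, 1, **kw)

    def test_threshold_half_mean_when_subnet_outputs_zero(self, rng):
        unit = self._unit()
        # zero the second dense layer: sigmoid(0) = 0.5 exactly
        unit.fc2.w.data[:] = 0.0
        unit.fc2.b.data[:] = 0.0
        fm = rng.standard_normal((2, 4, 16))
        tau = learn_threshold(fm, unit)
        np.testing.assert_allclose(tau, 0.5 * np.abs(fm).mean(axis=2), atol=1e-12)

    def test_zero_feature_map_gives_zero_threshold(self):
        unit = self._unit()
        tau = learn_threshold(np.zeros((2, 4, 8)), unit)
        np.testing.assert_allclose(tau, 0.0)

    def test_threshold_strictly_below_mean_abs(self, rng):
        unit = self._unit(seed=3)
        fm = rng.standard_normal((5, 4, 32))
        tau = learn_threshold(fm, unit)
        assert np.all(tau >= 0.0)
        assert np.all(tau < np.abs(fm).mean(axis=2))

    def test_channel_shared_single_threshold(self, rng):
        unit = self._unit(seed=1, mode="channel_shared")
        fm = rng.standard_normal((3, 4, 16))
        tau = unit.learn_threshold(Tensor(fm), training=False).data
        assert tau.shape == (3, 1, 1)


class TestResidualBlock:
    def test_identity_when_branch_zeroed(self, rng):
        unit = RsbuUnit(np.random.default_rng(2), 4, 4, 3, 1)
        unit.conv2.w.data[:] = 0.0
        unit.conv2.b.data[:] = 0.0
        unit.bn2.beta.data[:] = 0.0
        x = rng.standard_normal((2, 4, 12))
        np.testing.assert_allclose(residual_block_forward(x, unit), x, atol=1e-12)

    def test_output_channels_match_stage(self, rng):
        unit = RsbuUnit(np.random.default_rng(0), 3, 8, 3, 2)
        y = residual_block_forward(rng.standard_normal((2, 3, 16)), unit)
        assert y.shape == (2, 8, 8)

    def test_forward_matches_hand_unrolled_oracle(self):
        """Step-by-step conv/BN/ReLU/conv/BN/shrink+shortcut on a 1x8 input."""
        unit = RsbuUnit(np.random.default_rng(5), 1, 1, 3, 1)
        x = np.linspace(-1.0, 1.0, 8).reshape(1, 1, 8)

        def conv(v, w, b):
            vp = np.pad(v, 1)
            return np.array([(vp[i:i + 3] * w).sum() + b for i in range(8)])

        def bn_eval(v, bn):
            return ((v - bn.running_mean[0])
                    / np.sqrt(bn.running_var[0] + bn.eps)
                    * bn.gamma.data[0] + bn.beta.data[0])

        h = conv(x[0, 0], unit.conv1.w.data[0, 0], unit.conv1.b.data[0])
        h = np.maximum(bn_eval(h, unit.bn1), 0.0)
        r = bn_eval(conv(h, unit.conv2.w.data[0, 0], unit.conv2.b.data[0]), unit.bn2)
        z = np.abs(r).mean()
        a = z * unit.fc1.w.data[0, 0] + unit.fc1.b.data[0]
        a = bn_eval(np.array([a]), unit.bnf)[0]
        a = max(a, 0.0) * unit.fc2.w.data[0, 0] + unit.fc2.b.data[0]
        alpha = 1.0 / (1.0 + np.exp(-a))
        tau = alpha * z
        shrunk = np.sign(r) * np.maximum(np.abs(r) - tau, 0.0)
        expected = x[0, 0] + shrunk
        np.testing.assert_allclose(residual_block_forward(x, unit)[0, 0],
                                   expected, atol=1e-10)


def _toy_dataset(n=160, seed=0):
    """Force proportional to a weighted channel MAV: learnable by a small net."""
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.0, 1.0, n)
    X = amp[:, None] * rng.standard_normal((n, 2 * 24))
    y = 2.0 * np.abs(X[:, :24]).mean(axis=1) + 0.5 * np.abs(X[:, 24:]).mean(axis=1)
    return WindowedDataset(X, y, 24, 24, 2, labels=("u", "v"), kind="raw")


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self):
        ds = _toy_dataset()
        cfg = DrsnConfig(n_units=1, channels=(4,), epochs=0, seed=0)
        model = train_drsn(cfg, ds, ds)
        assert model.history["train_mse"] == []
        assert len(predict_force(model, ds)) == len(ds)

    def test_same_seed_identical_loss_history(self):
        ds = _toy_dataset()
        tr = ds.subset(np.arange(120))
        va = ds.subset(np.arange(120, 160))
        cfg = DrsnConfig(n_units=1, channels=(4,), epochs=4, seed=9)
        m1 = train_drsn(cfg, tr, va)
        m2 = train_drsn(cfg, tr, va)
        assert m1.history == m2.history

    def test_linear_synthetic_task_learned(self):
        """A 1-unit network reaches rho >= 0.9 on a weighted-MAV force task."""
        ds = _toy_dataset(n=300, seed=42)
        tr = ds.subset(np.arange(220))
        va = ds.subset(np.arange(220, 300))
        cfg = DrsnConfig(n_units=1, channels=(8,), epochs=30, seed=42)
        model = train_drsn(cfg, tr, va)
        pred = predict_force(model, va)
        rho = np.corrcoef(pred, va.y)[0, 1]
        assert rho >= 0.9

    def test_beats_constant_mean_predictor_on_train(self):
        ds = _toy_dataset(n=200, seed=3)
        cfg = DrsnConfig(n_units=1, channels=(6,), epochs=25, seed=3)
        model = train_drsn(cfg, ds, ds)
        pred = predict_force(model, ds)
        assert np.mean((pred - ds.y) ** 2) < np.var(ds.y)

    def test_empty_dataset_rejected_and_empty_predictions(self):
        ds = _toy_dataset()
        empty = ds.subset(np.arange(0))
        with pytest.raises(ValueError):
            train_drsn(DrsnConfig(n_units=1, channels=(4,), epochs=1), empty, ds)
        model = train_drsn(DrsnConfig(n_units=1, channels=(4,), epochs=0), ds, ds)
        assert predict_force(model, empty).size == 0

    def test_save_load_predict_bit_identical(self, tmp_path):
        ds = _toy_dataset(n=100, seed=5)
        cfg = DrsnConfig(n_units=2, channels=(4, 6), epochs=3, seed=5)
        model = train_drsn(cfg, ds, ds)
        path = tmp_path / "drsn.npz"
        save_drsn(model, path)
        loaded = load_drsn(path)
        np.testing.assert_array_equal(predict_force(model, ds),
                                      predict_force(loaded, ds))
        assert loaded.history == model.history

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DrsnConfig(n_units=0, channels=())
        with pytest.raises(ValueError):
            DrsnConfig(n_units=2, channels=(4,))
        with pytest.raises(ValueError):
            RsbuUnit(np.random.default_rng(0), 2, 2, mode="bogus")
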
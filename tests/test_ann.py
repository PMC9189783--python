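"""Range normalization, data splitting and Levenberg-Marquardt net training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fermopt.ann import (NetFit, NetSpec, denormalize, fit_ann, forward,
                         jacobian, normalize, split_data, train_lm)


class TestNormalize:
    @pytest.mark.parametrize("x,expected", [(2.0, -1.0), (8.0, 1.0), (5.0, 0.0)])
    def test_endpoints_and_midpoint(self, x, expected):
        assert normalize(x, 2.0, 8.0) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6), st.floats(0.01, 1e6))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_inverse(self, x, lo, width):
        hi = lo + width
        assert denormalize(normalize(x, lo, hi), lo, hi) == pytest.approx(
            x, rel=1e-9, abs=1e-6)

    def test_degenerate_range_errors(self):
        with pytest.raises(ValueError):
            normalize(1.0, 3.0, 3.0)


class TestSplit:
    def test_study_sizes(self):
        tr, val, te = split_data(50, (0.70, 0.15, 0.15), seed=3)
        assert (len(tr), len(val), len(te)) == (34, 8, 8)
        assert sorted(np.concatenate([tr, val, te])) == list(range(50))

    def test_deterministic_and_seed_sensitive(self):
        a = split_data(50, seed=5)
        b = split_data(50, seed=5)
        c = split_data(50, seed=6)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def _net(seed=0, H=3, k=2):
    spec = NetSpec(n_inputs=k, n_hidden=H, seed=seed)
    rng = np.random.default_rng(seed)
    return NetFit(spec, rng.normal(size=(H, k)), rng.normal(size=H),
                  rng.normal(size=H), float(rng.normal()))


class TestForward:
    def test_zero_weights_give_constant_output(self):
        net = _net()
        net.W1[:] = 0; net.b1[:] = 0; net.w2[:] = 0; net.b2 = 0.37
        out = forward(net, np.random.default_rng(1).uniform(-1, 1, (20, 2)))
        np.testing.assert_allclose(out, 0.37)

    def test_tanh_saturation(self):
        net = _net()
        net.W1[:] = 100.0
        h = np.tanh(np.atleast_2d([1.0, 1.0]) @ net.W1.T + net.b1)
        assert np.all(np.abs(h) > 1 - 1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="expected 2 inputs"):
            forward(_net(), np.ones((4, 3)))


class TestJacobian:
    @pytest.mark.parametrize("activation", ["tanh", "logistic"])
    def test_matches_central_finite_differences(self, activation):
        spec = NetSpec(n_inputs=3, n_hidden=4, activation=activation)
        rng = np.random.default_rng(7)
        net = NetFit(spec, rng.normal(size=(4, 3)) * 0.5, rng.normal(size=4),
                     rng.normal(size=4), 0.2)
        X = rng.uniform(-1, 1, (6, 3))
        J = jacobian(net, X)

        theta = np.concatenate([net.W1.ravel(), net.b1, net.w2, [net.b2]])
        eps = 1e-6
        J_fd = np.empty_like(J)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps; tm[i] -= eps
            def out(tv):
                W1 = tv[:12].reshape(4, 3); b1 = tv[12:16]; w2 = tv[16:20]; b2 = tv[20]
                n = NetFit(spec, W1, b1, w2, float(b2))
                return forward(n, X)
            J_fd[:, i] = (out(tp) - out(tm)) / (2 * eps)
        np.testing.assert_allclose(J, J_fd, atol=1e-6)


class TestTraining:
    def test_interpolates_linear_target(self):
        """A noiseless linear map is an easy target: train mse < 1e-6."""
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (40, 2))
        y = 0.3 * X[:, 0] - 0.2 * X[:, 1]
        spec = NetSpec(n_inputs=2, n_hidden=3, seed=1)
        fit = train_lm(spec, X, y)
        assert fit.mse["train"] < 1e-6

    def test_bit_identical_reproducibility(self, coded_runs, activity):
        spec = NetSpec(n_hidden=6, seed=42, max_epochs=50)
        y = (activity - activity.mean()) / activity.std()
        a = train_lm(spec, coded_runs / 2, y)
        b = train_lm(spec, coded_runs / 2, y)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.idx_train, b.idx_train)
        assert a.mse == b.mse

    def test_returns_best_validation_epoch(self, coded_runs, activity):
        spec = NetSpec(n_hidden=12, seed=2, max_epochs=200)
        y = (activity - activity.mean()) / (np.ptp(activity) / 2)
        fit = train_lm(spec, coded_runs / 2, y)
        val_trace = [v for (_, _, _, v) in fit.trace]
        assert fit.mse["val"] <= min(val_trace) + 1e-12

    def test_overfitting_is_possible_with_12_hidden_units(self, coded_runs, activity):
        """34 training points vs 85 weights: training error beats test error."""
        spec = NetSpec(n_hidden=12, seed=3, max_epochs=300,
                       max_validation_failures=300)  # disable early stop
        y = (activity - activity.mean()) / (np.ptp(activity) / 2)
        fit = train_lm(spec, coded_runs / 2, y)
        assert fit.mse["train"] < fit.mse["test"]

    def test_lm_superlinear_on_quadratic_bowl(self):
        """Near an optimum LM approaches Gauss-Newton: training sse collapses fast."""
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (30, 2))
        y = 0.5 * X[:, 0]
        spec = NetSpec(n_inputs=2, n_hidden=2, seed=5, max_epochs=300,
                       fractions=(1.0, 0.0, 0.0))
        fit = train_lm(spec, X, y)
        train_mse = [t for (_, _, t, _) in fit.trace]
        assert train_mse[-1] < 1e-10          # reached machine-level residual
        assert train_mse[-1] < 1e-6 * train_mse[0]


class TestWrapper:
    def test_fit_ann_predicts_on_original_scale(self, ccrd_runs, activity):
        from fermopt import datasets
        X = ccrd_runs[datasets.CCRD_FACTOR_COLUMNS].to_numpy(float)
        model = fit_ann(X, activity, n_hidden=6, seed=4)
        pred = model.predict(X)
        assert pred.shape == (50,)
        # predictions land in the response's order of magnitude
        assert 1e5 < np.median(pred) < 1e6
        assert model.net.r2["train"] > 0.9
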
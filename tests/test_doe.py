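"""Design generation, coded-level algebra and first-order screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fermopt.doe import (DesignMatrix, Factor, FactorSet, ccrd, fit_first_order,
                         rotatable_alpha, steepest_ascent_path, two_level_factorial)


class TestFactorial:
    def test_k2_yates_order(self, factors2):
        dm = two_level_factorial(factors2)
        np.testing.assert_array_equal(
            dm.coded, [[-1, -1], [1, -1], [-1, 1], [1, 1]])

    def test_balance_and_orthogonality(self, study_factors):
        dm = two_level_factorial(study_factors)
        assert len(dm) == 32
        Z = dm.coded
        np.testing.assert_allclose(Z.sum(axis=0), 0)
        np.testing.assert_allclose(Z.T @ Z, 32 * np.eye(5))

    def test_size_guard(self):
        big = FactorSet([Factor(f"f{i}", 0, 1) for i in range(13)])
        with pytest.raises(ValueError, match="k <= 12"):
            two_level_factorial(big)


class TestCcrd:
    def test_census_matches_study_design(self, study_factors):
        dm = ccrd(study_factors, n_center=8, alpha=2.0)
        assert len(dm) == 50
        counts = dict(zip(*np.unique(dm.point_class, return_counts=True)))
        assert counts == {"factorial": 32, "axial": 10, "center": 8}

    def test_axial_actual_levels(self, study_factors):
        """Axial cpe level is centre + 2 half-ranges: 46.9 + 2*1.2 = 49.3."""
        dm = ccrd(study_factors, n_center=8, alpha=2.0)
        axial = dm.actual[dm.point_class == "axial"]
        assert axial[:, 0].max() == pytest.approx(49.3)
        mg = dm.actual[dm.point_class == "axial"][:, 3]
        assert mg.min() == pytest.approx(0.05)

    def test_rotatable_alpha(self, study_factors):
        assert rotatable_alpha(32) == pytest.approx(32 ** 0.25)
        dm = ccrd(study_factors, n_center=6, alpha="rotatable")
        axial = dm.coded[dm.point_class == "axial"]
        assert np.abs(axial).max() == pytest.approx(2.3784142, rel=1e-6)

    def test_balance_property(self, study_factors):
        dm = ccrd(study_factors, n_center=5, alpha=1.5)
        np.testing.assert_allclose(dm.coded.sum(axis=0), 0, atol=1e-12)


class TestCoding:
    def test_study_levels(self, study_factors):
        assert study_factors.code([46.9, 23.9, 6.13, 0.27, 0.031]) == pytest.approx([0] * 5)
        coded = study_factors.code([48.1, 24.6, 6.93, 0.38, 0.039])
        assert coded == pytest.approx([1, 1, 1, 1, 1])
        assert study_factors.code([46.9, 23.9, 6.13, 0.05, 0.031])[3] == pytest.approx(-2)

    @given(st.lists(st.floats(-3, 3), min_size=5, max_size=5))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_decode_code_inverse(self, z):
        factors = FactorSet([Factor("cpe", 45.7, 48.1), Factor("csl", 23.2, 24.6),
                             Factor("casein", 5.33, 6.93), Factor("mg", 0.16, 0.38),
                             Factor("mn", 0.023, 0.039)])
        z = np.array(z)
        np.testing.assert_allclose(factors.code(factors.decode(z)), z,
                                   rtol=1e-12, atol=1e-9)


class TestFirstOrder:
    def test_exact_interpolation(self, factors2):
        dm = two_level_factorial(factors2)
        y = 3 + 2 * dm.coded[:, 0] - dm.coded[:, 1]
        fit = fit_first_order(dm, y)
        assert fit.intercept == pytest.approx(3)
        assert fit.coef == pytest.approx([2, -1])

    def test_contrast_oracle_on_orthogonal_design(self, study_factors, rng):
        """On an orthogonal design OLS slopes equal the simple contrasts sum(z*y)/n."""
        dm = two_level_factorial(study_factors)
        y = rng.normal(size=len(dm))
        fit = fit_first_order(dm, y)
        contrasts = dm.coded.T @ y / len(dm)
        np.testing.assert_allclose(fit.coef, contrasts, rtol=1e-10)

    def test_constant_response(self, factors2):
        dm = two_level_factorial(factors2)
        fit = fit_first_order(dm, np.full(4, 7.5))
        assert fit.intercept == pytest.approx(7.5)
        np.testing.assert_allclose(fit.coef, 0, atol=1e-12)

    def test_rank_deficiency_errors(self, factors2):
        dm = DesignMatrix(factors2, np.array([[1.0, 1.0]] * 5), ["center"] * 5)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_first_order(dm, np.arange(5.0))


class TestSteepestAscent:
    def _fit(self, coef, factors, rng, sigma=1e-9):
        dm = two_level_factorial(factors)
        reps = np.vstack([dm.coded] * 4)  # replicate for df so t-tests exist
        dm = DesignMatrix(factors, reps, ["factorial"] * len(reps))
        y = reps @ coef + 10 + rng.normal(0, sigma, len(reps))
        return fit_first_order(dm, y), dm

    def test_step_proportional_to_coefficients(self, factors2, rng):
        fit, _ = self._fit(np.array([2.0, 1.0]), factors2, rng)
        path = steepest_ascent_path(fit, factors2, base=[15.0, 2.0], n_steps=2)
        coded = factors2.code(path[["a", "b"]].to_numpy())
        np.testing.assert_allclose(coded[1] - coded[0], [1.0, 0.5], rtol=1e-5)

    def test_negative_coefficient_decreases(self, factors2, rng):
        fit, _ = self._fit(np.array([2.0, -1.0]), factors2, rng)
        path = steepest_ascent_path(fit, factors2, base=[15.0, 2.0], n_steps=3)
        assert (np.diff(path["b"]) < 0).all()

    def test_direction_is_normalized_gradient(self, factors2, rng):
        fit, _ = self._fit(np.array([1.5, 0.8]), factors2, rng)
        path = steepest_ascent_path(fit, factors2, base=[15.0, 2.0], n_steps=1)
        step = factors2.code(path[["a", "b"]].to_numpy())[1]
        cos = step @ fit.coef / (np.linalg.norm(step) * np.linalg.norm(fit.coef))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_path_climbs_capped_plane(self, factors2, rng):
        """On plane + concave cap the path response rises then falls; best step beats base."""
        fit, _ = self._fit(np.array([2.0, 1.0]), factors2, rng)
        path = steepest_ascent_path(fit, factors2, base=[15.0, 2.0], n_steps=8,
                                    step_size=0.5)
        coded = factors2.code(path[["a", "b"]].to_numpy())
        true = coded @ np.array([2.0, 1.0]) - 0.4 * (coded ** 2).sum(axis=1)
        best = int(np.argmax(true))
        assert 0 < best < len(true) - 1   # interior maximum
        assert true[best] > true[0]

    def test_no_significant_factor_errors(self, factors2, rng):
        fit, _ = self._fit(np.array([0.0, 0.0]), factors2, rng, sigma=1.0)
        fit.significant[:] = False
        with pytest.raises(ValueError, match="significant"):
            steepest_ascent_path(fit, factors2, base=[15.0, 2.0])
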
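"""Lag design, least-squares estimation, companion form and order selection,
each checked against an independently assembled oracle."""

import numpy as np
import pytest

from bvarburden import (
    DGPSpec,
    VARSpec,
    build_lag_design,
    companion_and_stability,
    generate_var_panel,
    ols_estimate,
    select_order,
)
from bvarburden.errors import InsufficientDataError, ValidationError
from bvarburden.synthetic_data import TimeSeriesPanel
from bvarburden.var_model import ma_coefficients

from conftest import make_panel


def _random_panel(t_length, n, seed):
    rng = np.random.default_rng(seed)
    return TimeSeriesPanel(
        variable_names=[f"v{i}" for i in range(n)],
        time_index=np.arange(t_length),
        values=rng.standard_normal((t_length, n)),
    )


class TestLagDesign:
    def test_shape_and_last_row(self):
        panel = _random_panel(5, 2, 0)
        y, x = build_lag_design(panel, VARSpec(order=2))
        assert y.shape == (3, 2)
        v = panel.values
        # regressor row for t=4 (0-based) is [1, y3', y2']
        np.testing.assert_allclose(x[-1], np.r_[1.0, v[3], v[2]])

    def test_order_zero_rejected(self):
        with pytest.raises(ValidationError):
            VARSpec(order=0)

    def test_matches_loop_built_oracle(self):
        panel = _random_panel(12, 3, 1)
        q = 2
        y, x = build_lag_design(panel, VARSpec(order=q))
        v = panel.values
        for row, t in enumerate(range(q, 12)):
            expected = [1.0]
            for ell in range(1, q + 1):
                expected.extend(v[t - ell])
            np.testing.assert_allclose(x[row], expected)
            np.testing.assert_allclose(y[row], v[t])

    def test_too_short_panel(self):
        with pytest.raises(InsufficientDataError):
            build_lag_design(_random_panel(2, 2, 0), VARSpec(order=2))


class TestOls:
    def test_noiseless_recovery(self):
        # a damped rotation keeps the noiseless path non-degenerate, so the
        # least-squares fit interpolates the dynamics exactly
        theta = 0.7
        b1 = 0.9 * np.array([[np.cos(theta), -np.sin(theta)],
                             [np.sin(theta), np.cos(theta)]])
        dgp = DGPSpec(
            n_variables=2, order=1, coefficients=[b1],
            drift=np.zeros(2), noise_covariance=np.zeros((2, 2)),
            initial_values=np.array([[1.0, 0.0]]), length=30, seed=0,
        )
        panel = generate_var_panel(dgp)
        fit = ols_estimate(panel, VARSpec(order=1))
        np.testing.assert_allclose(fit.coefficients[0], b1, atol=1e-8)
        np.testing.assert_allclose(fit.drift, 0.0, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        panel = _random_panel(40, 3, 5)
        spec = VARSpec(order=2)
        fit = ols_estimate(panel, spec)
        y, x = build_lag_design(panel, spec)
        coef = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(fit.drift, coef[0], atol=1e-10)
        n = 3
        for ell in range(2):
            np.testing.assert_allclose(
                fit.coefficients[ell], coef[1 + ell * n: 1 + (ell + 1) * n].T,
                atol=1e-10,
            )
        np.testing.assert_allclose(
            fit.sigma_u, fit.residuals.T @ fit.residuals / y.shape[0]
        )

    def test_residuals_orthogonal_to_regressors(self):
        panel = _random_panel(50, 2, 9)
        spec = VARSpec(order=2)
        fit = ols_estimate(panel, spec)
        _, x = build_lag_design(panel, spec)
        assert np.abs(x.T @ fit.residuals).max() < 1e-8

    def test_matches_statsmodels(self, long_bivariate_panel):
        sm_var = pytest.importorskip("statsmodels.tsa.api").VAR
        res = sm_var(long_bivariate_panel.values).fit(2, trend="c")
        fit = ols_estimate(long_bivariate_panel, VARSpec(order=2))
        np.testing.assert_allclose(fit.drift, res.intercept, atol=1e-8)
        np.testing.assert_allclose(
            np.array(fit.coefficients), res.coefs, atol=1e-8
        )

    def test_one_step_fitted_values_via_companion(self, bivariate_panel):
        # propagating the companion form reproduces in-sample fits exactly
        spec = VARSpec(order=2)
        fit = ols_estimate(bivariate_panel, spec)
        comp, _, _ = companion_and_stability(fit)
        v = bivariate_panel.values
        n, q = 2, 2
        for t in range(q, v.shape[0]):
            state = np.concatenate([v[t - 1 - j] for j in range(q)])
            pred = (comp @ state)[:n] + fit.drift
            resid = v[t] - pred
            np.testing.assert_allclose(resid, fit.residuals[t - q], atol=1e-10)

    def test_ols_consistency_with_sample_size(self):
        b1 = np.array([[0.5, 0.1], [0.2, 0.4]])
        errs = {100: [], 2000: []}
        for t_len in errs:
            for seed in range(50):
                panel = make_panel(t_length=t_len, seed=seed)
                fit = ols_estimate(panel, VARSpec(order=1))
                errs[t_len].append(np.abs(fit.coefficients[0] - b1).max())
        assert np.median(errs[2000]) < np.median(errs[100])


class TestCompanion:
    def test_scalar_ar1(self):
        comp, stable, radius = companion_and_stability([np.array([[0.5]])])
        assert comp.shape == (1, 1)
        assert radius == pytest.approx(0.5)
        assert stable

    def test_unit_root_not_stable(self):
        _, stable, radius = companion_and_stability([np.array([[1.0]])])
        assert radius == pytest.approx(1.0)
        assert not stable

    def test_var2_eigenvalues_match_polynomial_roots(self):
        # reciprocal roots of det(I - B1 z - B2 z^2) = 0 as oracle
        rng = np.random.default_rng(2)
        b1 = rng.standard_normal((2, 2)) * 0.3
        b2 = rng.standard_normal((2, 2)) * 0.2
        comp, _, _ = companion_and_stability([b1, b2])
        eig = np.sort_complex(np.linalg.eigvals(comp))

        # det as a polynomial in z: entries of I - B1 z - B2 z^2 are
        # quadratics; det = m00*m11 - m01*m10 via coefficient convolution
        def entry(i, j):
            return np.array([float(i == j), -b1[i, j], -b2[i, j]])

        det = np.convolve(entry(0, 0), entry(1, 1)) - np.convolve(
            entry(0, 1), entry(1, 0)
        )
        roots = np.roots(det[::-1])          # ascending -> descending powers
        recip = np.sort_complex(1.0 / roots)
        np.testing.assert_allclose(
            np.sort(np.abs(eig)), np.sort(np.abs(recip)), atol=1e-8
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            companion_and_stability([np.zeros((2, 2)), np.zeros((3, 3))])

    def test_ma_coefficients_ar1_closed_form(self):
        phi = 0.6
        psi = ma_coefficients([np.array([[phi]])], 8)
        np.testing.assert_allclose(psi[:, 0, 0], phi ** np.arange(9))


class TestSelectOrder:
    def test_recovers_var2(self):
        dgp = DGPSpec(
            n_variables=2, order=2,
            coefficients=[np.array([[0.3, 0.0], [0.0, 0.2]]),
                          np.array([[0.5, 0.1], [0.1, 0.5]])],
            drift=np.zeros(2), noise_covariance=np.eye(2),
            initial_values=np.zeros((2, 2)), length=400, seed=21,
        )
        panel = generate_var_panel(dgp)
        chosen, crits = select_order(panel, max_order=4)
        assert chosen == 2
        assert set(crits) == {1, 2, 3, 4}

    def test_white_noise_selects_smallest(self):
        panel = _random_panel(200, 2, 13)
        chosen, _ = select_order(panel, max_order=4)
        assert chosen == 1

    def test_criterion_matches_direct_formula(self):
        panel = _random_panel(60, 2, 17)
        max_order = 3
        _, crits = select_order(panel, max_order)
        v = panel.values
        t_c = 60 - max_order
        y = v[max_order:]
        for q in range(1, max_order + 1):
            x = np.hstack([np.ones((t_c, 1))] +
                          [v[max_order - ell: 60 - ell]
                           for ell in range(1, q + 1)])
            coef = np.linalg.lstsq(x, y, rcond=None)[0]
            e = y - x @ coef
            sigma = e.T @ e / t_c
            expected = (np.log(np.linalg.det(sigma))
                        + np.log(t_c) / t_c * 2 * (2 * q + 1))
            assert crits[q] == pytest.approx(expected, abs=1e-10)

    def test_too_short_panel(self):
        with pytest.raises(InsufficientDataError):
            select_order(_random_panel(8, 2, 0), max_order=4)
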
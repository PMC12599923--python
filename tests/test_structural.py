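"""Orthogonalization, impulse responses and variance decompositions against
closed-form, path-simulation and Monte-Carlo oracles."""

import numpy as np
import pytest

from bvarburden import (
    MinnesotaHyperparams,
    VARSpec,
    build_minnesota_prior,
    draw_posterior,
    estimate_scales,
    fevd,
    impulse_responses,
    ordering_robustness,
    orthogonalize,
)
from bvarburden.errors import DecompositionError, ValidationError
from bvarburden.posterior import PosteriorDraws
from bvarburden.structural import fevd_shares_single, irf_paths
from bvarburden.var_model import ma_coefficients

from conftest import make_panel


def manual_draws(coef_stacked, sigma, names, order, n_draws=1, seed=0):
    """Hand-assembled PosteriorDraws around known coefficients."""
    coef = np.tile(np.asarray(coef_stacked, dtype=float), (n_draws, 1))
    return PosteriorDraws(
        family="minnesota-fixed-sigma",
        coef_draws=coef,
        sigma_draws=None,
        fixed_sigma=np.asarray(sigma, dtype=float),
        variable_names=list(names),
        order=order,
        intercept=True,
        seed=seed,
    )


class TestOrthogonalize:
    def test_diagonal_sigma(self):
        sigma = np.diag([4.0, 9.0])
        np.testing.assert_allclose(
            orthogonalize(sigma), np.diag([2.0, 3.0])
        )

    def test_reconstruction(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 4))
        sigma = a @ a.T + 4 * np.eye(4)
        for ordering in (None, [2, 0, 3, 1]):
            p = orthogonalize(sigma, ordering, list(range(4)))
            np.testing.assert_allclose(p @ p.T, sigma, atol=1e-12)

    def test_hand_cholesky(self):
        sigma = np.array([[4.0, 2.0], [2.0, 3.0]])
        p = orthogonalize(sigma)
        np.testing.assert_allclose(
            p, [[2.0, 0.0], [1.0, np.sqrt(2.0)]], atol=1e-12
        )

    def test_lower_triangular_in_the_ordering(self):
        sigma = np.array([[4.0, 2.0], [2.0, 3.0]])
        p = orthogonalize(sigma, ["b", "a"], ["a", "b"])
        perm = [1, 0]
        permuted = p[np.ix_(perm, perm)]
        assert permuted[0, 1] == 0.0
        assert np.all(np.diag(permuted) > 0)
        np.testing.assert_allclose(p @ p.T, sigma, atol=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(DecompositionError):
            orthogonalize(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestImpulseResponses:
    def test_horizon_zero_is_the_factor(self):
        sigma = np.array([[4.0, 2.0], [2.0, 3.0]])
        beta = np.r_[0.0, 0.5, 0.1, 0.0, 0.2, 0.4]   # two equations, K=3
        draws = manual_draws(beta, sigma, ["a", "b"], 1)
        irf_set = impulse_responses(draws, horizon=3)
        np.testing.assert_allclose(
            irf_set.central[0], orthogonalize(sigma), atol=1e-12
        )

    def test_scalar_ar1_closed_form(self):
        phi, sd = 0.6, 2.0
        beta = np.r_[0.0, phi]
        draws = manual_draws(beta, [[sd ** 2]], ["y"], 1)
        irf_set = impulse_responses(draws, horizon=8)
        np.testing.assert_allclose(
            irf_set.central[:, 0, 0], sd * phi ** np.arange(9), atol=1e-12
        )

    def test_matches_shocked_minus_baseline_simulation(self):
        # exact by linearity: one impact-period innovation, zero noise after
        rng = np.random.default_rng(3)
        b1 = rng.standard_normal((3, 3)) * 0.3
        b2 = rng.standard_normal((3, 3)) * 0.15
        drift = rng.standard_normal(3)
        a = rng.standard_normal((3, 3))
        sigma = a @ a.T + np.eye(3)
        c = np.zeros((7, 3))
        c[0] = drift
        c[1:4] = b1.T
        c[4:7] = b2.T
        beta = np.ravel(c, order="F")
        draws = manual_draws(beta, sigma, ["a", "b", "c"], 2)
        horizon = 6
        paths = irf_paths(draws, horizon)
        p = orthogonalize(sigma)
        for j in range(3):
            shocked = np.zeros((2 + horizon + 1, 3))
            baseline = np.zeros_like(shocked)
            for t in range(2, shocked.shape[0]):
                shock = p[:, j] if t == 2 else 0.0
                shocked[t] = (drift + b1 @ shocked[t - 1]
                              + b2 @ shocked[t - 2] + shock)
                baseline[t] = (drift + b1 @ baseline[t - 1]
                               + b2 @ baseline[t - 2])
            response = shocked[2:] - baseline[2:]
            np.testing.assert_allclose(paths[0, :, :, j], response, atol=1e-10)

    def test_empty_draw_handling(self):
        sigma = np.eye(2)
        draws = manual_draws(np.zeros(6), sigma, ["a", "b"], 1)
        with pytest.raises(ValidationError):
            impulse_responses(draws, horizon=-1)

    def test_stable_responses_decay(self):
        beta = np.r_[0.0, 0.5, 0.1, 0.0, 0.2, 0.4]
        draws = manual_draws(beta, np.eye(2), ["a", "b"], 1)
        irf_set = impulse_responses(draws, horizon=50)
        peak = np.abs(irf_set.central).max()
        assert np.abs(irf_set.central[50]).max() < 0.01 * peak

    def test_bands_widen_as_prior_loosens(self):
        panel = make_panel(t_length=60, seed=5)
        spec = VARSpec(order=1)
        scales = estimate_scales(panel, 1)
        # scored on a cross-response cell, whose prior mean is zero, so the
        # posterior spread grows monotonically as the prior loosens
        widths = []
        for lam1 in (0.01, 0.05, 0.2, 1.0):
            prior = build_minnesota_prior(
                MinnesotaHyperparams(lam1, 0.5, 1.0, 1.0), scales, spec
            )
            draws = draw_posterior(prior, panel, spec, 600, 9,
                                   sigma_mode="fixed")
            irf_set = impulse_responses(draws, horizon=4)
            widths.append(
                float(irf_set.upper[1, 0, 1] - irf_set.lower[1, 0, 1])
            )
        assert np.all(np.diff(widths) > 0)


class TestFevd:
    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(6)
        b1 = rng.standard_normal((3, 3)) * 0.3
        a = rng.standard_normal((3, 3))
        sigma = a @ a.T + np.eye(3)
        c = np.zeros((4, 3))
        c[1:] = b1.T
        draws = manual_draws(np.ravel(c, order="F"), sigma, list("abc"), 1)
        out = fevd(draws, horizon=6)
        np.testing.assert_allclose(out.shares.sum(axis=2), 1.0, atol=1e-10)

    def test_no_dynamics_diagonal_sigma_own_share_one(self):
        draws = manual_draws(np.zeros(6), np.diag([2.0, 5.0]), ["a", "b"], 1)
        out = fevd(draws, horizon=5)
        for h in range(6):
            np.testing.assert_allclose(out.shares[h], np.eye(2), atol=1e-12)

    def test_matches_monte_carlo_variance_split(self):
        # brute-force split of the h-step forecast-error variance by
        # switching on one orthogonal shock at a time
        b1 = np.array([[0.5, 0.2], [0.1, 0.4]])
        sigma = np.array([[1.0, 0.4], [0.4, 2.0]])
        c = np.zeros((3, 2))
        c[1:] = b1.T
        draws = manual_draws(np.ravel(c, order="F"), sigma, ["a", "b"], 1)
        horizon = 3
        out = fevd(draws, horizon=horizon)
        p = orthogonalize(sigma)
        rng = np.random.default_rng(11)
        n_paths = 100_000
        var_by_shock = np.zeros((horizon + 1, 2, 2))
        for j in range(2):
            e = np.zeros((n_paths, horizon + 1, 2))
            e[:, :, j] = rng.standard_normal((n_paths, horizon + 1))
            u = e @ p.T
            y = np.zeros((n_paths, horizon + 1, 2))
            for h in range(horizon + 1):
                prev = y[:, h - 1] if h >= 1 else 0.0
                y[:, h] = (prev @ b1.T if h >= 1 else 0.0) + u[:, h]
            var_by_shock[:, :, j] = y.var(axis=0)
        shares = var_by_shock / var_by_shock.sum(axis=2, keepdims=True)
        np.testing.assert_allclose(out.shares, shares, atol=0.01)

    def test_unit_rescaling_invariance(self):
        b1 = np.array([[0.5, 0.2], [0.1, 0.4]])
        sigma = np.array([[1.0, 0.4], [0.4, 2.0]])
        scale = np.diag([10.0, 1.0])
        b1_s = scale @ b1 @ np.linalg.inv(scale)
        sigma_s = scale @ sigma @ scale
        for mats, sig in ((b1, sigma), (b1_s, sigma_s)):
            c = np.zeros((3, 2))
            c[1:] = mats.T
            draws = manual_draws(np.ravel(c, order="F"), sig, ["a", "b"], 1)
            out = fevd(draws, horizon=4)
            if mats is b1:
                base = out.shares
        np.testing.assert_allclose(out.shares, base, atol=1e-8)


class TestOrderingRobustness:
    @pytest.fixture
    def setup(self):
        panel = make_panel(t_length=70, seed=13)
        spec = VARSpec(order=1)
        scales = estimate_scales(panel, 1)
        prior = build_minnesota_prior(
            MinnesotaHyperparams(0.2, 0.5, 1.0, 1.0), scales, spec
        )
        return panel, spec, prior

    def test_diagonal_sigma_ordering_invariant(self):
        # with orthogonal innovations the identification is unique, so the
        # responses must agree across orderings
        dgp_sigma = np.diag([1.0, 0.5])
        panel = make_panel(
            t_length=4000, seed=17, noise_covariance=dgp_sigma,
            coefficients=[np.array([[0.5, 0.0], [0.0, 0.4]])],
        )
        from bvarburden import ols_estimate

        spec = VARSpec(order=1)
        c = np.zeros((3, 2))
        fit = ols_estimate(panel, spec)
        c[0] = fit.drift
        c[1:] = fit.coefficients[0].T
        sigma_d = np.diag(np.diag(fit.sigma_u))
        draws = manual_draws(np.ravel(c, order="F"), sigma_d,
                             panel.variable_names, 1)
        a = impulse_responses(draws, ordering=["y1", "y2"], horizon=5)
        b = impulse_responses(draws, ordering=["y2", "y1"], horizon=5)
        np.testing.assert_allclose(a.central, b.central, atol=1e-10)

    def test_matches_per_ordering_recomputation(self, setup):
        panel, spec, prior = setup
        orderings = [["y1", "y2"], ["y2", "y1"]]
        rob = ordering_robustness(
            panel, spec, prior, orderings, n_draws=300, horizon=5, seed=21
        )
        draws = draw_posterior(prior, panel, spec, 300, 21)
        for o in orderings:
            expected = impulse_responses(draws, ordering=o, horizon=5)
            got = rob.irf_sets[",".join(o)]
            np.testing.assert_allclose(got.central, expected.central,
                                       atol=1e-12)

    def test_agreement_flag_definition(self, setup):
        panel, spec, prior = setup
        rob = ordering_robustness(
            panel, spec, prior, [["y1", "y2"], ["y2", "y1"]],
            n_draws=200, horizon=5, seed=4,
        )
        cols = [c for c in rob.summary.columns if c.startswith("sign[")]
        for _, row in rob.summary.iterrows():
            expected = len({row[c] for c in cols}) == 1
            assert row["agreement"] == expected

    def test_invalid_permutation_rejected(self, setup):
        panel, spec, prior = setup
        with pytest.raises(ValidationError):
            ordering_robustness(panel, spec, prior,
                                [["y1", "y2"], ["y1", "nope"]], n_draws=10)
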
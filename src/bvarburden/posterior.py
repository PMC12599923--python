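"""Posterior inference for the Bayesian VAR.

Three routes:

* :func:`compute_posterior_minnesota` -- the textbook analytic Minnesota
  posterior: per-equation Gaussian with the error covariance held *fixed* at
  the diagonal of the least-squares residual covariance (the classic
  Litterman setup).  Zero-prior-variance coordinates stay clamped at the
  prior mean.
* :func:`draw_posterior` with the Minnesota family -- by default a genuine
  Gibbs sampler for the independent-Normal / inverse-Wishart model
  (coefficients keep the Minnesota Normal prior; Sigma gets a weakly
  informative inverse-Wishart prior), so posterior draws carry error
  -covariance uncertainty into the impulse-response bands.
  ``sigma_mode="fixed"`` instead returns i.i.d. draws from the analytic
  fixed-Sigma posterior above.
* :func:`draw_posterior` with the Normal-Wishart family -- exact i.i.d.
  draws from the conjugate matric-normal-inverse-Wishart posterior
  (Sigma ~ IW(S_n, nu_n), then C | Sigma matric normal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .errors import ValidationError
from .priors import (
    MINNESOTA,
    NORMAL_WISHART,
    PriorSpec,
    require_family,
)
from .synthetic_data import TimeSeriesPanel
from .var_model import VARSpec, build_lag_design, ols_estimate

#: default Gibbs burn-in for the Minnesota sigma_mode="gibbs" sampler; the
#: fixed-Sigma and Normal-Wishart routes draw i.i.d. and use no burn-in.
GIBBS_BURN_IN = 100


@dataclass
class PosteriorSummary:
    """Analytic Gaussian posterior of the stacked coefficient vector."""

    mean: np.ndarray                 # N*K
    covariance: np.ndarray           # N*K x N*K (block diagonal per equation)
    fixed_sigma: np.ndarray          # the fixed (diagonal) Sigma_u used
    variable_names: list[str]
    order: int
    intercept: bool

    def coefficient_matrices(self) -> tuple[np.ndarray, list[np.ndarray]]:
        return unstack_coefficients(
            self.mean, len(self.variable_names), self.order, self.intercept
        )


@dataclass
class PosteriorDraws:
    """Sampled coefficient (and covariance) draws."""

    family: str
    coef_draws: np.ndarray                    # n_draws x N*K
    sigma_draws: Optional[np.ndarray]         # n_draws x N x N, or None
    fixed_sigma: Optional[np.ndarray]         # N x N used when sigma_draws is None
    variable_names: list[str]
    order: int
    intercept: bool
    seed: int

    @property
    def n_draws(self) -> int:
        return self.coef_draws.shape[0]

    def coefficient_matrices(self, draw: int) -> tuple[np.ndarray, list[np.ndarray]]:
        return unstack_coefficients(
            self.coef_draws[draw],
            len(self.variable_names),
            self.order,
            self.intercept,
        )

    def sigma(self, draw: int) -> np.ndarray:
        if self.sigma_draws is not None:
            return self.sigma_draws[draw]
        return self.fixed_sigma

    def to_frame(self) -> pd.DataFrame:
        from .priors import coefficient_labels

        labels = coefficient_labels(
            self.variable_names, self.order, self.intercept
        )
        return pd.DataFrame(self.coef_draws, columns=labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def unstack_coefficients(
    beta: np.ndarray, n: int, order: int, intercept: bool
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Stacked vector -> (drift, [B_1..B_q]) under the package layout."""
    k = n * order + (1 if intercept else 0)
    c = beta.reshape(n, k)               # row i = equation i
    off = 1 if intercept else 0
    drift = c[:, 0].copy() if intercept else np.zeros(n)
    b_mats = [c[:, off + ell * n: off + (ell + 1) * n].copy()
              for ell in range(order)]
    return drift, b_mats


def _fixed_sigma_from_ols(panel: TimeSeriesPanel, spec: VARSpec) -> tuple[np.ndarray, np.ndarray]:
    """(full OLS residual covariance, its diagonal version)."""
    fit = ols_estimate(panel, spec)
    full = fit.sigma_u
    return full, np.diag(np.diag(full))


def regularized_residual_covariance(
    panel: TimeSeriesPanel, spec: VARSpec
) -> np.ndarray:
    """Positive-definite error-covariance estimate for orthogonalization.

    In data-poor samples (T - q close to the regressor count, the regime the
    Minnesota prior targets) the raw OLS residual covariance is singular, so
    its Cholesky factor does not exist.  This returns the inverse-Wishart
    posterior mean under a diagonal prior centered on the OLS variances,

        (S0 + E'E) / (nu0 + T_eff - N - 1),  S0 = diag(diag(Sigma_ols)),
        nu0 = N + 2,

    which shrinks toward the diagonal, is always positive definite, and
    converges to the OLS covariance as T grows.
    """
    fit = ols_estimate(panel, spec)
    n = fit.sigma_u.shape[0]
    t_eff = fit.nobs_effective
    s0 = np.diag(np.diag(fit.sigma_u))
    ee = fit.residuals.T @ fit.residuals
    return (s0 + ee) / (n + 2 + t_eff - n - 1)


def compute_posterior_minnesota(
    prior: PriorSpec,
    panel: TimeSeriesPanel,
    spec: VARSpec,
) -> PosteriorSummary:
    """Analytic per-equation Gaussian posterior with fixed diagonal Sigma_u.

    Sigma_u is fixed at the diagonal of the OLS residual covariance.  For
    equation i with prior ``N(b0_i, diag(v0_i))`` and error variance
    ``s_i^2`` the posterior precision is ``diag(1/v0_i) + X'X / s_i^2``;
    coordinates with ``v0 = 0`` are held exactly at the prior mean (their
    contribution is conditioned out of the likelihood).
    """
    require_family(prior, MINNESOTA)
    y, x = build_lag_design(panel, spec)
    n = len(prior.variable_names)
    k = x.shape[1]
    full_sigma, diag_sigma = _fixed_sigma_from_ols(panel, spec)
    xtx = x.T @ x
    mean = np.zeros(n * k)
    cov = np.zeros((n * k, n * k))
    for i in range(n):
        sl = slice(i * k, (i + 1) * k)
        b0 = prior.beta0[sl]
        v0 = prior.v0_diag[sl]
        s2 = diag_sigma[i, i]
        free = v0 > 0
        mean_i = b0.copy()
        cov_i = np.zeros((k, k))
        if free.any():
            y_adj = y[:, i] - x[:, ~free] @ b0[~free]
            prec = xtx[np.ix_(free, free)] / s2 + np.diag(1.0 / v0[free])
            rhs = x[:, free].T @ y_adj / s2 + b0[free] / v0[free]
            cf = cho_factor(prec, lower=True)
            mean_i[free] = cho_solve(cf, rhs)
            cov_i[np.ix_(free, free)] = cho_solve(cf, np.eye(int(free.sum())))
        mean[sl] = mean_i
        cov[np.ix_(range(i * k, (i + 1) * k), range(i * k, (i + 1) * k))] = cov_i
    return PosteriorSummary(
        mean=mean,
        covariance=cov,
        fixed_sigma=diag_sigma,
        variable_names=list(prior.variable_names),
        order=spec.order,
        intercept=spec.intercept,
    )


def normal_wishart_posterior_params(
    prior: PriorSpec,
    panel: TimeSeriesPanel,
    spec: VARSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Conjugate update: returns (B_n, Omega_n, S_n, nu_n).

    ``C | Sigma, Y ~ MN(B_n, Omega_n, Sigma)`` and
    ``Sigma | Y ~ IW(S_n, nu_n)``.
    """
    require_family(prior, NORMAL_WISHART)
    y, x = build_lag_design(panel, spec)
    t_eff = y.shape[0]
    omega0_inv = np.diag(1.0 / prior.omega0_diag)
    k_n = omega0_inv + x.T @ x
    cf = cho_factor(k_n, lower=True)
    omega_n = cho_solve(cf, np.eye(k_n.shape[0]))
    b_n = cho_solve(cf, omega0_inv @ prior.b0_matrix + x.T @ y)
    s_n = (
        prior.wishart_scale
        + y.T @ y
        + prior.b0_matrix.T @ omega0_inv @ prior.b0_matrix
        - b_n.T @ k_n @ b_n
    )
    s_n = 0.5 * (s_n + s_n.T)
    nu_n = prior.wishart_dof + t_eff
    return b_n, omega_n, s_n, nu_n


def _draw_minnesota_fixed(
    prior: PriorSpec,
    panel: TimeSeriesPanel,
    spec: VARSpec,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    summary = compute_posterior_minnesota(prior, panel, spec)
    n = len(prior.variable_names)
    k = summary.mean.size // n
    draws = np.tile(summary.mean, (n_draws, 1))
    for i in range(n):
        sl = slice(i * k, (i + 1) * k)
        cov_i = summary.covariance[sl, sl]
        v0 = prior.v0_diag[sl]
        free = v0 > 0
        if not free.any():
            continue
        sub = cov_i[np.ix_(free, free)]
        chol = np.linalg.cholesky(sub + 1e-14 * np.trace(sub) / max(free.sum(), 1) * np.eye(int(free.sum())))
        z = rng.standard_normal((n_draws, int(free.sum())))
        draws[:, np.flatnonzero(free) + i * k] += z @ chol.T
    return draws, regularized_residual_covariance(panel, spec)


def _draw_minnesota_gibbs(
    prior: PriorSpec,
    panel: TimeSeriesPanel,
    spec: VARSpec,
    n_draws: int,
    rng: np.random.Generator,
    burn_in: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent-Normal / inverse-Wishart Gibbs sampler.

    Coefficients keep the Minnesota prior ``N(beta0, V0)``; Sigma gets a
    weakly informative ``IW(diag(diag(Sigma_ols)), N + 2)`` prior.  The chain
    alternates ``vec(C) | Sigma`` (Gaussian, full cross-equation GLS
    precision ``V0^-1 + Sigma^-1 (x) X'X``) and ``Sigma | C`` (inverse
    Wishart), initialized at the OLS residual covariance.
    """
    y, x = build_lag_design(panel, spec)
    t_eff, n = y.shape
    k = x.shape[1]
    xtx = x.T @ x
    full_sigma, diag_sigma = _fixed_sigma_from_ols(panel, spec)
    s0 = diag_sigma
    nu0 = n + 2

    b0 = prior.beta0
    v0 = prior.v0_diag
    free = v0 > 0
    n_free = int(free.sum())
    free_idx = np.flatnonzero(free)
    fixed_idx = np.flatnonzero(~free)

    beta = b0.copy()
    sigma = diag_sigma.copy()      # PD even when the full OLS cov is singular
    coef_out = np.empty((n_draws, n * k))
    sigma_out = np.empty((n_draws, n, n))

    for it in range(burn_in + n_draws):
        # --- vec(C) | Sigma ---
        sigma_inv = np.linalg.inv(sigma)
        prec_data = np.kron(sigma_inv, xtx)
        data_rhs = np.ravel(x.T @ y @ sigma_inv, order="F")
        prec = prec_data[np.ix_(free_idx, free_idx)].copy()
        prec[np.diag_indices_from(prec)] += 1.0 / v0[free_idx]
        rhs = data_rhs[free_idx] + b0[free_idx] / v0[free_idx]
        if fixed_idx.size:
            rhs = rhs - prec_data[np.ix_(free_idx, fixed_idx)] @ b0[fixed_idx]
        chol = np.linalg.cholesky(prec)
        mean_free = cho_solve((chol, True), rhs)
        z = rng.standard_normal(n_free)
        beta[free_idx] = mean_free + solve_triangular(chol.T, z, lower=False)
        # --- Sigma | C ---
        c_mat = beta.reshape(n, k).T
        resid = y - x @ c_mat
        s_post = s0 + resid.T @ resid
        s_post = 0.5 * (s_post + s_post.T)
        sigma = stats.invwishart.rvs(df=nu0 + t_eff, scale=s_post,
                                     random_state=rng)
        sigma = np.atleast_2d(sigma)
        if it >= burn_in:
            coef_out[it - burn_in] = beta
            sigma_out[it - burn_in] = sigma
    return coef_out, sigma_out


def _draw_normal_wishart(
    prior: PriorSpec,
    panel: TimeSeriesPanel,
    spec: VARSpec,
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    b_n, omega_n, s_n, nu_n = normal_wishart_posterior_params(
        prior, panel, spec
    )
    k, n = b_n.shape
    chol_omega = np.linalg.cholesky(
        omega_n + 1e-14 * np.trace(omega_n) / k * np.eye(k)
    )
    coef_out = np.empty((n_draws, n * k))
    sigma_out = np.empty((n_draws, n, n))
    for d in range(n_draws):
        sigma = np.atleast_2d(
            stats.invwishart.rvs(df=nu_n, scale=s_n, random_state=rng)
        )
        chol_sigma = np.linalg.cholesky(sigma)
        z = rng.standard_normal((k, n))
        c = b_n + chol_omega @ z @ chol_sigma.T
        coef_out[d] = np.ravel(c, order="F")
        sigma_out[d] = sigma
    return coef_out, sigma_out


def draw_posterior(
    prior: PriorSpec,
    panel: TimeSeriesPanel,
    spec: VARSpec,
    n_draws: int,
    seed: int,
    sigma_mode: str = "gibbs",
    burn_in: int | None = None,
) -> PosteriorDraws:
    """Posterior draws for either prior family.  Deterministic per seed.

    Parameters
    ----------
    sigma_mode
        Minnesota family only: ``"gibbs"`` (default) samples Sigma jointly
        with the coefficients; ``"fixed"`` draws i.i.d. from the analytic
        fixed-Sigma posterior (Sigma held at the OLS residual covariance for
        downstream orthogonalization).
    burn_in
        Gibbs burn-in; defaults to ``GIBBS_BURN_IN`` in Gibbs mode and 0 for
        the i.i.d. routes.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if prior.family == MINNESOTA:
        if sigma_mode == "fixed":
            coef, fixed_sigma = _draw_minnesota_fixed(
                prior, panel, spec, n_draws, rng
            )
            return PosteriorDraws(
                family=MINNESOTA,
                coef_draws=coef,
                sigma_draws=None,
                fixed_sigma=fixed_sigma,
                variable_names=list(prior.variable_names),
                order=spec.order,
                intercept=spec.intercept,
                seed=seed,
            )
        if sigma_mode != "gibbs":
            raise ValidationError("sigma_mode must be 'gibbs' or 'fixed'")
        bi = GIBBS_BURN_IN if burn_in is None else burn_in
        coef, sig = _draw_minnesota_gibbs(prior, panel, spec, n_draws, rng, bi)
        return PosteriorDraws(
            family=MINNESOTA,
            coef_draws=coef,
            sigma_draws=sig,
            fixed_sigma=None,
            variable_names=list(prior.variable_names),
            order=spec.order,
            intercept=spec.intercept,
            seed=seed,
        )
    require_family(prior, NORMAL_WISHART)
    coef, sig = _draw_normal_wishart(prior, panel, spec, n_draws, rng)
    return PosteriorDraws(
        family=NORMAL_WISHART,
        coef_draws=coef,
        sigma_draws=sig,
        fixed_sigma=None,
        variable_names=list(prior.variable_names),
        order=spec.order,
        intercept=spec.intercept,
        seed=seed,
    )
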
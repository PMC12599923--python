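"""Reduced-form VAR machinery.

Lag-design construction, equation-by-equation least-squares estimation (the
unrestricted "standard VAR" benchmark), the companion-form representation
used for impulse responses and forecasts, and lag-order selection by the
Schwarz/Bayesian information criterion.

Coefficient layout convention used package-wide: each equation's coefficient
vector is ``[intercept, lag-1 block, ..., lag-q block]`` where a lag block
lists the N variables in panel order; the stacked coefficient vector
concatenates equations (equation-major), i.e. it is ``vec(C)`` for the
``K x N`` matrix ``C`` whose columns are the equations' coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientDataError,
    SingularDesignError,
    ValidationError,
)
from .synthetic_data import TimeSeriesPanel


@dataclass
class VARSpec:
    """Estimation specification: lag order, intercept, variable ordering."""

    order: int
    intercept: bool = True
    variable_ordering: list[str] | None = None

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError("lag order must be >= 1")

    def n_regressors(self, n_variables: int) -> int:
        return n_variables * self.order + (1 if self.intercept else 0)

    def validate_ordering(self, names: list[str]) -> list[str]:
        if self.variable_ordering is None:
            return list(names)
        if sorted(self.variable_ordering) != sorted(names):
            raise ValidationError(
                "variable_ordering must be a permutation of the panel names"
            )
        return list(self.variable_ordering)


@dataclass
class VARFit:
    """An estimated reduced-form VAR."""

    coefficients: list[np.ndarray]        # B_1 .. B_q
    drift: np.ndarray                     # N (zeros when no intercept)
    sigma_u: np.ndarray                   # residual covariance, divisor T - q
    residuals: np.ndarray                 # (T - q) x N
    nobs_effective: int
    variable_names: list[str] = field(default_factory=list)
    intercept: bool = True

    @property
    def order(self) -> int:
        return len(self.coefficients)

    @property
    def n_variables(self) -> int:
        return self.drift.shape[0]

    def coefficient_matrix(self) -> np.ndarray:
        """K x N matrix with equations as columns (layout above)."""
        n, q = self.n_variables, self.order
        k = n * q + (1 if self.intercept else 0)
        c = np.zeros((k, n))
        off = 0
        if self.intercept:
            c[0] = self.drift
            off = 1
        for ell, b in enumerate(self.coefficients):
            c[off + ell * n: off + (ell + 1) * n] = b.T
        return c

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "intercept": self.intercept,
            "variable_names": self.variable_names,
            "drift": self.drift.tolist(),
            "coefficients": [b.tolist() for b in self.coefficients],
            "sigma_u": self.sigma_u.tolist(),
            "nobs_effective": self.nobs_effective,
        }


def build_lag_design(
    panel: TimeSeriesPanel, spec: VARSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Stack the VAR(q) into regression form.

    Returns ``(Y, X)``: ``Y`` has rows ``y_t'`` for ``t = q..T-1`` and the
    matching row of ``X`` is ``[1 (if intercept), y_{t-1}', ..., y_{t-q}']``.
    """
    q = spec.order
    vals = panel.values
    t_len, n = vals.shape
    if t_len <= q:
        raise InsufficientDataError(
            f"panel length {t_len} insufficient for order {q}"
        )
    y = vals[q:]
    blocks = []
    if spec.intercept:
        blocks.append(np.ones((t_len - q, 1)))
    for ell in range(1, q + 1):
        blocks.append(vals[q - ell: t_len - ell])
    x = np.hstack(blocks)
    return y, x


def ols_estimate(panel: TimeSeriesPanel, spec: VARSpec) -> VARFit:
    """Equation-by-equation least squares (the unrestricted benchmark).

    The residual covariance uses divisor ``T - q`` (no per-parameter degrees
    of freedom adjustment) so it is constant across the models compared.
    """
    y, x = build_lag_design(panel, spec)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise SingularDesignError("lagged regressor matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    t_eff = y.shape[0]
    sigma_u = resid.T @ resid / t_eff
    n = y.shape[1]
    off = 1 if spec.intercept else 0
    drift = coef[0] if spec.intercept else np.zeros(n)
    b_mats = [coef[off + ell * n: off + (ell + 1) * n].T
              for ell in range(spec.order)]
    return VARFit(
        coefficients=b_mats,
        drift=drift.copy(),
        sigma_u=sigma_u,
        residuals=resid,
        nobs_effective=t_eff,
        variable_names=list(panel.variable_names),
        intercept=spec.intercept,
    )


def companion_and_stability(
    coefficients: list[np.ndarray] | VARFit, order: int | None = None
) -> tuple[np.ndarray, bool, float]:
    """Companion matrix, stability flag and spectral radius.

    Accepts either a :class:`VARFit` or the list of per-lag matrices; the
    optional ``order`` must match the list length when given.
    """
    if isinstance(coefficients, VARFit):
        mats = coefficients.coefficients
    else:
        mats = [np.asarray(b, dtype=float) for b in coefficients]
    if order is not None and order != len(mats):
        raise ValidationError("order does not match number of matrices")
    if not mats:
        raise ValidationError("at least one coefficient matrix required")
    n = mats[0].shape[0]
    for b in mats:
        if b.shape != (n, n):
            raise ValidationError("coefficient matrices must be square, equal size")
    q = len(mats)
    comp = np.zeros((n * q, n * q))
    comp[:n] = np.hstack(mats)
    if q > 1:
        comp[n:, :-n] = np.eye(n * (q - 1))
    radius = float(np.abs(np.linalg.eigvals(comp)).max())
    return comp, radius < 1.0, radius


def ma_coefficients(
    coefficients: list[np.ndarray], horizon: int
) -> np.ndarray:
    """Moving-average matrices ``Psi_0..Psi_H`` of the VAR (``Psi_0 = I``)."""
    n = coefficients[0].shape[0]
    q = len(coefficients)
    psi = np.zeros((horizon + 1, n, n))
    psi[0] = np.eye(n)
    for h in range(1, horizon + 1):
        acc = np.zeros((n, n))
        for j in range(1, min(h, q) + 1):
            acc += coefficients[j - 1] @ psi[h - j]
        psi[h] = acc
    return psi


def select_order(
    panel: TimeSeriesPanel,
    max_order: int,
    intercept: bool = True,
) -> tuple[int, dict[int, float]]:
    """Lag order by the Schwarz (Bayesian) information criterion.

    All candidate orders are fitted on the *common sample* (the rows usable
    at ``max_order``) so criterion values are comparable.  For order q,

        BIC(q) = log det(Sigma_mle) + log(T_c)/T_c * N * (N q + intercept)

    with ``Sigma_mle`` the residual cross-product over the common sample
    divided by its length ``T_c``.  Ties break toward the smaller order.
    """
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    vals = panel.values
    t_len, n = vals.shape
    t_c = t_len - max_order
    if t_c <= max_order + 1:
        raise InsufficientDataError(
            f"panel length {t_len} too short for max_order {max_order}"
        )
    y = vals[max_order:]
    crits: dict[int, float] = {}
    for q in range(1, max_order + 1):
        blocks = [np.ones((t_c, 1))] if intercept else []
        for ell in range(1, q + 1):
            blocks.append(vals[max_order - ell: t_len - ell])
        x = np.hstack(blocks)
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        sigma = resid.T @ resid / t_c
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            # numerically singular residual covariance: unusable candidate
            logdet = np.inf
        k = n * (n * q + (1 if intercept else 0))
        crits[q] = float(logdet + np.log(t_c) / t_c * k)
    best = min(crits, key=lambda q: (crits[q], q))
    return best, crits
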
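"""Shrinkage priors for the Bayesian VAR.

The Minnesota (Litterman) prior centers every equation on a random walk with
drift: the own first-lag coefficient has prior mean 1, everything else
(including intercepts) prior mean 0.  Its diagonal prior variance for the
coefficient of lag ``l`` of variable j in equation i is

* own lag (j == i):        (lambda1 / d(l))^2
* cross lag (j != i):      (lambda1 * lambda2 / d(l))^2 * (sigma_i/sigma_j)^2
* intercept ("exogenous"): (lambda3 * sigma_i)^2

where ``d(l) = l**lambda4`` (harmonic decay, linear at lambda4 = 1) or
``d(l) = lambda4**-(l-1)`` (geometric), and sigma_i is the residual standard
deviation of a univariate autoregression for variable i.  lambda1 weighs
prior against data overall; lambda2 the cross-variable block; lambda3 the
intercept; lambda4 the lag decay.

The Normal-Wishart family is the conjugate matric-normal-inverse-Wishart
prior: coefficients ``C | Sigma ~ MN(B0, Omega0, Sigma)`` with the same
random-walk mean and per-regressor scales matching the Minnesota layout, and
``Sigma ~ IW(S0, nu0)`` with ``S0 = diag(sigma_i^2)`` and ``nu0 = N + 2`` so
the prior expectation of the error covariance is exactly ``diag(sigma_i^2)``.
The Kronecker structure cannot carry a per-pair cross-variable weight, so
lambda2 is effectively 1 in this family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, FamilyMismatchError, ValidationError
from .synthetic_data import TimeSeriesPanel
from .var_model import VARSpec

DECAY_FORMS = ("harmonic", "geometric")

MINNESOTA = "minnesota-fixed-sigma"
NORMAL_WISHART = "normal-wishart"


@dataclass
class MinnesotaHyperparams:
    """The four shrinkage hyperparameters of the Minnesota prior."""

    lambda1: float = 0.1
    lambda2: float = 0.5
    lambda3: float = 0.1
    lambda4: float = 1.0
    decay_form: str = "harmonic"

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise ValidationError("lambda1 must be > 0")
        if min(self.lambda2, self.lambda3, self.lambda4) < 0:
            raise ValidationError("lambda2, lambda3, lambda4 must be >= 0")
        if self.decay_form == "linear-harmonic":   # accepted alias
            self.decay_form = "harmonic"
        if self.decay_form not in DECAY_FORMS:
            raise ValidationError(f"decay_form must be one of {DECAY_FORMS}")

    def decay(self, lag: int) -> float:
        """Prior-s.d. decay divisor d(l) >= 1 at lag ``l``."""
        if self.decay_form == "harmonic":
            return float(lag) ** self.lambda4
        return self.lambda4 ** (-(lag - 1)) if self.lambda4 > 0 else np.inf


@dataclass
class ScaleEstimates:
    """Per-variable residual scales sigma_i from univariate autoregressions."""

    variable_names: list[str]
    sigmas: np.ndarray

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.sigmas.shape != (len(self.variable_names),):
            raise ValidationError("one sigma per variable required")
        if np.any(self.sigmas <= 0):
            raise ValidationError("scales must be positive")

    def sigma(self, name: str) -> float:
        return float(self.sigmas[self.variable_names.index(name)])


@dataclass
class PriorSpec:
    """A fully constructed prior, in the package's stacked layout.

    For the Minnesota family ``beta0``/``v0_diag`` give the mean and the
    diagonal prior variance of the stacked coefficient vector.  For the
    Normal-Wishart family ``b0_matrix`` (K x N) and ``omega0_diag`` (K) give
    the matric-normal mean and row scale, with ``wishart_scale``/
    ``wishart_dof`` the inverse-Wishart parameters for Sigma.
    """

    family: str
    variable_names: list[str]
    order: int
    intercept: bool
    beta0: np.ndarray
    v0_diag: Optional[np.ndarray] = None
    b0_matrix: Optional[np.ndarray] = None
    omega0_diag: Optional[np.ndarray] = None
    wishart_scale: Optional[np.ndarray] = None
    wishart_dof: Optional[float] = None
    hyper: Optional[MinnesotaHyperparams] = None
    scales: Optional[ScaleEstimates] = None
    coefficient_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.variable_names)
        k = n * self.order + (1 if self.intercept else 0)
        if self.beta0.shape != (n * k,):
            raise ValidationError("beta0 has wrong length for the layout")
        if self.family == MINNESOTA:
            if self.v0_diag is None or self.v0_diag.shape != (n * k,):
                raise ValidationError("Minnesota prior requires diagonal V0")
            if np.any(self.v0_diag < 0):
                raise ValidationError("V0 diagonal entries must be >= 0")
        elif self.family == NORMAL_WISHART:
            if self.wishart_dof is None or self.wishart_dof <= n - 1:
                raise ValidationError("Wishart dof must exceed N - 1")
        else:
            raise ValidationError(f"unknown prior family {self.family!r}")
        if not self.coefficient_labels:
            self.coefficient_labels = coefficient_labels(
                self.variable_names, self.order, self.intercept
            )

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "variable_names": self.variable_names,
            "order": self.order,
            "intercept": self.intercept,
            "beta0": self.beta0.tolist(),
        }
        if self.v0_diag is not None:
            out["v0_diag"] = self.v0_diag.tolist()
        if self.b0_matrix is not None:
            out["b0_matrix"] = self.b0_matrix.tolist()
            out["omega0_diag"] = self.omega0_diag.tolist()
            out["wishart_scale"] = self.wishart_scale.tolist()
            out["wishart_dof"] = self.wishart_dof
        return out


def coefficient_labels(
    names: list[str], order: int, intercept: bool
) -> list[str]:
    """Stacked-layout labels ``eq:<i>|<term>`` (equation-major)."""
    per_eq = []
    if intercept:
        per_eq.append("const")
    for ell in range(1, order + 1):
        per_eq.extend(f"L{ell}.{j}" for j in names)
    return [f"eq:{i}|{term}" for i in names for term in per_eq]


def estimate_scales(panel: TimeSeriesPanel, order: int) -> ScaleEstimates:
    """Residual standard deviation of a univariate AR(order) per variable.

    Each variable is regressed (with intercept) on its own ``order`` lags;
    the residual standard deviation uses ``T_eff - order - 1`` degrees of
    freedom.  A (near-)constant column raises :class:`DegenerateInputError`.
    """
    q = order
    t_len = panel.n_obs
    if t_len <= q + 1:
        raise ValidationError(f"need more than {q + 1} observations")
    sigmas = np.empty(panel.n_variables)
    for i, name in enumerate(panel.variable_names):
        series = panel.values[:, i]
        y = series[q:]
        x = np.column_stack(
            [np.ones(t_len - q)] + [series[q - ell: t_len - ell]
                                    for ell in range(1, q + 1)]
        )
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        dof = max(len(y) - (q + 1), 1)
        var = float(resid @ resid) / dof
        scale_ref = max(1.0, float(np.abs(series).max()))
        if var <= (1e-12 * scale_ref) ** 2:
            raise DegenerateInputError(
                f"variable {name!r} has (near) zero residual variance"
            )
        sigmas[i] = np.sqrt(var)
    return ScaleEstimates(list(panel.variable_names), sigmas)


def build_minnesota_prior(
    hyper: MinnesotaHyperparams,
    scales: ScaleEstimates,
    spec: VARSpec,
) -> PriorSpec:
    """Assemble the Minnesota prior (beta0, diagonal V0) for ``spec``."""
    names = scales.variable_names
    n = len(names)
    q = spec.order
    k = spec.n_regressors(n)
    beta0 = np.zeros(n * k)
    v0 = np.zeros(n * k)
    off = 1 if spec.intercept else 0
    for i in range(n):                       # equation i
        base = i * k
        if spec.intercept:
            v0[base] = (hyper.lambda3 * scales.sigmas[i]) ** 2
        for ell in range(1, q + 1):
            d = hyper.decay(ell)
            for j in range(n):
                pos = base + off + (ell - 1) * n + j
                if j == i:
                    if ell == 1:
                        beta0[pos] = 1.0
                    v0[pos] = (hyper.lambda1 / d) ** 2
                else:
                    ratio = scales.sigmas[i] / scales.sigmas[j]
                    v0[pos] = (hyper.lambda1 * hyper.lambda2 / d) ** 2 * ratio ** 2
    return PriorSpec(
        family=MINNESOTA,
        variable_names=list(names),
        order=q,
        intercept=spec.intercept,
        beta0=beta0,
        v0_diag=v0,
        hyper=hyper,
        scales=scales,
    )


def build_normal_wishart_prior(
    hyper: MinnesotaHyperparams,
    scales: ScaleEstimates,
    spec: VARSpec,
    wishart_dof: float | None = None,
) -> PriorSpec:
    """Conjugate matric-normal-inverse-Wishart prior.

    The Kronecker column scale reproduces the Minnesota per-lag variances
    with lambda2 forced to 1 (the structure cannot vary cross-variable
    tightness per pair); ``S0 = diag(sigma_i^2)``, ``nu0 = N + 2`` by default
    so ``E[Sigma] = S0``.  Requires lambda3 > 0 (a zero intercept scale is
    not representable with a positive-definite Omega0).
    """
    names = scales.variable_names
    n = len(names)
    q = spec.order
    k = spec.n_regressors(n)
    nu0 = float(n + 2) if wishart_dof is None else float(wishart_dof)
    if nu0 <= n - 1:
        raise ValidationError("Wishart dof must exceed N - 1")
    if spec.intercept and hyper.lambda3 <= 0:
        raise ValidationError(
            "normal-wishart family requires lambda3 > 0 (positive Omega0)"
        )
    omega0 = np.empty(k)
    off = 0
    if spec.intercept:
        omega0[0] = hyper.lambda3 ** 2
        off = 1
    for ell in range(1, q + 1):
        d = hyper.decay(ell)
        for j in range(n):
            omega0[off + (ell - 1) * n + j] = (
                (hyper.lambda1 / d) ** 2 / scales.sigmas[j] ** 2
            )
    b0 = np.zeros((k, n))
    for i in range(n):
        b0[off + i, i] = 1.0                 # own first lag
    beta0 = np.ravel(b0, order="F")
    return PriorSpec(
        family=NORMAL_WISHART,
        variable_names=list(names),
        order=q,
        intercept=spec.intercept,
        beta0=beta0,
        b0_matrix=b0,
        omega0_diag=omega0,
        wishart_scale=np.diag(scales.sigmas ** 2),
        wishart_dof=nu0,
        hyper=hyper,
        scales=scales,
    )


def require_family(prior: PriorSpec, family: str) -> None:
    if prior.family != family:
        raise FamilyMismatchError(
            f"expected a {family} prior, got {prior.family}"
        )
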
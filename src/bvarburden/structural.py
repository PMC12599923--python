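"""Recursive identification and dynamic analysis.

Orthogonalized (Cholesky) one-standard-deviation impulse responses with
posterior credible bands, forecast-error variance decompositions, and
ordering-robustness runs.  Responses are computed per posterior draw by
companion propagation of the draw's coefficients, right-multiplied by the
draw's lower-triangular covariance factor in the requested ordering; the
central estimate is the pointwise posterior median and the bands are
pointwise equal-tailed quantiles across draws.

Array convention: ``irf[h, i, j]`` is the response of variable ``i`` at
horizon ``h`` to a one-standard-deviation orthogonalized shock in variable
``j``, with variables indexed in the panel's original label order regardless
of the identification ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DecompositionError, ValidationError
from .posterior import PosteriorDraws, draw_posterior
from .priors import PriorSpec
from .synthetic_data import TimeSeriesPanel
from .var_model import VARSpec, ma_coefficients


def _band_quantiles(band_level: float) -> tuple[float, float]:
    if not 0 < band_level < 100:
        raise ValidationError("band_level must be in (0, 100)")
    alpha = (100.0 - band_level) / 2.0
    return alpha, 100.0 - alpha


def _ordering_indices(names: list[str], ordering) -> np.ndarray:
    if ordering is None:
        return np.arange(len(names))
    ordering = list(ordering)
    if sorted(ordering) != sorted(names):
        raise ValidationError(
            f"ordering {ordering} is not a permutation of {names}"
        )
    return np.array([names.index(v) for v in ordering])


@dataclass
class IRFSet:
    """Horizon-indexed orthogonalized responses with posterior bands."""

    variable_names: list[str]
    ordering: list[str]
    band_level: float
    central: np.ndarray        # (H+1, N, N) posterior median
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.central + 1e-12)
                and np.all(self.central <= self.upper + 1e-12)):
            raise ValidationError("band quantiles must bracket the median")

    @property
    def horizon(self) -> int:
        return self.central.shape[0] - 1

    def cell(self, shock: str, response: str) -> np.ndarray:
        i = self.variable_names.index(response)
        j = self.variable_names.index(shock)
        return self.central[:, i, j]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for h in range(self.horizon + 1):
            for i, resp in enumerate(self.variable_names):
                for j, shock in enumerate(self.variable_names):
                    rows.append((shock, resp, h, self.central[h, i, j],
                                 self.lower[h, i, j], self.upper[h, i, j]))
        return pd.DataFrame(
            rows, columns=["shock", "response", "horizon",
                           "central", "lower", "upper"]
        )

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "variable_names": self.variable_names,
            "ordering": self.ordering,
            "band_level": self.band_level,
            "central": self.central.tolist(),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
        }


@dataclass
class FEVDSet:
    """Cumulative forecast-error variance shares per shock."""

    variable_names: list[str]
    ordering: list[str]
    shares: np.ndarray        # (H+1, N, N): shares[h, i, j] = share of shock j

    def __post_init__(self) -> None:
        if np.any(self.shares < -1e-10) or np.any(self.shares > 1 + 1e-10):
            raise ValidationError("variance shares must lie in [0, 1]")
        sums = self.shares.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValidationError("variance shares must sum to one per cell")

    @property
    def horizon(self) -> int:
        return self.shares.shape[0] - 1

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for h in range(self.horizon + 1):
            for i, resp in enumerate(self.variable_names):
                for j, shock in enumerate(self.variable_names):
                    rows.append((resp, shock, h, self.shares[h, i, j]))
        return pd.DataFrame(
            rows, columns=["response", "shock", "horizon", "share"]
        )

    def to_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "variable_names": self.variable_names,
            "ordering": self.ordering,
            "shares": self.shares.tolist(),
        }


def orthogonalize(sigma: np.ndarray, ordering=None,
                  variable_names: list[str] | None = None) -> np.ndarray:
    """Lower-triangular-in-the-ordering factor P with ``P P' = Sigma``.

    ``ordering`` may be a permutation of ``variable_names`` (or of integer
    positions when names are omitted).  The factor is returned with rows and
    columns in the *original* label order; it is lower triangular only after
    permuting both axes into the identification ordering.
    """
    sigma = np.asarray(sigma, dtype=float)
    n = sigma.shape[0]
    if variable_names is None:
        variable_names = list(range(n))
    if ordering is None:
        perm = np.arange(n)
    else:
        perm = _ordering_indices(list(variable_names), list(ordering))
    permuted = sigma[np.ix_(perm, perm)]
    try:
        chol = np.linalg.cholesky(permuted)
    except np.linalg.LinAlgError as exc:
        raise DecompositionError(
            "covariance not positive definite in the requested ordering"
        ) from exc
    factor = np.zeros_like(sigma)
    factor[np.ix_(perm, perm)] = chol
    return factor


def irf_paths(
    draws: PosteriorDraws, horizon: int, ordering=None
) -> np.ndarray:
    """Per-draw orthogonalized responses, shape (n_draws, H+1, N, N)."""
    if draws.n_draws < 1:
        raise ValidationError("draws must be nonempty")
    if horizon < 0:
        raise ValidationError("horizon must be >= 0")
    names = draws.variable_names
    n = len(names)
    out = np.empty((draws.n_draws, horizon + 1, n, n))
    fixed_factor = None
    if draws.sigma_draws is None:
        fixed_factor = orthogonalize(draws.fixed_sigma, ordering, names)
    for d in range(draws.n_draws):
        _, b_mats = draws.coefficient_matrices(d)
        psi = ma_coefficients(b_mats, horizon)
        factor = (fixed_factor if fixed_factor is not None
                  else orthogonalize(draws.sigma_draws[d], ordering, names))
        out[d] = psi @ factor
    return out


def impulse_responses(
    draws: PosteriorDraws,
    spec: VARSpec | None = None,
    ordering=None,
    horizon: int = 10,
    band_level: float = 90.0,
) -> IRFSet:
    """Posterior median IRFs with equal-tailed credible bands.

    ``band_level`` of 90 gives the 5th/95th percentile band; 95 gives
    2.5th/97.5th.  The shock size is one standard deviation of the
    orthogonalized innovation (the Cholesky factor column).
    """
    paths = irf_paths(draws, horizon, ordering)
    lo_q, hi_q = _band_quantiles(band_level)
    central = np.median(paths, axis=0)
    lower = np.percentile(paths, lo_q, axis=0)
    upper = np.percentile(paths, hi_q, axis=0)
    names = draws.variable_names
    ordering_list = list(ordering) if ordering is not None else list(names)
    return IRFSet(
        variable_names=list(names),
        ordering=ordering_list,
        band_level=band_level,
        central=central,
        lower=lower,
        upper=upper,
    )


def fevd_shares_single(
    b_mats: list[np.ndarray], factor: np.ndarray, horizon: int
) -> np.ndarray:
    """FEVD of one model: cumulative squared orthogonalized MA weights."""
    psi = ma_coefficients(b_mats, horizon)
    theta = psi @ factor
    cum = np.cumsum(theta ** 2, axis=0)        # (H+1, N, N)
    totals = cum.sum(axis=2, keepdims=True)
    return cum / totals


def fevd(
    draws: PosteriorDraws,
    spec: VARSpec | None = None,
    ordering=None,
    horizon: int = 10,
) -> FEVDSet:
    """Posterior median variance shares, renormalized to sum to one."""
    if draws.n_draws < 1:
        raise ValidationError("draws must be nonempty")
    names = draws.variable_names
    n = len(names)
    fixed_factor = None
    if draws.sigma_draws is None:
        fixed_factor = orthogonalize(draws.fixed_sigma, ordering, names)
    all_shares = np.empty((draws.n_draws, horizon + 1, n, n))
    for d in range(draws.n_draws):
        _, b_mats = draws.coefficient_matrices(d)
        factor = (fixed_factor if fixed_factor is not None
                  else orthogonalize(draws.sigma_draws[d], ordering, names))
        all_shares[d] = fevd_shares_single(b_mats, factor, horizon)
    med = np.median(all_shares, axis=0)
    med = med / med.sum(axis=2, keepdims=True)
    ordering_list = list(ordering) if ordering is not None else list(names)
    return FEVDSet(
        variable_names=list(names), ordering=ordering_list, shares=med
    )


@dataclass
class OrderingRobustness:
    """IRFs per ordering plus a cumulative-response sign-agreement table."""

    irf_sets: dict[str, IRFSet]
    summary: pd.DataFrame       # shock, response, sign per ordering, agreement

    @property
    def all_agree(self) -> bool:
        return bool(self.summary["agreement"].all())


def ordering_robustness(
    panel: TimeSeriesPanel,
    spec: VARSpec,
    prior: PriorSpec,
    orderings: list[list[str]],
    n_draws: int = 1000,
    horizon: int = 10,
    seed: int = 0,
    band_level: float = 90.0,
    sigma_mode: str = "gibbs",
) -> OrderingRobustness:
    """Run the IRF pipeline under several orderings with a shared seed.

    The posterior draws are identical across orderings (the ordering only
    enters through the orthogonalization factor), so differences isolate the
    identification choice.  Per (shock, response) pair the summary records
    the sign of the cumulative central response under each ordering and
    whether all orderings agree.
    """
    if len(orderings) < 2:
        raise ValidationError("need at least two orderings")
    names = list(panel.variable_names)
    for o in orderings:
        _ordering_indices(names, list(o))
    draws = draw_posterior(prior, panel, spec, n_draws, seed,
                           sigma_mode=sigma_mode)
    irf_sets: dict[str, IRFSet] = {}
    signs: dict[str, np.ndarray] = {}
    for o in orderings:
        label = ",".join(o)
        irf_set = impulse_responses(draws, spec, o, horizon, band_level)
        irf_sets[label] = irf_set
        signs[label] = np.sign(irf_set.central.sum(axis=0))
    rows = []
    labels = list(irf_sets)
    for i, resp in enumerate(names):
        for j, shock in enumerate(names):
            per = [signs[lab][i, j] for lab in labels]
            rows.append(
                {"shock": shock, "response": resp,
                 **{f"sign[{lab}]": s for lab, s in zip(labels, per)},
                 "agreement": len({s for s in per}) == 1}
            )
    return OrderingRobustness(irf_sets=irf_sets, summary=pd.DataFrame(rows))


def plot_irfs(irf_set: IRFSet, path=None):
    """Optional panel-grid plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = irf_set.variable_names
    n = len(names)
    fig, axes = plt.subplots(n, n, figsize=(2.4 * n, 2.0 * n),
                             sharex=True, squeeze=False)
    h = np.arange(irf_set.horizon + 1)
    for j, shock in enumerate(names):
        for i, resp in enumerate(names):
            ax = axes[j][i]
            ax.fill_between(h, irf_set.lower[:, i, j],
                            irf_set.upper[:, i, j], alpha=0.3, color="grey")
            ax.plot(h, irf_set.central[:, i, j], color="k")
            ax.axhline(0.0, lw=0.5, color="grey")
            if j == 0:
                ax.set_title(resp, fontsize=8)
            if i == 0:
                ax.set_ylabel(f"{shock} shock", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
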
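"""Holdout forecast evaluation: standard VAR vs Bayesian VARs.

The last ``h`` observations are withheld, each model is fitted on the
remaining sample, and the held-out rows are forecast by iterating the fitted
equations ``h`` steps ahead (direct h-step recursion from a single fit).
Point forecasts use the OLS coefficients (standard VAR) or the analytic
posterior-mean coefficients (Minnesota, Normal-Wishart); averaging the
recursion over posterior draws is available behind ``use_posterior_draws``.
Scores are root-mean-squared error and mean absolute error per variable, on
the modeling scale of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .posterior import (
    compute_posterior_minnesota,
    draw_posterior,
    normal_wishart_posterior_params,
    unstack_coefficients,
)
from .priors import (
    MinnesotaHyperparams,
    build_minnesota_prior,
    build_normal_wishart_prior,
    estimate_scales,
)
from .synthetic_data import TimeSeriesPanel
from .var_model import VARSpec, ols_estimate

MODELS = ("standard-var", "minnesota", "normal-wishart")


@dataclass
class ForecastScore:
    """Per-variable RMSE and MAE for one fitted model."""

    model: str
    variable_names: list[str]
    rmse: np.ndarray
    mae: np.ndarray
    holdout: int

    def __post_init__(self) -> None:
        self.rmse = np.asarray(self.rmse, dtype=float)
        self.mae = np.asarray(self.mae, dtype=float)
        if np.any(~np.isfinite(self.rmse)) or np.any(~np.isfinite(self.mae)):
            raise ValidationError("scores must be finite")
        if np.any(self.rmse + 1e-12 < self.mae) or np.any(self.mae < 0):
            raise ValidationError("RMSE >= MAE >= 0 must hold per variable")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "model": self.model,
            "variable": self.variable_names,
            "RMSE": self.rmse,
            "MAE": self.mae,
        })


def iterate_forecast(
    drift: np.ndarray,
    b_mats: list[np.ndarray],
    history: np.ndarray,
    steps: int,
) -> np.ndarray:
    """Iterate ``y_t = drift + sum_j B_j y_{t-j}`` forward ``steps`` times.

    ``history`` holds at least q rows, most recent last.
    """
    q = len(b_mats)
    buf = list(history[-q:])
    out = np.empty((steps, drift.shape[0]))
    for s in range(steps):
        y = drift.copy()
        for j, b in enumerate(b_mats, start=1):
            y += b @ buf[-j]
        out[s] = y
        buf.append(y)
    return out


def _point_coefficients(
    train: TimeSeriesPanel,
    spec: VARSpec,
    model: str,
    hyper: MinnesotaHyperparams,
) -> tuple[np.ndarray, list[np.ndarray]]:
    if model == "standard-var":
        fit = ols_estimate(train, spec)
        return fit.drift, fit.coefficients
    scales = estimate_scales(train, spec.order)
    n = train.n_variables
    if model == "minnesota":
        prior = build_minnesota_prior(hyper, scales, spec)
        summary = compute_posterior_minnesota(prior, train, spec)
        return summary.coefficient_matrices()
    if model == "normal-wishart":
        prior = build_normal_wishart_prior(hyper, scales, spec)
        b_n, *_ = normal_wishart_posterior_params(prior, train, spec)
        stacked = np.ravel(b_n, order="F")
        return unstack_coefficients(stacked, n, spec.order, spec.intercept)
    raise ValidationError(f"unknown model {model!r}; expected one of {MODELS}")


def holdout_forecast(
    panel: TimeSeriesPanel,
    spec: VARSpec,
    model: str,
    h: int = 2,
    hyper: MinnesotaHyperparams | None = None,
    seed: int = 0,
    use_posterior_draws: bool = False,
    n_draws: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Forecast the withheld last ``h`` rows; returns (forecasts, actuals)."""
    if h < 1:
        raise ValidationError("holdout length h must be >= 1")
    t_len = panel.n_obs
    if t_len - h <= spec.order + 1:
        raise InsufficientDataError(
            f"holdout {h} leaves too few observations for order {spec.order}"
        )
    hyper = hyper or MinnesotaHyperparams()
    train = TimeSeriesPanel(
        variable_names=list(panel.variable_names),
        time_index=panel.time_index[: t_len - h],
        values=panel.values[: t_len - h],
        transform_tags=dict(panel.transform_tags),
    )
    actuals = panel.values[t_len - h:]
    history = train.values
    if use_posterior_draws and model != "standard-var":
        scales = estimate_scales(train, spec.order)
        if model == "minnesota":
            prior = build_minnesota_prior(hyper, scales, spec)
        else:
            prior = build_normal_wishart_prior(hyper, scales, spec)
        draws = draw_posterior(prior, train, spec, n_draws, seed)
        acc = np.zeros((h, panel.n_variables))
        for d in range(draws.n_draws):
            drift, b_mats = draws.coefficient_matrices(d)
            acc += iterate_forecast(drift, b_mats, history, h)
        forecasts = acc / draws.n_draws
    else:
        drift, b_mats = _point_coefficients(train, spec, model, hyper)
        forecasts = iterate_forecast(drift, b_mats, history, h)
    return forecasts, actuals


def score_forecasts(
    actuals: np.ndarray, forecasts: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable (RMSE, MAE) over the holdout steps."""
    actuals = np.asarray(actuals, dtype=float)
    forecasts = np.asarray(forecasts, dtype=float)
    if actuals.shape != forecasts.shape:
        raise ValidationError("actuals and forecasts must have equal shape")
    err = forecasts - actuals
    rmse = np.sqrt(np.mean(err ** 2, axis=0))
    mae = np.mean(np.abs(err), axis=0)
    return rmse, mae


def compare_models(
    panel: TimeSeriesPanel,
    spec: VARSpec,
    model_configs: list[dict] | None = None,
    h: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """RMSE/MAE table, one row per (model, variable).

    ``model_configs`` entries are dicts with keys ``model`` (one of
    ``MODELS``), optional ``label`` and optional ``hyper``
    (:class:`MinnesotaHyperparams`).  Defaults to all three models with the
    default hyperparameters.
    """
    if model_configs is None:
        model_configs = [{"model": m} for m in MODELS]
    if not model_configs:
        raise ValidationError("at least one model config required")
    frames = []
    for cfg in model_configs:
        model = cfg["model"]
        label = cfg.get("label", model)
        hyper = cfg.get("hyper")
        forecasts, actuals = holdout_forecast(
            panel, spec, model, h=h, hyper=hyper, seed=seed,
            use_posterior_draws=cfg.get("use_posterior_draws", False),
        )
        rmse, mae = score_forecasts(actuals, forecasts)
        score = ForecastScore(
            model=label,
            variable_names=list(panel.variable_names),
            rmse=rmse,
            mae=mae,
            holdout=h,
        )
        frames.append(score.to_frame())
    return pd.concat(frames, ignore_index=True)
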
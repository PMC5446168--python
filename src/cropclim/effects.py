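"""Percent-yield-change effect curves conditioned on climate quantiles.

A fitted model's coefficients live on the log-yield scale.  To express them
as the headline quantities -- "hot and dry conditions change yields by
x% (CI)" -- the linear predictor is evaluated at chosen anomaly values with
every variable not involved in the effect pinned at zero (its average), then
transformed by ``exp(eta) - 1`` into a relative difference.  Interaction
structure is displayed by sweeping one variable over its observed range
while the interacting variable sits at an empirical quantile: 0.05
(extreme dry / cold), 0.50 (normal), 0.95 (extreme wet / hot).

Confidence intervals are pointwise delta-method ones: the standard error of
``eta = c' beta`` is ``sqrt(c' V c)`` and the band is transformed through
the same exp-minus-one map.  The intercept and region deviations (BLUPs)
are excluded: curves describe departures from the trend expectation at
average climate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TERM_EXPONENTS

__all__ = ["QuantileSet", "climate_quantiles", "effect_at", "effect_curve"]

_VARS = ("d_temp", "d_spei", "d_temp_lag", "d_spei_lag")


@dataclass
class QuantileSet:
    """Empirical quantiles of one anomaly variable."""

    variable: str
    probs: tuple[float, ...]
    values: np.ndarray
    scope: str = "pooled"
    interpolation: str = "linear"

    def __getitem__(self, prob: float) -> float:
        return float(self.values[self.probs.index(prob)])


def climate_quantiles(
    panel: pd.DataFrame,
    variable: str,
    probs: tuple[float, ...] = (0.05, 0.50, 0.95),
    region: str | None = None,
) -> QuantileSet:
    """Empirical quantiles (linear interpolation) of an anomaly variable.

    Pooled over all rows by default; pass ``region`` for per-region scope.
    Requires at least 20 observations.
    """
    if variable not in _VARS:
        raise ValueError(f"unknown variable {variable!r}")
    sub = panel if region is None else panel[panel["region"] == region]
    x = sub[variable].dropna().to_numpy(float)
    if len(x) < 20:
        raise ValueError(f"only {len(x)} observations in scope; need >= 20")
    vals = np.quantile(x, probs, method="linear")
    return QuantileSet(variable=variable, probs=tuple(probs), values=vals,
                       scope="pooled" if region is None else str(region))


def _effect_row(fit, d_temp, d_spei, d_temp_lag, d_spei_lag) -> np.ndarray:
    """Design row over the fit's active non-intercept terms."""
    vals = np.array([d_temp, d_spei, d_temp_lag, d_spei_lag], float)
    row = []
    for t in fit.mask:
        if t == 1:
            continue
        row.append(float(np.prod(vals ** TERM_EXPONENTS[t - 1])))
    return np.array(row)


def effect_at(
    fit,
    d_temp: float = 0.0,
    d_spei: float = 0.0,
    d_temp_lag: float = 0.0,
    d_spei_lag: float = 0.0,
    data_range: dict[str, tuple[float, float]] | None = None,
) -> dict:
    """Percent yield effect and 95% CI at one anomaly point.

    ``fit`` is any object with ``mask``, ``fixef`` and ``fixef_cov``
    (mixed-model or single-region).  The intercept is excluded, so the
    all-zero anomaly point is exactly 0%.
    """
    if data_range:
        for name, v in zip(_VARS, (d_temp, d_spei, d_temp_lag, d_spei_lag)):
            if name in data_range:
                lo, hi = data_range[name]
                half = 3 * (hi - lo) / 2
                mid = (hi + lo) / 2
                if not (mid - half <= v <= mid + half):
                    warnings.warn(
                        f"{name}={v} is outside 3x the data range; extrapolating",
                        stacklevel=2)
    c = _effect_row(fit, d_temp, d_spei, d_temp_lag, d_spei_lag)
    names = [n for n in fit.term_names if n != "intercept"]
    beta = fit.fixef[names].to_numpy()
    V = fit.fixef_cov.loc[names, names].to_numpy()
    eta = float(c @ beta)
    se = float(np.sqrt(max(c @ V @ c, 0.0)))
    pct = 100 * (np.exp(eta) - 1)
    lo = 100 * (np.exp(eta - 1.96 * se) - 1)
    hi = 100 * (np.exp(eta + 1.96 * se) - 1)
    return {"eta": eta, "se": se, "effect_pct": pct, "lo_pct": lo, "hi_pct": hi}


def effect_curve(
    fit,
    panel: pd.DataFrame,
    x: str = "d_temp",
    condition: str | None = "d_spei",
    cond_prob: float = 0.50,
    n_grid: int = 101,
    region: str | None = None,
    model_id: str = "",
) -> pd.DataFrame:
    """Sweep one anomaly over [q05, q95] with another pinned at a quantile.

    Lag variables are pinned at 0 unless the curve is an intensification
    curve, i.e. ``condition`` names a lag variable, in which case that lag
    is held at its quantile while ``x`` is the current-year variable.
    Returns a tidy frame (model, x, x_value, condition, cond_value,
    effect, lo, hi) with curve metadata in the columns.
    """
    qx = climate_quantiles(panel, x, region=region)
    grid = np.linspace(qx[0.05], qx[0.95], n_grid)
    pinned = {v: 0.0 for v in _VARS}
    cond_value = 0.0
    if condition is not None:
        qc = climate_quantiles(panel, condition, region=region)
        cond_value = qc[cond_prob]
        pinned[condition] = cond_value
    rows = []
    for xv in grid:
        point = dict(pinned)
        point[x] = xv
        eff = effect_at(
            fit,
            d_temp=point["d_temp"], d_spei=point["d_spei"],
            d_temp_lag=point["d_temp_lag"], d_spei_lag=point["d_spei_lag"],
        )
        rows.append({"model": model_id, "x": x, "x_value": xv,
                     "condition": condition if condition else "",
                     "cond_prob": cond_prob if condition else np.nan,
                     "cond_value": cond_value,
                     "effect": eff["effect_pct"], "lo": eff["lo_pct"],
                     "hi": eff["hi_pct"]})
    return pd.DataFrame(rows)
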
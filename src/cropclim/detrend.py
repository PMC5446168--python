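"""Penalized-spline detrending of yield and growing-season climate series.

Long-term trends (technology trends in yields, warming trends in temperature)
would confound the year-to-year climate/yield relationship, so every series is
reduced to anomalies around a smooth trend before modelling.  The trend is a
penalized regression spline of calendar year:

* cubic B-spline basis with a small, data-length-dependent dimension
  (``max(3, n_years // 10)`` for yields, 5 for climate; doubled for series
  flagged as poorly fit),
* second-order difference ("wiggliness") penalty with the smoothing parameter
  chosen by generalized cross-validation (GCV),
* optionally a second, separately selected penalty on the span of the
  wiggliness penalty's null space (the linear-in-year component), so that a
  trendless series can be shrunk all the way to a constant.  This is the
  double-penalty shrinkage approach used for climate series, where the
  existence of a trend is an open question rather than a given.

The response for yields is the *logarithm* of yield: climate acts on yields
multiplicatively, so anomalies are relative, and log-first/detrend-second is
the order used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "TrendFit",
    "basis_dim_yield",
    "fit_trend",
    "build_anomaly_panel",
]

# smoothing-parameter grids, iterated smoothest-first so that GCV ties
# resolve toward the more parsimonious fit.  The null-space penalty is a
# discrete shrink-or-not choice: either the linear-in-year component is
# unpenalized, or the whole trend is shrunk to a constant.  This keeps
# detrending exactly invariant to adding a linear ramp whenever a trend is
# detected, while still allowing trendless series to collapse to their mean.
_LAM_SMOOTH = np.concatenate([np.logspace(9, -8, 35), [0.0]])
_LAM_NULL = np.array([1e12, 0.0])


def basis_dim_yield(n_years: int, poor_fit: bool = False) -> int:
    """Maximum spline basis dimension for a yield series of ``n_years``.

    One tenth of the series length (rounded down), floored at 3; doubled for
    series whose residuals show the trend was under-fit.
    """
    k = max(3, n_years // 10)
    return 2 * k if poor_fit else k


@dataclass
class TrendFit:
    """A fitted trend: input = trend + residuals, exactly."""

    years: np.ndarray
    values: np.ndarray
    trend: np.ndarray
    residuals: np.ndarray
    basis_dim: int
    edf: float
    lam_smooth: float
    lam_null: float | None
    shrink: bool
    penalized_to_constant: bool
    gcv: float
    series_id: str = ""

    def lag1_autocorr(self) -> float:
        r = self.residuals - self.residuals.mean()
        denom = float(r @ r)
        if denom == 0:
            return 0.0
        return float(r[1:] @ r[:-1]) / denom


def _knots(k: int) -> tuple[np.ndarray, int]:
    degree = 3 if k >= 4 else k - 1          # k=3 -> quadratic
    n_interior = k - degree - 1
    interior = np.linspace(0, 1, n_interior + 2)[1:-1]
    t = np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])
    return t, degree


def _bspline_basis(x01: np.ndarray, k: int) -> np.ndarray:
    """B-spline design with exactly ``k`` basis functions on [0, 1]."""
    t, degree = _knots(k)
    return BSpline.design_matrix(x01, t, degree).toarray()


def _curvature_penalty(k: int) -> np.ndarray:
    """Exact integrated squared second derivative penalty, ``S[i,j] =
    int B_i''(x) B_j''(x) dx`` over [0, 1].

    The null space is exactly the linear functions, so a straight-line
    trend is unpenalized.  Second derivatives of the basis are piecewise
    polynomials of degree <= 1, so 2-point Gauss quadrature per inter-knot
    interval is exact.
    """
    t, degree = _knots(k)
    breaks = np.unique(t)
    gauss_x = np.array([-1, 1]) / np.sqrt(3)
    S = np.zeros((k, k))
    eye = np.eye(k)
    for a, b in zip(breaks[:-1], breaks[1:]):
        h = (b - a) / 2
        pts = (a + b) / 2 + h * gauss_x
        d2 = np.column_stack([
            BSpline(t, eye[j], degree)(pts, nu=2) for j in range(k)
        ])
        S += h * (d2.T @ d2)                  # both Gauss weights equal 1
    return S


def fit_trend(
    years: np.ndarray,
    values: np.ndarray,
    k: int,
    shrink: bool = True,
    gamma: float = 1.4,
    series_id: str = "",
) -> TrendFit:
    """Fit a penalized spline of year with GCV-selected smoothing.

    Parameters
    ----------
    years, values
        The series; years need not be contiguous (gaps are allowed) but
        must be strictly increasing.
    k
        Maximum basis dimension (the effective dimension is selected by
        the penalty).
    shrink
        Also penalize the linear component so that a trendless series can
        be shrunk to a constant.
    gamma
        Degrees-of-freedom inflation in the GCV score,
        ``n * RSS / (n - gamma * edf)^2``.  Plain GCV (``gamma=1``) is
        known to undersmooth short series; 1.4 is the standard guard.
    """
    years = np.asarray(years, float)
    values = np.asarray(values, float)
    n = len(years)
    if n != len(values):
        raise ValueError("years and values differ in length")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    if k >= n:
        raise ValueError(f"basis dimension k={k} must be below n={n}")
    if k < 3:
        raise ValueError("basis dimension must be at least 3")

    x01 = (years - years[0]) / (years[-1] - years[0])
    B = _bspline_basis(x01, k)

    # absorb the sum-to-zero constraint: constant direction removed from B
    C = B.sum(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(C, full_matrices=True)
    Q = vt[1:].T                                  # k x (k-1)
    Bt = B @ Q

    # curvature penalty, transformed to the constrained space
    S1 = Q.T @ _curvature_penalty(k) @ Q
    ev, U = np.linalg.eigh(S1)
    s_max = ev[-1]
    S1 = S1 / s_max                               # unit spectral scale
    # null space of the wiggliness penalty within the constrained space
    null = U[:, ev < 1e-10 * s_max]
    S0 = null @ null.T

    ybar = values.mean()
    yc = values - ybar
    BtB = Bt.T @ Bt
    Bty = Bt.T @ yc
    yss = float(yc @ yc)

    lam0_grid = _LAM_NULL if shrink else np.array([0.0])
    best = None
    gcv_floor = 1e-13 * yss / n          # ties this small resolve to smoother fits
    for lam0 in lam0_grid:
        P0 = lam0 * S0
        for lam1 in _LAM_SMOOTH:
            M = BtB + lam1 * S1 + P0
            if lam1 == 0.0 and lam0 == 0.0:
                M = M + 1e-12 * np.eye(k - 1)
            try:
                coef = np.linalg.solve(M, Bty)
                edf = 1.0 + float(np.trace(np.linalg.solve(M, BtB)))
            except np.linalg.LinAlgError:
                continue
            rss = max(yss - 2 * float(coef @ Bty) + float(coef @ (BtB @ coef)), 0.0)
            denom = n - gamma * edf
            if denom <= 0:
                continue
            gcv = n * rss / denom**2
            if best is None or gcv < best[0] * (1 - 1e-10) - gcv_floor:
                best = (gcv, lam1, lam0, coef, edf)

    gcv, lam1, lam0, coef, edf = best
    trend = ybar + Bt @ coef
    residuals = values - trend
    fitobj = TrendFit(
        years=years,
        values=values,
        trend=trend,
        residuals=residuals,
        basis_dim=k,
        edf=edf,
        lam_smooth=lam1,
        lam_null=lam0 if shrink else None,
        shrink=shrink,
        penalized_to_constant=bool(edf < 1.001),
        gcv=gcv,
        series_id=series_id,
    )
    return fitobj


_CLIMATE_K = 5


@dataclass
class AnomalyPanelResult:
    """Detrended panel plus per-series diagnostics and exclusions."""

    panel: pd.DataFrame
    diagnostics: pd.DataFrame
    excluded: list[dict] = field(default_factory=list)


def build_anomaly_panel(
    yields: pd.DataFrame,
    climate: pd.DataFrame,
    poor_fit: list[tuple[str, str]] | None = None,
    min_years: int = 20,
    autocorr_warn: float = 0.5,
) -> AnomalyPanelResult:
    """Detrend log yields and growing-season climate into an anomaly panel.

    Parameters
    ----------
    yields
        Columns region, crop, year, yield (t/ha, positive).
    climate
        Columns region, crop, year, temp, spei (growing-season means).
    poor_fit
        (region, crop) pairs whose yield trend basis dimension is doubled.
    min_years
        Series shorter than this are excluded (with a log entry).

    Returns a panel with columns region, crop, year, d_yield, d_temp,
    d_spei, d_temp_lag, d_spei_lag; lags refer to calendar year t-1 and are
    missing where that year is absent.
    """
    poor_fit = set(map(tuple, poor_fit or []))
    rows, diags, excluded = [], [], []
    for (region, crop), ydf in yields.groupby(["region", "crop"], sort=True):
        ydf = ydf.sort_values("year")
        cdf = climate[(climate["region"] == region) & (climate["crop"] == crop)]
        cdf = cdf.sort_values("year")
        merged = pd.merge(ydf, cdf, on=["region", "crop", "year"], how="inner")
        n = len(merged)
        if n < min_years:
            excluded.append(
                {"region": region, "crop": crop, "n_years": n,
                 "reason": f"series shorter than minimum ({min_years})"}
            )
            continue
        yrs = merged["year"].to_numpy(float)
        k_y = basis_dim_yield(n, (region, crop) in poor_fit)
        f_y = fit_trend(yrs, np.log(merged["yield"].to_numpy(float)), k_y,
                        shrink=False, series_id=f"{region}/{crop}/log_yield")
        k_c = min(_CLIMATE_K, n - 1)
        f_t = fit_trend(yrs, merged["temp"].to_numpy(float), k_c, shrink=True,
                        series_id=f"{region}/{crop}/temp")
        f_s = fit_trend(yrs, merged["spei"].to_numpy(float), k_c, shrink=True,
                        series_id=f"{region}/{crop}/spei")
        for f in (f_y, f_t, f_s):
            if abs(f.lag1_autocorr()) > autocorr_warn:
                warnings.warn(
                    f"{f.series_id}: residual lag-1 autocorrelation "
                    f"{f.lag1_autocorr():+.2f}; consider the poor-fit list",
                    stacklevel=2,
                )
            diags.append(
                {"region": region, "crop": crop, "series": f.series_id.rsplit("/", 1)[-1],
                 "basis_dim": f.basis_dim, "edf": f.edf,
                 "penalized_to_constant": f.penalized_to_constant,
                 "resid_lag1_autocorr": f.lag1_autocorr()}
            )
        sub = pd.DataFrame(
            {"region": region, "crop": crop, "year": merged["year"].to_numpy(int),
             "d_yield": f_y.residuals, "d_temp": f_t.residuals,
             "d_spei": f_s.residuals}
        )
        # lags by calendar year t-1 (NaN where absent, incl. the first year)
        prev = sub.set_index("year")[["d_temp", "d_spei"]]
        sub["d_temp_lag"] = prev["d_temp"].reindex(sub["year"] - 1).to_numpy()
        sub["d_spei_lag"] = prev["d_spei"].reindex(sub["year"] - 1).to_numpy()
        rows.append(sub)

    if not rows:
        raise ValueError("no series passed the minimum-length requirement")
    panel = pd.concat(rows, ignore_index=True)
    return AnomalyPanelResult(panel=panel, diagnostics=pd.DataFrame(diags),
                              excluded=excluded)
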
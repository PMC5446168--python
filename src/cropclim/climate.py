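"""Growing-season, crop-area-weighted aggregation of gridded monthly climate.

Gridded monthly temperature and SPEI are reduced to one (region, crop, year)
pair of numbers in two steps: a growing-season mean over the months between
planting and harvest (whole months, inclusive on both ends), then a
crop-area-weighted mean over the grid cells of each region.  Cross-year
seasons (harvest day-of-year before planting day-of-year) are attributed to
the harvest year.  Wheat uses the four months ending at the harvest month --
the crop is dormant and climate-insensitive through winter, and the
winter/spring split in crop calendars is unreliable.  Rice may have two
weighted seasons; for maize only the main season is used.

Grids are handled as :class:`xarray.Dataset` objects with dims
``(cell, year, month)`` and variables ``temp`` and ``spei``; a long-format
CSV reader/writer is provided for interchange.
"""

from __future__ import annotations

import calendar
import warnings

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "growing_season_months",
    "season_mean",
    "area_weighted_region_mean",
    "combine_multi_season",
    "aggregate_grid",
    "grid_to_long",
    "long_to_grid",
]

# day-of-year (non-leap) of the first day of each month, 1-based months
_MONTH_START = np.cumsum([0] + [calendar.monthrange(2001, m)[1] for m in range(1, 13)])


def _month_of_doy(doy: int) -> int:
    if not 1 <= doy <= 365:
        raise ValueError(f"day-of-year {doy} outside [1, 365]")
    return int(np.searchsorted(_MONTH_START, doy, side="right"))


def growing_season_months(
    plant_doy: int, harvest_doy: int, crop_rule: str | None = None
) -> list[tuple[int, int]]:
    """Months of the growing season, as (month, year_offset) pairs.

    All months containing any day between planting and harvest (inclusive)
    are used whole; no day-weighting.  ``year_offset`` is relative to the
    harvest year (0 = harvest year, -1 = the year before), so cross-year
    seasons -- harvest day-of-year before planting day-of-year -- span the
    boundary and are attributed to the harvest year.

    ``crop_rule="wheat"`` ignores the planting date and returns exactly the
    four months ending at the harvest month.
    """
    pm, hm = _month_of_doy(plant_doy), _month_of_doy(harvest_doy)
    if crop_rule == "wheat":
        months = [(hm - k) for k in range(3, -1, -1)]
        return [(m + 12, -1) if m < 1 else (m, 0) for m in months]
    if harvest_doy >= plant_doy:
        return [(m, 0) for m in range(pm, hm + 1)]
    # cross-year season
    return [(m, -1) for m in range(pm, 13)] + [(m, 0) for m in range(1, hm + 1)]


def season_mean(monthly: dict[int, float] | pd.Series,
                months: list[tuple[int, int]] | list[int]) -> float:
    """Unweighted mean of the listed months; NaN if any month is missing.

    ``monthly`` maps month number (or (month, offset) pair) to a value.
    Plain month numbers in ``months`` are treated as offset 0.
    """
    vals = []
    for m in months:
        key = m if m in monthly else (m[0] if isinstance(m, tuple) else m)
        try:
            v = monthly[key]
        except KeyError:
            return float("nan")
        vals.append(v)
    if any(pd.isna(v) for v in vals):
        return float("nan")
    return float(np.mean(vals))


def area_weighted_region_mean(cell_values: np.ndarray, weights: np.ndarray,
                              missing_warn: float = 0.25) -> float:
    """Crop-area-weighted mean over cells, renormalized over non-missing cells.

    Weight scale is irrelevant (weights are renormalized); if more than
    ``missing_warn`` of the total weight sits on missing cells a warning is
    raised, and if everything is missing the result is NaN.
    """
    cell_values = np.asarray(cell_values, float)
    weights = np.asarray(weights, float)
    if np.any(weights < 0):
        raise ValueError("negative area weights")
    ok = ~np.isnan(cell_values)
    wtot = weights.sum()
    if wtot <= 0:
        raise ValueError("all-zero area weights")
    if not ok.any():
        return float("nan")
    frac_missing = weights[~ok].sum() / wtot
    if frac_missing > missing_warn:
        warnings.warn(
            f"{frac_missing:.0%} of region weight on missing cells", stacklevel=2
        )
    return float(weights[ok] @ cell_values[ok] / weights[ok].sum())


def combine_multi_season(
    season_panels: list[pd.DataFrame], season_weights: list[float],
    crop: str | None = None,
) -> pd.DataFrame:
    """Season-weight-average per-season climate panels into one panel.

    Panels share (region, crop, year) keys and carry temp/spei columns.
    For maize only the main (largest-weight) season is used; single-season
    crops pass through unchanged.
    """
    if len(season_panels) != len(season_weights):
        raise ValueError("season/weight count mismatch")
    w = np.asarray(season_weights, float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("season weights must sum to 1")
    if crop == "maize" and len(season_panels) > 1:
        main = int(np.argmax(w))
        return season_panels[main].copy()
    if len(season_panels) == 1:
        return season_panels[0].copy()
    out = season_panels[0].copy()
    keys = ["region", "crop", "year"]
    out = out.set_index(keys)
    acc_t = w[0] * out["temp"]
    acc_s = w[0] * out["spei"]
    for wi, p in zip(w[1:], season_panels[1:]):
        p = p.set_index(keys)
        if not p.index.equals(out.index):
            p = p.reindex(out.index)
        acc_t = acc_t + wi * p["temp"]
        acc_s = acc_s + wi * p["spei"]
    out["temp"], out["spei"] = acc_t, acc_s
    return out.reset_index()


def aggregate_grid(
    grid: xr.Dataset,
    calendar_df: pd.DataFrame,
    weights: pd.DataFrame,
    crop: str,
    crop_rule: str | None = None,
) -> pd.DataFrame:
    """Gridded monthly climate -> (region, crop, year) growing-season panel.

    Parameters
    ----------
    grid
        Dims (cell, year, month=1..12), variables temp and spei.
    calendar_df
        Columns region, crop, season, plant_doy, harvest_doy, weight.
    weights
        Columns cell, region, weight (crop area per cell).
    crop_rule
        Forwarded to :func:`growing_season_months` ("wheat" for the
        four-months-before-harvest rule).

    The first year is NaN-free only if no season crosses the year boundary;
    cross-year seasons lose their first year (no previous-year months).
    """
    cal = calendar_df[calendar_df["crop"] == crop]
    if cal.empty:
        raise ValueError(f"no calendar entries for crop {crop!r}")
    years = grid["year"].values
    rows = []
    for region, rcal in cal.groupby("region"):
        wsub = weights[weights["region"] == region]
        cells = wsub["cell"].values
        w = wsub["weight"].to_numpy(float)
        sub = grid.sel(cell=cells)
        season_panels, season_w = [], []
        for _, srow in rcal.iterrows():
            months = growing_season_months(int(srow["plant_doy"]),
                                           int(srow["harvest_doy"]), crop_rule)
            tmean = _season_cell_means(sub["temp"].values, months)
            smean = _season_cell_means(sub["spei"].values, months)
            t_reg = np.array([area_weighted_region_mean(tmean[:, j], w)
                              for j in range(len(years))])
            s_reg = np.array([area_weighted_region_mean(smean[:, j], w)
                              for j in range(len(years))])
            season_panels.append(pd.DataFrame(
                {"region": region, "crop": crop, "year": years,
                 "temp": t_reg, "spei": s_reg}))
            season_w.append(float(srow["weight"]))
        season_w = list(np.asarray(season_w) / np.sum(season_w))
        combined = combine_multi_season(season_panels, season_w, crop=crop)
        rows.append(combined.dropna(subset=["temp", "spei"]))
    return pd.concat(rows, ignore_index=True)


def _season_cell_means(arr: np.ndarray, months: list[tuple[int, int]]) -> np.ndarray:
    """(cell, year, 12) monthly array -> (cell, year) season means.

    Months with offset -1 are taken from the previous year; the first year
    is NaN in that case.
    """
    n_cell, n_year, _ = arr.shape
    stack = np.full((len(months), n_cell, n_year), np.nan)
    for i, (m, off) in enumerate(months):
        if off == 0:
            stack[i] = arr[:, :, m - 1]
        elif off == -1:
            stack[i, :, 1:] = arr[:, :-1, m - 1]
        else:
            raise ValueError(f"unsupported year offset {off}")
    return stack.mean(axis=0)   # propagates NaN: missing month -> missing cell-year


def grid_to_long(grid: xr.Dataset) -> pd.DataFrame:
    """Long-format (cell, year, month, temp, spei) CSV-ready frame."""
    return (grid.to_dataframe().reset_index()
            [["cell", "year", "month", "temp", "spei"]]
            .sort_values(["cell", "year", "month"]).reset_index(drop=True))


def long_to_grid(df: pd.DataFrame) -> xr.Dataset:
    ds = df.set_index(["cell", "year", "month"]).to_xarray()
    return ds[["temp", "spei"]]
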
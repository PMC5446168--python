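"""Synthetic climate/yield data with known ground truth.

Generates the four inputs the analysis consumes -- gridded monthly climate,
crop calendars, crop-area weights, and production/area tables -- from a
generative model that matches the statistical structure the analysis
assumes, so that every downstream stage (QC, aggregation, detrending, the
hierarchical fit, validation) can be tested against known parameters
without any external downloads.

The generative model:

* **Temperature** per cell/month/year = cell climatology + seasonal
  sinusoid + linear warming trend + a regional year anomaly shared by the
  cells of a region (weather is regional) + cell-month noise.
* **SPEI** is standard normal per (cell, month) marginally, built from a
  shared regional component plus cell noise (droughts are regional);
  optionally AR(1) across years as a stress-test.
* **Log yield** per region/year = base + smooth multiplicative technology
  trend + the 13-term anomaly expansion dotted with (global coefficients +
  per-region random deviations) + heteroscedastic noise
  ``N(0, sigma2 * phi_c)``.

Ground truth (:class:`TruthParams`) is written beside the data with a
distinct ``.truth.json`` extension so recovery tests can never confuse it
with pipeline inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .climate import aggregate_grid, grid_to_long
from .design import N_TERMS, TERM_EXPONENTS

__all__ = [
    "SyntheticConfig",
    "TruthParams",
    "gen_climate_grid",
    "gen_crop_calendar",
    "gen_area_weights",
    "gen_truth",
    "gen_region_anomalies",
    "gen_yield_panel",
    "gen_dataset",
    "SyntheticDataset",
]

# sub-stream tags so each generator op is reproducible from the seed alone,
# independent of call order
_STREAMS = {"climate": 11, "truth": 12, "weights": 13, "yield": 14, "anomalies": 15}


def _rng(config: "SyntheticConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the real data's shape: 25 producing regions observed
    1961-2014 (54 years), a handful of half-degree cells per region, a
    single March-to-September growing season, a saturating green-revolution
    yield trend of about one log unit, residual log-yield noise of 0.08,
    and region variance ratios between 0.5 and 2.
    """

    n_regions: int = 25
    n_cells_per_region: int = 4
    year_start: int = 1961
    year_end: int = 2014
    crop: str = "maize"
    #: per-season (plant_doy, harvest_doy, weight), same for all regions
    seasons: tuple[tuple[int, int, float], ...] = ((61, 266, 1.0),)
    trend_kind: str = "smooth"            # none | linear | smooth
    yield_trend_amplitude: float = 1.0    # log units over the study period
    base_log_yield: float = 0.7           # ~2 t/ha in 1961
    temp_trend_per_decade: float = 0.25   # deg C
    temp_year_anom_sd: float = 0.5        # regional growing-season anomaly scale
    temp_month_sd: float = 1.0            # cell-month weather noise
    spei_regional_rho: float = 0.8        # share of SPEI variance that is regional
    spei_ar1: float = 0.0                 # optional year-to-year persistence
    noise_sd_log_yield: float = 0.08      # residual sigma
    phi_range: tuple[float, float] = (0.5, 2.0)
    active_terms: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    beta_active: tuple[float, ...] = (0.0, -0.02, -0.01, 0.03, -0.005, -0.015)
    rel_slope_sd: float = 0.5             # random-slope sd as fraction of |beta|
    intercept_re_sd: float = 0.01
    random_sd_overrides: dict = field(default_factory=dict)
    #: anomaly scales for the direct region-anomaly generator; SPEI is a
    #: standardized index, so its region anomaly scale is ~1
    d_temp_sd: float = 0.6
    d_spei_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.n_cells_per_region < 1:
            raise ValueError("n_cells_per_region must be positive")
        if abs(sum(w for _, _, w in self.seasons) - 1.0) > 1e-8:
            raise ValueError("season weights must sum to 1")
        if not (self.phi_range[0] > 0 and self.phi_range[1] >= self.phi_range[0]):
            raise ValueError("phi_range must be a positive interval")
        if len(self.active_terms) != len(self.beta_active):
            raise ValueError("active_terms and beta_active lengths differ")
        if self.trend_kind not in ("none", "linear", "smooth"):
            raise ValueError(f"unknown trend_kind {self.trend_kind!r}")

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def trend(self, years: np.ndarray) -> np.ndarray:
        """Deterministic log-yield trend at the given years."""
        years = np.asarray(years, float)
        span = max(self.year_end - self.year_start, 1)
        u = (years - self.year_start) / span
        if self.trend_kind == "none":
            return np.zeros_like(u)
        if self.trend_kind == "linear":
            return self.yield_trend_amplitude * u
        # saturating (green-revolution-like) gain
        return self.yield_trend_amplitude * (1 - np.exp(-3 * u)) / (1 - np.exp(-3.0))


@dataclass(eq=False)
class TruthParams:
    """Generating parameters: the quantity recovery tests compare against."""

    beta: np.ndarray              # (13,) global fixed effects
    D_diag: np.ndarray            # (13,) random-effect variances
    sigma2: float
    phi: np.ndarray               # (n_regions,) variance ratios, phi[0] == 1
    b: np.ndarray                 # (n_regions, 13) realized deviations
    active: tuple[int, ...]

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        self.D_diag = np.asarray(self.D_diag, float)
        self.phi = np.asarray(self.phi, float)
        self.b = np.asarray(self.b, float)
        if np.any(self.D_diag < 0) or self.sigma2 <= 0 or np.any(self.phi <= 0):
            raise ValueError("invalid variance parameters")
        if abs(self.phi[0] - 1.0) > 1e-12:
            raise ValueError("phi for the first region must equal 1")

    def to_json(self, path) -> None:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in asdict(self).items()}
        d["active"] = list(self.active)
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthParams":
        d = json.loads(Path(path).read_text())
        d["active"] = tuple(d["active"])
        return cls(**d)


# ---------------------------------------------------------------------------
# climate grid


def gen_climate_grid(config: SyntheticConfig) -> xr.Dataset:
    """Gridded monthly temperature and SPEI, dims (cell, year, month)."""
    rng = _rng(config, "climate")
    n_reg, n_cell = config.n_regions, config.n_cells_per_region
    years = config.years
    ny = len(years)
    ncells = n_reg * n_cell
    months = np.arange(1, 13)

    clim = rng.normal(12.0, 3.0, size=ncells)                     # cell climatology
    seas_amp = rng.uniform(8.0, 12.0, size=ncells)
    seasonal = np.cos(2 * np.pi * (months - 7) / 12)              # peak in July
    trend = config.temp_trend_per_decade * (years - years[0]) / 10.0
    year_anom = rng.normal(0.0, config.temp_year_anom_sd, size=(n_reg, ny))
    month_noise = rng.normal(0.0, config.temp_month_sd, size=(ncells, ny, 12))

    temp = (clim[:, None, None]
            + seas_amp[:, None, None] * seasonal[None, None, :]
            + trend[None, :, None]
            + np.repeat(year_anom, n_cell, axis=0)[:, :, None]
            + month_noise)

    rho = config.spei_regional_rho
    u = rng.standard_normal((n_reg, ny, 12))
    v = rng.standard_normal((ncells, ny, 12))
    if config.spei_ar1 > 0:
        a = config.spei_ar1
        scale = np.sqrt(1 - a**2)
        for arr in (u, v):
            for t in range(1, ny):
                arr[:, t, :] = a * arr[:, t - 1, :] + scale * rng.standard_normal(arr[:, t, :].shape)
    spei = np.sqrt(rho) * np.repeat(u, n_cell, axis=0) + np.sqrt(1 - rho) * v

    cells = [f"{r}_C{j}" for r in config.regions for j in range(n_cell)]
    ds = xr.Dataset(
        {"temp": (("cell", "year", "month"), temp),
         "spei": (("cell", "year", "month"), spei)},
        coords={"cell": cells, "year": years, "month": months},
    )
    ds["temp_deterministic"] = (("cell", "year", "month"),
                                (clim[:, None, None]
                                 + seas_amp[:, None, None] * seasonal[None, None, :]
                                 + trend[None, :, None]) * np.ones((ncells, ny, 12)))
    return ds


def gen_crop_calendar(config: SyntheticConfig) -> pd.DataFrame:
    """Per-region calendar rows; cross-year seasons are flagged."""
    rows = []
    for region in config.regions:
        for s, (plant, harvest, weight) in enumerate(config.seasons):
            if not (1 <= plant <= 365 and 1 <= harvest <= 365):
                raise ValueError("day-of-year outside [1, 365]")
            rows.append({"region": region, "crop": config.crop, "season": s,
                         "plant_doy": plant, "harvest_doy": harvest,
                         "weight": weight, "cross_year": harvest < plant})
    return pd.DataFrame(rows)


def gen_area_weights(config: SyntheticConfig) -> pd.DataFrame:
    """Dirichlet crop-area weights per cell; sum to 1 within each region."""
    rng = _rng(config, "weights")
    rows = []
    for region in config.regions:
        w = rng.dirichlet(np.full(config.n_cells_per_region, 2.0))
        for j in range(config.n_cells_per_region):
            rows.append({"cell": f"{region}_C{j}", "region": region,
                         "weight": float(w[j])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth and yields


def gen_truth(config: SyntheticConfig) -> TruthParams:
    """Draw global coefficients, random-effect variances and realizations."""
    rng = _rng(config, "truth")
    beta = np.zeros(N_TERMS)
    D = np.zeros(N_TERMS)
    for t, bv in zip(config.active_terms, config.beta_active):
        beta[t - 1] = bv
        if t in config.random_sd_overrides:
            sd = float(config.random_sd_overrides[t])
        elif t == 1 or bv == 0.0:
            sd = config.intercept_re_sd
        else:
            sd = config.rel_slope_sd * abs(bv)
        D[t - 1] = sd**2
    b = rng.normal(0.0, np.sqrt(D)[None, :], size=(config.n_regions, N_TERMS))
    phi = rng.uniform(config.phi_range[0], config.phi_range[1],
                      size=config.n_regions)
    phi[0] = 1.0
    return TruthParams(beta=beta, D_diag=D, sigma2=config.noise_sd_log_yield**2,
                       phi=phi, b=b, active=tuple(config.active_terms))


def gen_region_anomalies(config: SyntheticConfig, lead_years: int = 1) -> pd.DataFrame:
    """Region-year climate anomalies, starting ``lead_years`` before the panel.

    Direct route to the modelling currency (no grid, no aggregation): zero
    mean draws at the growing-season anomaly scales.  The lead year(s) make
    lagged anomalies defined from ``year_start`` onwards.
    """
    rng = _rng(config, "anomalies")
    years = np.arange(config.year_start - lead_years, config.year_end + 1)
    rows = []
    for region in config.regions:
        dT = rng.normal(0.0, config.d_temp_sd, size=len(years))
        dS = rng.normal(0.0, config.d_spei_sd, size=len(years))
        rows.append(pd.DataFrame({"region": region, "crop": config.crop,
                                  "year": years, "d_temp": dT, "d_spei": dS}))
    return pd.concat(rows, ignore_index=True)


def _attach_lags(anoms: pd.DataFrame) -> pd.DataFrame:
    out = []
    for _, sub in anoms.groupby(["region"], sort=True):
        sub = sub.sort_values("year").reset_index(drop=True)
        prev = sub.set_index("year")[["d_temp", "d_spei"]]
        sub["d_temp_lag"] = prev["d_temp"].reindex(sub["year"] - 1).to_numpy()
        sub["d_spei_lag"] = prev["d_spei"].reindex(sub["year"] - 1).to_numpy()
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def gen_yield_panel(
    truth: TruthParams,
    anomalies: pd.DataFrame,
    config: SyntheticConfig,
    noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Production/area tables plus the hidden log-yield decomposition.

    ``anomalies`` holds region-year d_temp/d_spei (lags are derived here by
    calendar year; missing lags enter the generative model as zero, which
    only matters for lag-active truths on panels without a lead year).
    """
    regions = sorted(anomalies["region"].unique())
    if len(regions) != len(truth.phi):
        raise ValueError("region set does not match truth dimensions")
    rng = _rng(config, "yield")
    panel = _attach_lags(anomalies)
    keep = panel["year"] >= config.year_start
    panel = panel.loc[keep].reset_index(drop=True)
    A = panel[["d_temp", "d_spei", "d_temp_lag", "d_spei_lag"]].fillna(0.0).to_numpy()
    X = np.prod(A[:, None, :] ** TERM_EXPONENTS[None, :, :], axis=2)

    reg_index = {r: i for i, r in enumerate(regions)}
    ri = panel["region"].map(reg_index).to_numpy()
    coef = truth.beta[None, :] + truth.b[ri]
    signal = np.einsum("ij,ij->i", X, coef)
    trend = config.trend(panel["year"].to_numpy())
    eps = (rng.normal(0.0, 1.0, size=len(panel))
           * np.sqrt(truth.sigma2 * truth.phi[ri])) if noise else np.zeros(len(panel))
    log_yield = config.base_log_yield + trend + signal + eps

    area = 1e6 * np.exp(rng.normal(0.0, 0.3, size=len(regions)))
    truth_panel = panel.copy()
    truth_panel["log_trend"] = config.base_log_yield + trend
    truth_panel["signal"] = signal
    truth_panel["eps"] = eps
    truth_panel["log_yield"] = log_yield

    production = pd.DataFrame({
        "region": panel["region"], "crop": config.crop,
        "year": panel["year"].astype(int),
        "area": area[ri],
    })
    production["production"] = np.exp(log_yield) * production["area"]
    production = production[["region", "crop", "year", "production", "area"]]
    return production, truth_panel


@dataclass
class SyntheticDataset:
    """Everything one simulated study provides, observable and hidden."""

    config: SyntheticConfig
    truth: TruthParams
    grid: xr.Dataset
    calendar: pd.DataFrame
    weights: pd.DataFrame
    production: pd.DataFrame
    season_panel: pd.DataFrame     # aggregated growing-season climate (observable)
    anomalies_true: pd.DataFrame   # hidden true anomalies
    truth_panel: pd.DataFrame      # hidden log-yield decomposition

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        grid_to_long(self.grid[["temp", "spei"]]).to_csv(
            outdir / "climate_monthly.csv", index=False)
        self.calendar.to_csv(outdir / "calendar.csv", index=False)
        self.weights.to_csv(outdir / "area_weights.csv", index=False)
        self.production.to_csv(outdir / "production.csv", index=False)
        self.season_panel.to_csv(outdir / "season_climate.csv", index=False)
        self.truth.to_json(outdir / "params.truth.json")
        self.truth_panel.to_csv(outdir / "panel.truth.csv", index=False)


def gen_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Full simulated study: grid -> aggregation -> yields.

    The generator reuses the pipeline's own aggregation operators, then
    derives true anomalies by aggregating the deterministic temperature
    component the same way (for SPEI the deterministic component is zero).
    """
    grid = gen_climate_grid(config)
    calendar_df = gen_crop_calendar(config)
    weights = gen_area_weights(config)
    truth = gen_truth(config)
    crop_rule = "wheat" if config.crop == "wheat" else None

    season = aggregate_grid(grid[["temp", "spei"]], calendar_df, weights,
                            config.crop, crop_rule)
    det = (grid[["temp_deterministic"]]
           .rename({"temp_deterministic": "temp"}))
    det = det.assign(spei=xr.zeros_like(det["temp"]))
    season_det = aggregate_grid(det, calendar_df, weights, config.crop, crop_rule)
    anoms = season.merge(season_det, on=["region", "crop", "year"],
                         suffixes=("", "_det"))
    anoms["d_temp"] = anoms["temp"] - anoms["temp_det"]
    anoms["d_spei"] = anoms["spei"] - anoms["spei_det"]
    anoms = anoms[["region", "crop", "year", "d_temp", "d_spei"]]

    production, truth_panel = gen_yield_panel(truth, anoms, config)
    return SyntheticDataset(
        config=config, truth=truth, grid=grid, calendar=calendar_df,
        weights=weights, production=production,
        season_panel=season[["region", "crop", "year", "temp", "spei"]],
        anomalies_true=anoms, truth_panel=truth_panel,
    )
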
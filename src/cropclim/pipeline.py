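"""End-to-end pipeline: simulated raw data to effect curves and validation.

One call runs the full chain the analysis scripts narrate step by step:
generate (or load) raw inputs, build QC'd yields, aggregate growing-season
climate, detrend into anomalies, fit and eliminate the hierarchical model,
fit the top producers' single-region models, evaluate effect curves at
climate quantiles, and cross-validate the nested variants.  All outputs are
plain CSV/JSON; rerunning with the same seed reproduces every file
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import qc
from .country import bic_select
from .design import DesignMatrix, build_design
from .detrend import AnomalyPanelResult, build_anomaly_panel
from .effects import effect_at, effect_curve, climate_quantiles
from .mixed import MixedFit, backward_eliminate, wald_tests
from .synthetic import SyntheticConfig, SyntheticDataset, gen_dataset
from .validation import compare_models

__all__ = ["PipelineResult", "run_pipeline", "prepare_panel"]


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    yields: pd.DataFrame
    panel_result: AnomalyPanelResult
    design: DesignMatrix
    global_fit: MixedFit
    country_fits: dict
    curves: pd.DataFrame
    cv_table: pd.DataFrame
    qc_log: list


def prepare_panel(
    production: pd.DataFrame,
    season_climate: pd.DataFrame,
    exclusions: list[dict] | None = None,
    poor_fit: list[tuple[str, str]] | None = None,
    min_years: int = 20,
) -> tuple[pd.DataFrame, AnomalyPanelResult, list]:
    """QC production tables into yields and detrend into the anomaly panel."""
    yields, log = qc.compute_yield(production)
    if exclusions:
        yields, exc_log = qc.apply_exclusions(yields, exclusions)
        log += exc_log
    kept = []
    for _, series in yields.groupby(["region", "crop"], sort=True):
        filt, flog = qc.filter_repeated_production(series, min_years=min_years)
        log += flog
        kept.append(filt)
    yields = pd.concat(kept, ignore_index=True)
    panel_res = build_anomaly_panel(yields, season_climate,
                                    poor_fit=poor_fit, min_years=min_years)
    return yields, panel_res, log


def run_pipeline(
    config: SyntheticConfig | None = None,
    outdir: str | Path | None = None,
    alpha: float = 0.05,
    n_country: int = 3,
    run_cv: bool = True,
) -> PipelineResult:
    """Run the whole analysis on one simulated study.

    ``n_country`` largest regions (by total production) also get
    single-region BIC-selected fits and curves, mirroring the per-producer
    panels of the figures.
    """
    config = config or SyntheticConfig()
    ds = gen_dataset(config)
    yields, panel_res, log = prepare_panel(ds.production, ds.season_panel)
    panel = panel_res.panel
    design = build_design(panel)

    global_fit = backward_eliminate(design, alpha=alpha)

    curves = []
    for cond_prob in (0.05, 0.50, 0.95):
        curves.append(effect_curve(global_fit, panel, x="d_temp",
                                   condition="d_spei", cond_prob=cond_prob,
                                   model_id="global"))
    curves.append(effect_curve(global_fit, panel, x="d_spei",
                               condition="d_temp", cond_prob=0.50,
                               model_id="global"))

    top = (ds.production.groupby("region")["production"].sum()
           .sort_values(ascending=False).index[:n_country])
    country_fits = {}
    for region in top:
        if (design.regions == region).sum() < 18 + 5:
            continue
        cf = bic_select(design, region=region, crop=config.crop)
        country_fits[region] = cf
        for cond_prob in (0.05, 0.50, 0.95):
            curves.append(effect_curve(cf, panel, x="d_temp",
                                       condition="d_spei", cond_prob=cond_prob,
                                       region=region, model_id=str(region)))
    curves = pd.concat(curves, ignore_index=True)

    cv_table = (compare_models(design, level="global", alpha=alpha,
                               full_fit=global_fit)
                if run_cv else pd.DataFrame())

    result = PipelineResult(
        dataset=ds, yields=yields, panel_result=panel_res, design=design,
        global_fit=global_fit, country_fits=country_fits, curves=curves,
        cv_table=cv_table, qc_log=log,
    )
    if outdir is not None:
        _write(result, Path(outdir))
    return result


def _write(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.dataset.write(outdir / "data")
    res.yields.to_csv(outdir / "yields.csv", index=False)
    res.panel_result.panel.to_csv(outdir / "anomaly_panel.csv", index=False)
    res.panel_result.diagnostics.to_csv(outdir / "trend_diagnostics.csv", index=False)
    res.curves.to_csv(outdir / "effect_curves.csv", index=False)
    if len(res.cv_table):
        res.cv_table.to_csv(outdir / "loocv_table.csv", index=False)
    wald_tests(res.global_fit).to_csv(outdir / "global_wald.csv")
    fits = {"global": res.global_fit.to_dict()}
    fits.update({str(r): f.to_dict() for r, f in res.country_fits.items()})
    (outdir / "fits.json").write_text(json.dumps(fits, indent=1, sort_keys=True))
    qc.write_qc_log(res.qc_log, outdir / "qc_log.jsonl")


def headline_effects(fit: MixedFit, panel: pd.DataFrame) -> pd.DataFrame:
    """Percent effects at the hot/dry/wet quantile corners (the headline table)."""
    qt = climate_quantiles(panel, "d_temp")
    qs = climate_quantiles(panel, "d_spei")
    rows = []
    for label, dT, dS in [
        ("hot, median SPEI", qt[0.95], qs[0.50]),
        ("cold, median SPEI", qt[0.05], qs[0.50]),
        ("dry, median temp", qt[0.50], qs[0.05]),
        ("wet, median temp", qt[0.50], qs[0.95]),
        ("hot and dry", qt[0.95], qs[0.05]),
        ("hot and wet", qt[0.95], qs[0.95]),
    ]:
        eff = effect_at(fit, d_temp=dT, d_spei=dS)
        rows.append({"condition": label, "d_temp": dT, "d_spei": dS,
                     "effect_pct": eff["effect_pct"], "lo_pct": eff["lo_pct"],
                     "hi_pct": eff["hi_pct"]})
    return pd.DataFrame(rows)
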
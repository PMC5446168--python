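"""Quantile-conditioned percent-effect curves and the headline table.

Converts the fitted global model into percent-yield-change curves:
temperature swept from its 5th to 95th percentile with SPEI pinned at its
dry (0.05), normal (0.50) and wet (0.95) quantiles, and vice versa.  Also
prints the hot/dry/wet corner effects with 95% CIs and renders the curves
(black = main effect, dashed/dotted = interaction conditions, shaded CI).
"""

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cropclim.mixed import MixedFit, VarianceParams
from cropclim.effects import effect_curve
from cropclim.pipeline import headline_effects

ROOT = Path(__file__).resolve().parents[1] / "results"


def _load_global_fit() -> MixedFit:
    from cropclim.design import TERM_NAMES

    d = json.loads((ROOT / "fits.json").read_text())["global"]
    phi = pd.Series(d["phi"])
    names = [TERM_NAMES[m - 1] for m in d["mask"]]
    return MixedFit(
        mask=tuple(d["mask"]), beta=np.array([d["beta"][n] for n in names]),
        cov_beta=np.array(d["cov_beta"]),
        variance=VarianceParams(D_diag=np.array(d["D_diag"]),
                                sigma2=d["sigma2"], phi=phi),
        blup=pd.DataFrame(d["blup"]).T, loglik=d["loglik"],
        n_obs=d["n_obs"], n_regions=d["n_regions"],
        converged=d["converged"], n_iter=0,
    )


def main() -> None:
    fit = _load_global_fit()
    panel = pd.read_csv(ROOT / "anomaly_panel.csv")

    curves = []
    for x, cond in (("d_temp", "d_spei"), ("d_spei", "d_temp")):
        for q in (0.05, 0.50, 0.95):
            curves.append(effect_curve(fit, panel, x=x, condition=cond,
                                       cond_prob=q, model_id="global"))
    curves = pd.concat(curves, ignore_index=True)
    curves.to_csv(ROOT / "effect_curves.csv", index=False)

    table = headline_effects(fit, panel)
    table.to_csv(ROOT / "headline_effects.csv", index=False)
    for _, r in table.iterrows():
        print(f"{r['condition']:>18}: {r['effect_pct']:+.1f}% "
              f"({r['lo_pct']:+.1f}, {r['hi_pct']:+.1f})")

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    styles = {0.05: "--", 0.50: "-", 0.95: ":"}
    for ax, x in zip(axes, ("d_temp", "d_spei")):
        for q, sub in curves[curves["x"] == x].groupby("cond_prob"):
            ax.plot(sub["x_value"], sub["effect"], styles[q], color="k",
                    label=f"cond q{q:.2f}")
            if q == 0.50:
                ax.fill_between(sub["x_value"], sub["lo"], sub["hi"],
                                alpha=0.2, color="grey")
        ax.axhline(0, lw=0.5, color="grey")
        ax.set_xlabel(f"{x} anomaly")
    axes[0].set_ylabel("yield change [%]")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(ROOT / "effect_curves.png", dpi=120)
    print(f"curves and figure under {ROOT}")


if __name__ == "__main__":
    main()
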
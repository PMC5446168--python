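"""Measurement-error robustness of the detected interaction structure.

Adds Gaussian noise (5%..50% of each series' own sd) to the detrended log
yields, refits the selected global model without re-selection, and tracks
the p-value of the highest-order retained term over 60 replications per
level.  Writes the p-value table and the stacked-bar significance summary
to results/, and prints the noise level at which mean significance is
first lost.
"""

from pathlib import Path

import json
import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from cropclim.noise import run_noise_sim

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 20170526


def main() -> None:
    panel = pd.read_csv(ROOT / "anomaly_panel.csv")
    mask = tuple(json.loads((ROOT / "fits.json").read_text())["global"]["mask"])
    fractions = tuple(np.round(np.arange(0.05, 0.51, 0.05), 2))
    res = run_noise_sim(panel, mask=mask, fractions=fractions, reps=60,
                        master_seed=SEED, level="mixed")
    res.pvalues.to_csv(ROOT / "noise_pvalues.csv", index=False)
    res.summary.to_csv(ROOT / "noise_summary.csv", index=False)

    mp = res.mean_p()
    lost = mp[mp > 0.05]
    print(f"highest-order term group: {res.term_group}")
    print(mp.round(4).to_string())
    if len(lost):
        print(f"mean p first exceeds 0.05 at {100 * lost.index[0]:.0f}% noise")
    else:
        print("mean p stays below 0.05 up to 50% noise")

    bins = res.summary.set_index("fraction")
    ax = bins.plot.bar(stacked=True, figsize=(7, 3.5),
                       color=["#d62728", "#ff9896", "#aec7e8", "#1f77b4"])
    ax.set_ylabel("share of replications")
    ax.set_xlabel("noise sd as fraction of series sd")
    plt.tight_layout()
    plt.savefig(ROOT / "noise_significance.png", dpi=120)


if __name__ == "__main__":
    main()
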
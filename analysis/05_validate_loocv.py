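"""Leave-one-out cross-validation of the nested model variants.

Compares the selected model (Full) against the model re-selected without
interaction terms (NoInter) and a linear-terms-only model (OnlyLin), at the
pooled level and for the largest producer.  RMSE and median absolute error
on the log scale go to results/loocv_table.csv; empty cells mean the
simpler variant's formula coincided with the richer one.
"""

from pathlib import Path

import pandas as pd

from cropclim.design import build_design
from cropclim.validation import compare_models

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = pd.read_csv(ROOT / "anomaly_panel.csv")
    design = build_design(panel)
    crop = panel["crop"].iloc[0]

    rows = [compare_models(design, level="global", crop=crop)]
    yields = pd.read_csv(ROOT / "yields.csv")
    top = (yields.groupby("region")["production"].sum()
           .sort_values(ascending=False).index[0])
    rows.append(compare_models(design, level="region", region=top, crop=crop))
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(ROOT / "loocv_table.csv", index=False)
    show = table[["crop", "level", "model", "rmse", "mae", "note"]].round(4)
    print(show.to_string(index=False))


if __name__ == "__main__":
    main()
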
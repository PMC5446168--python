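"""Simulate one full study's raw inputs with known ground truth.

Generates the four inputs the analysis consumes -- gridded monthly
temperature/SPEI, a crop calendar, crop-area weights, and production/area
tables -- for 12 producing regions over 1961-2014, and writes them (plus
the hidden truth, kept under a distinct .truth extension) to
results/data/.  Downstream scripts only read the observable files.
"""

from pathlib import Path

from cropclim.synthetic import SyntheticConfig, gen_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 20170526


def main() -> None:
    cfg = SyntheticConfig(n_regions=12, n_cells_per_region=4, seed=SEED)
    ds = gen_dataset(cfg)
    ds.write(OUT)
    print(f"wrote {len(ds.production)} production records for "
          f"{cfg.n_regions} regions, {cfg.year_start}-{cfg.year_end}")
    print(f"true active terms: {ds.truth.active}; sigma = "
          f"{ds.truth.sigma2 ** 0.5:.3f}; phi in "
          f"[{ds.truth.phi.min():.2f}, {ds.truth.phi.max():.2f}]")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
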
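import numpy as np
import pandas as pd
import pytest

from cropclim.climate import (
    area_weighted_region_mean,
    combine_multi_season,
    aggregate_grid,
    growing_season_months,
    season_mean,
)
from cropclim.synthetic import SyntheticConfig, gen_area_weights, gen_climate_grid, gen_crop_calendar


class TestGrowingSeasonMonths:
    def test_march_to_september_worked_example(self):
        # planting Mar 2 (doy 61) or Mar 29 (doy 88), harvest Sep 23 (doy 266)
        # or Sep 5 (doy 248): March..September inclusive, 7 months
        for plant in (61, 88):
            for harvest in (248, 266):
                months = growing_season_months(plant, harvest)
                assert months == [(m, 0) for m in range(3, 10)]

    def test_wheat_four_months_ending_at_harvest(self):
        assert growing_season_months(280, 190, "wheat") == [(m, 0) for m in (4, 5, 6, 7)]

    def test_wheat_rule_can_cross_year(self):
        assert growing_season_months(250, 40, "wheat") == [
            (11, -1), (12, -1), (1, 0), (2, 0)]

    def test_cross_year_season(self):
        # plant Nov 10 (doy 314), harvest Feb 20 (doy 51)
        assert growing_season_months(314, 51) == [
            (11, -1), (12, -1), (1, 0), (2, 0)]

    def test_single_month_not_an_error(self):
        assert growing_season_months(32, 58) == [(2, 0)]

    def test_bad_doy_rejected(self):
        with pytest.raises(ValueError):
            growing_season_months(0, 100)


class TestSeasonMean:
    def test_constant(self):
        assert season_mean({m: 4.2 for m in range(1, 13)}, [3, 4, 5]) == 4.2

    def test_arithmetic(self):
        assert season_mean({3: 1.0, 4: 2.0, 5: 3.0}, [3, 4, 5]) == 2.0

    def test_single_month_identity(self):
        assert season_mean({7: 9.9}, [7]) == 9.9

    def test_missing_month_gives_nan(self):
        assert np.isnan(season_mean({3: 1.0}, [3, 4]))


class TestAreaWeightedMean:
    def test_equal_weights_is_mean(self):
        assert area_weighted_region_mean([1, 2, 3], [1, 1, 1]) == 2.0

    def test_weighted(self):
        assert area_weighted_region_mean([1.0, 3.0], [0.25, 0.75]) == 2.5

    def test_single_cell_identity(self):
        assert area_weighted_region_mean([5.5], [1.0]) == 5.5

    def test_missing_cells_renormalized_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            v = area_weighted_region_mean([np.nan, 3.0], [0.5, 0.5])
        assert v == 3.0

    def test_all_missing_is_nan(self):
        assert np.isnan(area_weighted_region_mean([np.nan], [1.0]))

    def test_weight_rescaling_invariance(self):
        a = area_weighted_region_mean([1.0, 4.0], [0.2, 0.8])
        b = area_weighted_region_mean([1.0, 4.0], [2.0, 8.0])
        assert a == pytest.approx(b)


def _panel(temp, spei, region="R01", crop="rice"):
    return pd.DataFrame({"region": region, "crop": crop, "year": [2000],
                         "temp": [temp], "spei": [spei]})


class TestCombineMultiSeason:
    def test_degenerate_weights(self):
        out = combine_multi_season([_panel(20.0, 0.1), _panel(30.0, -0.5)], [1.0, 0.0])
        assert out.loc[0, "temp"] == 20.0

    def test_arithmetic(self):
        out = combine_multi_season([_panel(20.0, 1.0), _panel(30.0, 0.0)], [0.5, 0.5])
        assert out.loc[0, "temp"] == 25.0 and out.loc[0, "spei"] == 0.5

    def test_maize_main_season_only(self):
        out = combine_multi_season(
            [_panel(20.0, 1.0, crop="maize"), _panel(30.0, 0.0, crop="maize")],
            [0.7, 0.3], crop="maize")
        assert out.loc[0, "temp"] == 20.0

    def test_weight_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_multi_season([_panel(1, 1)], [0.5, 0.5])


@pytest.fixture(scope="module")
def setup():
    cfg = SyntheticConfig(n_regions=2, n_cells_per_region=3,
                          year_start=2000, year_end=2005, seed=1)
    return (gen_climate_grid(cfg), gen_crop_calendar(cfg),
            gen_area_weights(cfg), cfg)


class TestAggregateGrid:

    def test_matches_hand_computation(self, setup):
        grid, cal, w, cfg = setup
        out = aggregate_grid(grid[["temp", "spei"]], cal, w, cfg.crop)
        # hand-compute region R01, year 2003, months Mar..Sep
        sub = grid.sel(cell=[f"R01_C{j}" for j in range(3)], year=2003)
        cell_means = sub["temp"].values[:, 2:9].mean(axis=1)
        wts = w[w["region"] == "R01"]["weight"].to_numpy()
        expect = float(wts @ cell_means / wts.sum())
        got = out[(out["region"] == "R01") & (out["year"] == 2003)]["temp"].iloc[0]
        assert got == pytest.approx(expect, abs=1e-12)

    def test_linearity_in_cell_values(self, setup):
        grid, cal, w, cfg = setup
        out1 = aggregate_grid(grid[["temp", "spei"]], cal, w, cfg.crop)
        scaled = grid[["temp", "spei"]].copy()
        scaled["temp"] = scaled["temp"] * 3.0
        out2 = aggregate_grid(scaled, cal, w, cfg.crop)
        np.testing.assert_allclose(out2["temp"], 3.0 * out1["temp"])
        np.testing.assert_allclose(out2["spei"], out1["spei"])

    def test_cell_order_invariance(self, setup):
        grid, cal, w, cfg = setup
        out1 = aggregate_grid(grid[["temp", "spei"]], cal, w, cfg.crop)
        w2 = w.iloc[::-1].reset_index(drop=True)
        out2 = aggregate_grid(grid[["temp", "spei"]], cal, w2, cfg.crop)
        pd.testing.assert_frame_equal(out1, out2)

    def test_cross_year_season_attributed_to_harvest_year(self):
        cfg = SyntheticConfig(n_regions=1, n_cells_per_region=1,
                              year_start=2000, year_end=2003,
                              seasons=((314, 51, 1.0),), seed=3)
        grid = gen_climate_grid(cfg)
        out = aggregate_grid(grid[["temp", "spei"]], gen_crop_calendar(cfg),
                             gen_area_weights(cfg), cfg.crop)
        # first year is lost (needs previous November/December)
        assert out["year"].min() == 2001
        t = grid["temp"].values[0]
        expect = np.mean([t[0, 10], t[0, 11], t[1, 0], t[1, 1]])
        got = out[out["year"] == 2001]["temp"].iloc[0]
        assert got == pytest.approx(expect, abs=1e-12)
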
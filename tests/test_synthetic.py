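import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cropclim.synthetic import (
    SyntheticConfig,
    gen_area_weights,
    gen_climate_grid,
    gen_crop_calendar,
    gen_dataset,
    gen_region_anomalies,
    gen_truth,
    gen_yield_panel,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="n_regions"):
            SyntheticConfig(n_regions=0)
        with pytest.raises(ValueError, match="weights"):
            SyntheticConfig(seasons=((61, 266, 0.7),))
        with pytest.raises(ValueError, match="phi_range"):
            SyntheticConfig(phi_range=(0.0, 1.0))
        with pytest.raises(ValueError, match="positive"):
            SyntheticConfig(n_cells_per_region=0)


class TestClimateGrid:
    def test_degenerate_noise_gives_identical_years(self):
        cfg = SyntheticConfig(n_regions=2, n_cells_per_region=2,
                              year_start=2000, year_end=2004,
                              temp_trend_per_decade=0.0, temp_year_anom_sd=0.0,
                              temp_month_sd=0.0, seed=0)
        t = gen_climate_grid(cfg)["temp"].values
        for y in range(1, t.shape[1]):
            np.testing.assert_allclose(t[:, y, :], t[:, 0, :])

    def test_spei_marginal_standard_normal(self):
        cfg = SyntheticConfig(n_regions=5, n_cells_per_region=5,
                              year_start=1961, year_end=2014, seed=1)
        s = gen_climate_grid(cfg)["spei"].values.ravel()
        draws = s[:10_000]
        assert abs(draws.mean()) < 0.05
        assert abs(draws.std(ddof=1) - 1) < 0.05

    def test_spei_passes_ks_in_most_seeds(self):
        # one cell per region: cells within a region share the regional
        # drought component, so the independent-draw sample for the KS
        # check uses distinct regions only
        rejections = 0
        for seed in range(20):
            cfg = SyntheticConfig(n_regions=16, n_cells_per_region=1,
                                  year_start=1961, year_end=2014, seed=seed)
            s = gen_climate_grid(cfg)["spei"].values.ravel()[:10_000]
            rejections += kstest(s, "norm").pvalue < 0.01
        assert rejections <= 1

    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(n_regions=2, year_start=2000, year_end=2003, seed=5)
        g1, g2 = gen_climate_grid(cfg), gen_climate_grid(cfg)
        np.testing.assert_array_equal(g1["temp"].values, g2["temp"].values)
        np.testing.assert_array_equal(g1["spei"].values, g2["spei"].values)

    def test_warming_trend_present(self):
        cfg = SyntheticConfig(n_regions=2, temp_trend_per_decade=1.0,
                              temp_year_anom_sd=0.0, temp_month_sd=0.0, seed=2)
        t = gen_climate_grid(cfg)["temp"].values
        decadal = t[:, 10, 0] - t[:, 0, 0]
        np.testing.assert_allclose(decadal, 1.0, atol=1e-10)


class TestCalendarAndWeights:
    def test_single_season_passthrough(self):
        cfg = SyntheticConfig(n_regions=3, seasons=((61, 266, 1.0),))
        cal = gen_crop_calendar(cfg)
        assert (cal["plant_doy"] == 61).all() and (cal["harvest_doy"] == 266).all()
        assert not cal["cross_year"].any()

    def test_two_seasons_weights_sum_to_one(self):
        cfg = SyntheticConfig(crop="rice", seasons=((32, 180, 0.7), (190, 330, 0.3)))
        cal = gen_crop_calendar(cfg)
        assert cal.groupby("region")["weight"].sum().eq(1.0).all()

    def test_cross_year_flagged(self):
        cfg = SyntheticConfig(seasons=((305, 150, 1.0),))
        assert gen_crop_calendar(cfg)["cross_year"].all()

    def test_weights_normalized_within_region(self):
        cfg = SyntheticConfig(n_regions=4, n_cells_per_region=5, seed=3)
        w = gen_area_weights(cfg)
        np.testing.assert_allclose(w.groupby("region")["weight"].sum(), 1.0)


class TestTruth:
    def test_all_zero_mask_gives_null_model(self):
        cfg = SyntheticConfig(active_terms=(), beta_active=())
        t = gen_truth(cfg)
        assert not t.beta.any() and not t.b.any()

    def test_zero_variances_give_zero_deviations(self):
        cfg = SyntheticConfig(rel_slope_sd=0.0, intercept_re_sd=0.0)
        t = gen_truth(cfg)
        assert not t.b.any()

    def test_empirical_b_variance_matches_D(self):
        cfg = SyntheticConfig(n_regions=500, seed=4)
        t = gen_truth(cfg)
        active = np.where(t.D_diag > 0)[0]
        emp = t.b[:, active].var(axis=0, ddof=1)
        np.testing.assert_allclose(emp, t.D_diag[active], rtol=0.15)

    def test_phi_first_region_pinned(self):
        t = gen_truth(SyntheticConfig(seed=9))
        assert t.phi[0] == 1.0
        assert (t.phi >= 0.5).all() and (t.phi <= 2.0).all()


class TestYieldPanel:
    def test_zero_coefficients_zero_noise_equals_trend(self):
        cfg = SyntheticConfig(n_regions=3, active_terms=(), beta_active=(),
                              seed=1, trend_kind="smooth")
        truth = gen_truth(cfg)
        anoms = gen_region_anomalies(cfg)
        prod, tp = gen_yield_panel(truth, anoms, cfg, noise=False)
        np.testing.assert_allclose(tp["log_yield"], tp["log_trend"], atol=1e-12)

    def test_heteroscedastic_residuals_scale_with_phi(self):
        cfg = SyntheticConfig(n_regions=6, seed=2, phi_range=(0.25, 4.0),
                              active_terms=(), beta_active=())
        truth = gen_truth(cfg)
        resid_var = {r: [] for r in cfg.regions}
        for rep in range(100):
            cfg_rep = SyntheticConfig(**{**cfg.__dict__, "seed": 10_000 + rep,
                                         "active_terms": (), "beta_active": ()})
            t_rep = gen_truth(cfg_rep)
            anoms = gen_region_anomalies(cfg_rep)
            _, tp = gen_yield_panel(truth, anoms, cfg_rep)
            for r, sub in tp.groupby("region"):
                resid_var[r].append(sub["eps"].var(ddof=1))
        est = np.array([np.mean(resid_var[r]) for r in cfg.regions])
        expect = truth.sigma2 * truth.phi
        np.testing.assert_allclose(est, expect, rtol=0.15)

    def test_doubling_beta_doubles_covariance_with_yield(self):
        base = dict(n_regions=1, seed=3, active_terms=(1, 2),
                    rel_slope_sd=0.0, intercept_re_sd=0.0, trend_kind="none")
        cfg1 = SyntheticConfig(**base, beta_active=(0.0, -0.02))
        cfg2 = SyntheticConfig(**base, beta_active=(0.0, -0.04))
        a = gen_region_anomalies(cfg1)
        _, tp1 = gen_yield_panel(gen_truth(cfg1), a, cfg1, noise=False)
        _, tp2 = gen_yield_panel(gen_truth(cfg2), a, cfg2, noise=False)
        c1 = np.cov(tp1["d_temp"], tp1["log_yield"])[0, 1]
        c2 = np.cov(tp2["d_temp"], tp2["log_yield"])[0, 1]
        assert c2 == pytest.approx(2 * c1, rel=1e-10)

    def test_mismatched_regions_rejected(self):
        cfg = SyntheticConfig(n_regions=3, seed=1)
        truth = gen_truth(cfg)
        anoms = gen_region_anomalies(SyntheticConfig(n_regions=2, seed=1))
        with pytest.raises(ValueError, match="region set"):
            gen_yield_panel(truth, anoms, cfg)


class TestDataset:
    def test_same_seed_identical_outputs(self, tmp_path):
        cfg = SyntheticConfig(n_regions=2, n_cells_per_region=2,
                              year_start=2000, year_end=2006, seed=7)
        d1, d2 = gen_dataset(cfg), gen_dataset(cfg)
        pd.testing.assert_frame_equal(d1.production, d2.production)
        pd.testing.assert_frame_equal(d1.season_panel, d2.season_panel)
        d1.write(tmp_path / "a")
        d2.write(tmp_path / "b")
        for f in ("production.csv", "climate_monthly.csv", "params.truth.json"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_truth_written_with_distinct_extension(self, tmp_path):
        cfg = SyntheticConfig(n_regions=2, n_cells_per_region=1,
                              year_start=2000, year_end=2003, seed=8)
        gen_dataset(cfg).write(tmp_path)
        assert (tmp_path / "params.truth.json").exists()
        from cropclim.synthetic import TruthParams
        t = TruthParams.from_json(tmp_path / "params.truth.json")
        assert t.phi[0] == 1.0
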
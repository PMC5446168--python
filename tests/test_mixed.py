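import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from conftest import model_panel
from cropclim.design import DesignMatrix, build_design
from cropclim.mixed import (
    VarianceParams,
    backward_eliminate,
    fit_mixed,
    gls_at,
    information_criteria,
    joint_wald_test,
    marginal_loglik,
    wald_tests,
)
from cropclim.synthetic import SyntheticConfig

MASK6 = (1, 2, 3, 4, 5, 6)


def _variance(regions, d_scale=0.005, sigma2=0.0064, phi=None, rng_seed=0):
    rng = np.random.default_rng(rng_seed)
    D = np.zeros(13)
    D[:6] = rng.uniform(0, d_scale, 6)
    phi_s = pd.Series(phi if phi is not None else rng.uniform(0.5, 2.0, len(regions)),
                      index=regions)
    phi_s.iloc[0] = 1.0
    return VarianceParams(D_diag=D, sigma2=sigma2, phi=phi_s)


def _brute_force_loglik(design, beta, vp, mask):
    regions = sorted(set(design.regions))
    cols = [m - 1 for m in mask]
    X, y = design.X[:, cols], design.y
    V = np.zeros((len(y), len(y)))
    for r in regions:
        sel = np.where(design.regions == r)[0]
        Xc = X[sel]
        V[np.ix_(sel, sel)] = ((Xc * vp.D_diag[cols]) @ Xc.T
                               + vp.sigma2 * float(vp.phi[r]) * np.eye(len(sel)))
    return multivariate_normal.logpdf(y, mean=X @ beta, cov=V)


class TestMarginalLoglik:
    def test_matches_joint_mvn_density(self, small_design):
        regions = sorted(set(small_design.regions))
        for seed in range(5):
            vp = _variance(regions, rng_seed=seed)
            beta = np.random.default_rng(seed).normal(0, 0.02, 6)
            ll = marginal_loglik(small_design, beta, vp, mask=MASK6)
            assert ll == pytest.approx(
                _brute_force_loglik(small_design, beta, vp, MASK6), abs=1e-8)

    def test_degenerate_limit_is_iid_normal(self, small_design):
        regions = sorted(set(small_design.regions))
        vp = VarianceParams(D_diag=np.zeros(13), sigma2=0.01,
                            phi=pd.Series(1.0, index=regions))
        beta = np.zeros(6)
        r = small_design.y - small_design.X[:, [m - 1 for m in MASK6]] @ beta
        n = len(r)
        expect = -0.5 * (n * np.log(2 * np.pi * 0.01) + r @ r / 0.01)
        assert marginal_loglik(small_design, beta, vp, mask=MASK6) == pytest.approx(
            expect, abs=1e-8)

    def test_region_permutation_invariance(self, small_design):
        regions = sorted(set(small_design.regions))
        vp = _variance(regions, rng_seed=3)
        beta = np.full(6, 0.01)
        perm = np.random.default_rng(0).permutation(small_design.n_obs)
        d2 = DesignMatrix(X=small_design.X[perm], y=small_design.y[perm],
                          regions=small_design.regions[perm],
                          index=small_design.index.iloc[perm].reset_index(drop=True))
        assert marginal_loglik(d2, beta, vp, mask=MASK6) == pytest.approx(
            marginal_loglik(small_design, beta, vp, mask=MASK6), abs=1e-8)


class TestFitMixed:
    def test_degenerate_truth_recovery(self):
        # truth has no random variation and homogeneous errors
        hits, d_small = 0, 0
        for seed in range(10):
            cfg = SyntheticConfig(n_regions=10, year_start=1985, year_end=2014,
                                  seed=seed, rel_slope_sd=0.0, intercept_re_sd=0.0,
                                  phi_range=(1.0, 1.0))
            panel = model_panel(cfg)
            d = build_design(panel)
            fit = fit_mixed(d, mask=MASK6)
            d_small += fit.variance.D_diag.max() < 1e-3
            # OLS analytic standard errors
            X = d.X[:, [m - 1 for m in MASK6]]
            bols, res, *_ = np.linalg.lstsq(X, d.y, rcond=None)
            r = d.y - X @ bols
            s2 = r @ r / (len(d.y) - 6)
            se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
            truth = panel.attrs["truth"].beta[:6]
            hits += np.all(np.abs(fit.beta - truth) < 3 * se)
        assert d_small >= 9
        assert hits >= 9

    def test_loglik_at_mle_beats_truth(self):
        wins = 0
        for seed in range(10):
            cfg = SyntheticConfig(n_regions=8, year_start=1990, year_end=2014,
                                  seed=100 + seed)
            panel = model_panel(cfg)
            truth = panel.attrs["truth"]
            d = build_design(panel)
            fit = fit_mixed(d, mask=MASK6)
            vp = VarianceParams(D_diag=truth.D_diag, sigma2=truth.sigma2,
                                phi=pd.Series(truth.phi,
                                              index=sorted(set(d.regions))))
            ll_truth = marginal_loglik(d, truth.beta[:6], vp, mask=MASK6)
            wins += fit.loglik >= ll_truth - 1e-6
        assert wins == 10

    def test_duplicating_regions_halves_beta_variance(self, small_panel):
        d = build_design(small_panel)
        p2 = small_panel.copy()
        p2["region"] = p2["region"] + "_copy"
        d2 = build_design(pd.concat([small_panel, p2], ignore_index=True))
        f1 = fit_mixed(d, mask=MASK6)
        f2 = fit_mixed(d2, mask=MASK6)
        ratio = np.diag(f2.cov_beta) / np.diag(f1.cov_beta)
        assert np.all(ratio > 0.35) and np.all(ratio < 0.65)

    def test_rescaling_equivariance(self, small_panel):
        k = 2.5
        d1 = build_design(small_panel)
        p2 = small_panel.copy()
        p2["d_temp"] = p2["d_temp"] * k
        p2["d_temp_lag"] = p2["d_temp_lag"] * k
        d2 = build_design(p2)
        f1 = fit_mixed(d1, mask=MASK6)
        f2 = fit_mixed(d2, mask=MASK6)
        names = f1.fixef.index
        assert f2.fixef["dT"] == pytest.approx(f1.fixef["dT"] / k, rel=1e-3)
        assert f2.fixef["dT2"] == pytest.approx(f1.fixef["dT2"] / k**2, rel=1e-3)
        assert f2.fixef["dT:dS"] == pytest.approx(f1.fixef["dT:dS"] / k, rel=1e-3)

    def test_deterministic_given_data(self, small_design):
        f1 = fit_mixed(small_design, mask=MASK6)
        f2 = fit_mixed(small_design, mask=MASK6)
        np.testing.assert_array_equal(f1.beta, f2.beta)
        assert f1.loglik == f2.loglik

    def test_single_region_rejected(self, small_panel):
        sub = small_panel[small_panel["region"] == small_panel["region"].iloc[0]]
        with pytest.raises(ValueError, match="at least 2 regions"):
            fit_mixed(build_design(sub), mask=MASK6)

    def test_intercept_required(self, small_design):
        with pytest.raises(ValueError, match="intercept"):
            fit_mixed(small_design, mask=(2, 4))


class TestGLS:
    def test_gls_at_zero_variance_is_ols(self, small_design):
        regions = sorted(set(small_design.regions))
        vp = VarianceParams(D_diag=np.zeros(13), sigma2=1.0,
                            phi=pd.Series(1.0, index=regions))
        beta, _ = gls_at(small_design, vp, mask=MASK6)
        X = small_design.X[:, [m - 1 for m in MASK6]]
        bols = np.linalg.lstsq(X, small_design.y, rcond=None)[0]
        np.testing.assert_allclose(beta, bols, atol=1e-8)


class TestBLUPs:
    def test_zero_D_gives_zero_blups(self):
        cfg = SyntheticConfig(n_regions=5, year_start=2000, year_end=2014, seed=2,
                              rel_slope_sd=0.0, intercept_re_sd=0.0)
        panel = model_panel(cfg)
        d = build_design(panel)
        fit = fit_mixed(d, mask=MASK6)
        if fit.variance.D_diag.max() < 1e-10:
            assert np.abs(fit.blup.to_numpy()).max() < 1e-6

    def test_precision_weighted_blups_sum_to_zero(self, small_design):
        fit = fit_mixed(small_design, mask=MASK6)
        # shrinkage identity: sum_c Z_c' V_c^-1 (y_c - X_c beta - Z_c b_c) = 0
        # at the GLS optimum when random and fixed designs coincide
        cols = [m - 1 for m in MASK6]
        total = np.zeros(len(cols))
        for r in sorted(set(small_design.regions)):
            sel = small_design.regions == r
            Xc = small_design.X[sel][:, cols]
            yc = small_design.y[sel]
            Vc = ((Xc * fit.variance.D_diag[cols]) @ Xc.T
                  + fit.variance.sigma2 * float(fit.variance.phi[r]) * np.eye(sel.sum()))
            resid = yc - Xc @ fit.beta
            total += Xc.T @ np.linalg.solve(Vc, resid)
        np.testing.assert_allclose(total, 0.0, atol=1e-6)

    def test_inactive_terms_have_zero_blups(self, small_design):
        fit = fit_mixed(small_design, mask=(1, 2, 4))
        inactive = [c for c in fit.blup.columns if c not in ("intercept", "dT", "dS")]
        assert (fit.blup[inactive] == 0).all().all()


class TestWald:
    def test_z_to_p_mapping(self, small_design):
        fit = fit_mixed(small_design, mask=MASK6)
        t = wald_tests(fit)
        row = t.iloc[1]
        assert row["p"] == pytest.approx(
            2 * (1 - __import__("scipy.stats", fromlist=["norm"]).norm.cdf(abs(row["z"]))))

    def test_joint_single_term_equals_squared_z(self, small_design):
        fit = fit_mixed(small_design, mask=MASK6)
        j = joint_wald_test(fit, (6,))
        z = wald_tests(fit).loc["dT:dS", "z"]
        assert j["stat"] == pytest.approx(z**2, rel=1e-10)
        assert j["df"] == 1


class TestInformationCriteria:
    def test_bic_parameter_penalty(self, small_design):
        f1 = fit_mixed(small_design, mask=MASK6)
        f2 = fit_mixed(small_design, mask=(1, 2, 3, 4, 5))
        ic1, ic2 = information_criteria(f1), information_criteria(f2)
        # one extra fixed effect + one extra variance parameter
        assert ic1["n_params"] - ic2["n_params"] == 2
        assert ic1["BIC"] == pytest.approx(
            -2 * f1.loglik + ic1["n_params"] * np.log(f1.n_obs))

    def test_adding_response_constant_leaves_delta_bic(self, small_panel):
        d1 = build_design(small_panel)
        p2 = small_panel.copy()
        p2["d_yield"] = p2["d_yield"] + 5.0
        d2 = build_design(p2)
        delta1 = (information_criteria(fit_mixed(d1, mask=MASK6))["BIC"]
                  - information_criteria(fit_mixed(d1, mask=(1, 2, 4)))["BIC"])
        delta2 = (information_criteria(fit_mixed(d2, mask=MASK6))["BIC"]
                  - information_criteria(fit_mixed(d2, mask=(1, 2, 4)))["BIC"])
        assert delta1 == pytest.approx(delta2, abs=1e-4)


class TestBackwardElimination:
    def test_strong_terms_retained(self):
        cfg = SyntheticConfig(n_regions=12, year_start=1975, year_end=2014,
                              seed=5, active_terms=(1, 2),
                              beta_active=(0.0, -0.05), rel_slope_sd=0.2)
        panel = model_panel(cfg)
        fit = backward_eliminate(build_design(panel), start_mask=(1, 2, 4, 10))
        assert 2 in fit.mask

    def test_marginality_in_elimination_trace(self, study_design):
        fit = backward_eliminate(study_design, start_mask=(1, 2, 3, 4, 5, 6))
        # every intermediate and final mask respects marginality: whenever a
        # higher-order term is retained, all terms it contains are retained
        from cropclim.design import contains
        masks = [tuple(t["mask"]) for t in fit.trace] + [fit.mask]
        for m in masks:
            for outer in m:
                for inner in range(1, 14):
                    if contains(outer, inner):
                        assert inner in m

    def test_all_significant_returns_full(self):
        cfg = SyntheticConfig(n_regions=20, seed=8, active_terms=(1, 2, 4),
                              beta_active=(0.0, -0.1, 0.1), rel_slope_sd=0.1)
        panel = model_panel(cfg)
        fit = backward_eliminate(build_design(panel), start_mask=(1, 2, 4))
        assert fit.mask == (1, 2, 4)
        assert fit.trace == []
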
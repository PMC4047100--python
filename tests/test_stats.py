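import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import sahpkit as sk
from sahpkit.synth import CohortGenParams
from sahpkit.stats import (
    build_long_table, fit_lme, lrt, interaction_lrt, cooks_screen,
    screen_and_mask, impute, pool, pool_scalar, correlate_sahp_spikes,
    power_curve, analytic_power, simulate_rejection, effect_spec_from_lme,
    _prepare, STEP_CENTER, STEP_SCALE,
)

from _oracles import loo_cooks


def null_params(**kw):
    base = dict(sahp_interaction_slope=0.0, seed=0)
    base.update(kw)
    return CohortGenParams(**base)


def make_table(params):
    table, _, gt = sk.generate_cohort(None, None, params)
    return table, gt


class TestBuildLongTable:
    def _cells(self, n=2):
        cells = []
        for i in range(n):
            cell = sk.CellRecord(cell_id=f"c{i}", group_label="vehicle")
            cell.features["ahp"] = {
                float(s): sk.AHPFit(v_med=-3.0, tau_med=150.0, v_slow=-1.0,
                                    tau_slow=5000.0, r2=0.9, sse=1.0,
                                    peak_amp=-4.0, t_fit_start=1.0,
                                    converged="ok")
                for s in sk.DEPOL_STEP_GRID
            }
            cells.append(cell)
        return cells

    def test_two_cells_give_26_rows(self):
        table = build_long_table(self._cells(2), "v_slow")
        assert len(table) == 26
        assert not table["missing"].any()

    def test_failed_fit_flagged_not_dropped(self):
        cells = self._cells(2)
        cells[0].features["ahp"][300.0] = replace(
            cells[0].features["ahp"][300.0], converged="failed")
        table = build_long_table(cells, "v_slow")
        assert len(table) == 26
        assert table["missing"].sum() == 1

    def test_generator_bookkeeping(self):
        params = null_params(missing_frac=0.1, seed=3)
        table, gt = make_table(params)
        assert len(table) == 13 * sum(params.n_cells_per_group)
        assert table["missing"].sum() == gt.n_missing


class TestFitLme:
    def test_zero_random_effects_matches_ols(self):
        """Balanced data: the GLS fixed effects coincide with OLS."""
        table, _ = make_table(null_params(random_intercept_sd=0.0,
                                          random_slope_sd=0.0, seed=1))
        res = fit_lme(table)
        df = _prepare(table)
        X = np.column_stack([
            np.ones(len(df)), df["treated"], df["step_c"],
            df["treated"] * df["step_c"],
        ])
        beta, *_ = np.linalg.lstsq(X, df["response"].to_numpy(), rcond=None)
        np.testing.assert_allclose(res.params.to_numpy(), beta, atol=1e-6)

    def test_recovers_generative_interaction(self):
        gamma = 0.003  # mV/pA
        ests = []
        rng = np.random.default_rng(0)
        for _ in range(20):
            table, _ = make_table(CohortGenParams(
                sahp_interaction_slope=gamma,
                seed=int(rng.integers(0, 2**31 - 1))))
            res = fit_lme(table)
            ests.append(-res.params[res.interaction_name] / STEP_SCALE)
        bias = np.mean(ests) - gamma
        assert abs(bias) < 0.1 * gamma + 2 * np.std(ests) / np.sqrt(20)

    def test_too_few_cells_rejected(self):
        table, _ = make_table(null_params(n_cells_per_group=(1, 1)))
        with pytest.raises(ValueError, match="at least 2 cells"):
            fit_lme(table)

    def test_step_factor_coding_has_12_df_interaction(self):
        table, _ = make_table(null_params(seed=5))
        res, full, red = interaction_lrt(table, step_factor=True)
        assert res.df == 12


class TestLrt:
    def test_identical_models_give_zero(self):
        table, _ = make_table(null_params(seed=2))
        full = fit_lme(table)
        out = lrt(full, full)
        assert out.chi_square == 0.0 and out.p_value == 1.0 and out.df == 0

    def test_interaction_df_is_one_with_continuous_coding(self):
        table, _ = make_table(null_params(seed=2))
        res, _, _ = interaction_lrt(table)
        assert res.df == 1
        assert res.chi_square >= 0.0

    def test_quick_type_one_error_sanity(self):
        rng = np.random.default_rng(10)
        rej = 0
        n = 40
        for _ in range(n):
            table, _ = make_table(null_params(
                seed=int(rng.integers(0, 2**31 - 1))))
            res, _, _ = interaction_lrt(table)
            rej += res.p_value < 0.05
        assert rej / n < 0.175  # generous small-sample band


class TestCooksScreen:
    def test_matches_leave_one_out_refits(self):
        table, _ = make_table(null_params(n_cells_per_group=(3, 2), seed=6))
        res = fit_lme(table)
        rep = cooks_screen(table, res)
        brute = loo_cooks(table, fit_lme, p=len(res.params))
        mask = ~np.isnan(brute)
        rho = pd.Series(rep.distances.to_numpy()[mask]).corr(
            pd.Series(brute[mask]), method="spearman")
        assert rho > 0.95

    def test_gls_approximation_tracks_refit(self):
        table, _ = make_table(null_params(n_cells_per_group=(3, 2), seed=6))
        res = fit_lme(table)
        exact = cooks_screen(table, res, method="refit").distances
        fast = cooks_screen(table, res, method="gls").distances
        rho = exact.corr(fast, method="spearman")
        assert rho > 0.8

    def test_gross_outlier_attains_max_and_flagged(self):
        table, _ = make_table(null_params(n_cells_per_group=(5, 4), seed=7))
        idx = table.index[60]
        table.loc[idx, "response"] += 20 * 0.3  # 20 residual sds
        res = fit_lme(table)
        rep = cooks_screen(table, res)
        assert rep.distances.idxmax() == idx
        assert idx in rep.flagged
        assert rep.cutoff == pytest.approx(4.0 / res.n_obs)

    def test_clean_null_flag_rate_low(self):
        table, _ = make_table(null_params(n_cells_per_group=(5, 4), seed=8))
        res = fit_lme(table)
        rep = cooks_screen(table, res)
        assert rep.n_flagged / res.n_obs < 0.12

    def test_screen_and_mask_sets_missing(self):
        table, gt = make_table(null_params(n_cells_per_group=(5, 4), seed=9,
                                           outlier_frac=0.06,
                                           outlier_scale=12.0))
        assert gt.n_outliers >= 1
        res = fit_lme(table)
        masked = screen_and_mask(table, res)
        assert masked["missing"].sum() >= 1
        assert masked.loc[masked["missing"], "response"].isna().all()


class TestImpute:
    def test_no_missing_returns_copies(self):
        table, _ = make_table(null_params(seed=1))
        out = impute(table, m=3)
        assert len(out) == 3
        for comp in out:
            pd.testing.assert_frame_equal(comp, table)

    def test_deterministic_under_seed(self):
        table, _ = make_table(null_params(missing_frac=0.1, seed=4))
        a = impute(table, m=2, seed=5)
        b = impute(table, m=2, seed=5)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_imputed_values_in_plausible_range(self):
        table, _ = make_table(null_params(missing_frac=0.1, seed=4))
        obs = table["response"].dropna()
        lo = obs.min() - 3 * obs.std()
        hi = obs.max() + 3 * obs.std()
        for comp in impute(table, m=5, seed=0):
            filled = comp.loc[comp["imputed"], "response"]
            assert filled.between(lo, hi).all()
            assert not comp["response"].isna().any()

    def test_all_missing_cell_dropped_with_warning(self):
        table, _ = make_table(null_params(seed=4))
        cell0 = table["cell_id"] == "c000"
        table.loc[cell0, "response"] = np.nan
        table.loc[cell0, "missing"] = True
        with pytest.warns(UserWarning, match="dropping 1 cell"):
            out = impute(table, m=2, seed=0)
        assert "c000" not in set(out[0]["cell_id"])

    def test_masked_truth_recovery(self):
        """MCAR deletion: the pooled interaction estimate stays close to the
        complete-data estimate."""
        full, _ = make_table(null_params(sahp_interaction_slope=0.003,
                                         seed=12))
        res_full = fit_lme(full)
        name = res_full.interaction_name
        masked = full.copy()
        rng = np.random.default_rng(0)
        drop = rng.choice(masked.index, size=int(0.1 * len(masked)),
                          replace=False)
        masked.loc[drop, "response"] = np.nan
        masked.loc[drop, "missing"] = True
        fits = [fit_lme(c) for c in impute(masked, m=8, seed=1)]
        pooled = pool_scalar(
            np.array([f.params[name] for f in fits]),
            np.array([f.bse[name] ** 2 for f in fits]))
        assert pooled.estimate == pytest.approx(
            res_full.params[name], abs=3 * pooled.se)


class TestPool:
    def test_identical_results_pool_to_single_fit(self):
        table, _ = make_table(null_params(seed=3))
        res = fit_lme(table)
        pooled = pool([res, res, res])
        for name in res.params.index:
            assert pooled.loc[name, "estimate"] == pytest.approx(
                res.params[name])
            assert pooled.loc[name, "se"] == pytest.approx(res.bse[name])

    def test_pooled_se_at_least_within_se(self):
        tables = [make_table(null_params(missing_frac=0.1, seed=s))[0]
                  for s in (20,)]
        fits = [fit_lme(c) for c in impute(tables[0], m=5, seed=2)]
        pooled = pool(fits)
        name = fits[0].interaction_name
        within = np.mean([f.bse[name] ** 2 for f in fits])
        assert pooled.loc[name, "se"] ** 2 >= within - 1e-12

    def test_lrt_pooling_reduces_to_chi_square_for_m1(self):
        table, _ = make_table(null_params(seed=3))
        res, _, _ = interaction_lrt(table)
        pooled = pool([res])
        assert pooled.p_value == pytest.approx(res.p_value)


class TestCorrelation:
    def _tables(self, coupled=True):
        rows_a, rows_b = [], []
        rng = np.random.default_rng(0)
        for grp in ("vehicle", "treated"):
            for step in sk.DEPOL_STEP_GRID:
                n = 0.05 * (step - 125.0)
                sahp = -0.01 * n + (0.0 if coupled
                                    else rng.normal(0, 0.5))
                rows_a.append({"cell_id": "c0", "group": grp, "step": step,
                               "response": sahp})
                rows_b.append({"cell_id": "c0", "group": grp, "step": step,
                               "response": n})
        return pd.DataFrame(rows_a), pd.DataFrame(rows_b)

    def test_exact_linear_relation_gives_minus_one(self):
        a, b = self._tables(coupled=True)
        out = correlate_sahp_spikes(a, b)
        for r, p in out.values():
            assert r == pytest.approx(-1.0, abs=1e-9)
            assert p < 1e-6

    def test_permuted_pairing_decorrelates(self):
        a, b = self._tables(coupled=True)
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(50):
            perm = a.copy()
            perm["response"] = rng.permutation(perm["response"].to_numpy())
            rs.append(correlate_sahp_spikes(perm, b)["vehicle"][0])
        assert abs(np.mean(rs)) < 0.15

    def test_too_few_points_rejected(self):
        a, b = self._tables()
        a = a[a["step"] < 200]
        b = b[b["step"] < 200]
        with pytest.raises(ValueError, match="fewer than 3"):
            correlate_sahp_spikes(a, b)


class TestPower:
    def test_analytic_power_increases_with_n_and_effect(self):
        eff = CohortGenParams(sahp_interaction_slope=0.001)
        p35 = analytic_power(eff, 35)
        p70 = analytic_power(eff, 70)
        assert p70 > p35
        assert analytic_power(replace(eff, sahp_interaction_slope=0.0),
                              70) == pytest.approx(0.05, abs=1e-9)

    def test_simulated_power_tracks_analytic(self):
        eff = CohortGenParams(sahp_interaction_slope=0.0015,
                              random_intercept_sd=0.3)
        phat, se = simulate_rejection(eff, alpha=0.05, n_sim=60, seed=3)
        expect = analytic_power(eff, 35)
        assert phat == pytest.approx(expect, abs=3 * se + 0.05)

    def test_power_curve_shape(self):
        eff = CohortGenParams(sahp_interaction_slope=0.0015)
        pc = power_curve(eff, n_grid=(20, 60), n_sim=40, seed=4)
        assert pc.power[1] >= pc.power[0] - 2 * (pc.mc_se[0] + pc.mc_se[1])

    def test_effect_spec_round_trip_from_lme(self):
        gamma = 0.003
        table, _ = make_table(CohortGenParams(sahp_interaction_slope=gamma,
                                              seed=13))
        res = fit_lme(table)
        eff = effect_spec_from_lme(res)
        assert eff.sahp_interaction_slope == pytest.approx(gamma, abs=0.0015)
        assert eff.residual_sd == pytest.approx(0.3, abs=0.1)
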
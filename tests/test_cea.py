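"""Within-trial analysis: SUR vs OLS oracle, ICER rules, bootstrap, CEAC,
multiple imputation and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from uroecon.cea import (
    MISpec, bootstrap_ce, build_analysis_frame, ceac, classify_icer, impute,
    mi_within_trial, pool_rubin, run_within_trial, sur_adjusted_increments,
)
from uroecon.synthdata import MissingSpec, default_config, simulate_trial


def random_frame(rng, n_per_arm=60):
    n = 2 * n_per_arm
    arm = np.repeat([0, 1], n_per_arm)
    stratum = rng.integers(0, 2, n)
    base = rng.normal(0.8, 0.1, n)
    cost = 2000 + 1500 * arm + 300 * stratum + rng.normal(0, 500, n)
    qaly = 1.6 + 0.05 * arm + 0.5 * (base - 0.8) + rng.normal(0, 0.2, n)
    return pd.DataFrame({"cost": cost, "qaly": qaly, "arm": arm,
                         "stratum": stratum, "base_utility": base,
                         "complete": True})


class TestSur:
    def test_matches_single_equation_ols_on_random_frames(self):
        """With identical regressors SUR point estimates equal per-equation
        least squares; statsmodels OLS is the independent oracle."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            frame = random_frame(rng)
            fit = sur_adjusted_increments(frame)
            X = sm.add_constant(frame[["arm", "stratum", "base_utility"]])
            for y, ours in (("cost", fit.coef_cost), ("qaly", fit.coef_qaly)):
                ols = sm.OLS(frame[y], X).fit()
                assert np.allclose(ours, ols.params.to_numpy(), atol=1e-8)

    def test_arm_only_model_equals_raw_mean_difference(self):
        frame = random_frame(np.random.default_rng(7))
        fit = sur_adjusted_increments(frame, regressors=("arm",))
        raw = frame.groupby("arm")[["cost", "qaly"]].mean()
        assert fit.delta_cost == pytest.approx(raw.loc[1, "cost"] - raw.loc[0, "cost"])
        assert fit.delta_qaly == pytest.approx(raw.loc[1, "qaly"] - raw.loc[0, "qaly"])

    def test_adjusted_means_differ_by_arm_coefficient(self):
        fit = sur_adjusted_increments(random_frame(np.random.default_rng(8)))
        up, ut = fit.adjusted_means["urethroplasty"], fit.adjusted_means["urethrotomy"]
        assert up[0] - ut[0] == pytest.approx(fit.delta_cost)
        assert up[1] - ut[1] == pytest.approx(fit.delta_qaly)

    def test_singular_design_names_collinear_column(self):
        frame = random_frame(np.random.default_rng(9))
        frame["stratum"] = 1  # constant -> collinear with intercept
        with pytest.raises(ValueError, match="stratum"):
            sur_adjusted_increments(frame)

    def test_parameter_recovery_with_built_in_increments(
            self, exact_config, unit_costs, toy_tariff):
        delta_min = 2000.0 / unit_costs.unit_cost("theatre_minute")
        cfg = exact_config(n_per_arm=5000, delta_theatre_min=delta_min, seed=3,
                           between_sd=0.10, within_sd=0.05)
        for arm in cfg.arms.values():
            arm.theatre_minutes = (arm.theatre_minutes[0], 25.0)
            arm.utility_traj = dict.fromkeys(arm.utility_traj, 0.85)
        records, truth = simulate_trial(cfg, unit_costs, toy_tariff)
        frame = build_analysis_frame(records, unit_costs, toy_tariff,
                                     discount_costs=False)
        fit = sur_adjusted_increments(frame)
        se_c, se_e = fit.se_delta
        assert truth.incremental_qaly == 0.0
        assert abs(fit.delta_cost - 2000.0) < 3 * se_c
        assert abs(fit.delta_qaly) < 3 * se_e


class TestClassifyIcer:
    @pytest.mark.parametrize("dc,de,label,value", [
        (2148.0, -0.01, "dominated", None),   # costlier, less effective
        (-100.0, 0.2, "dominant", None),
        (1500.0, 0.005, "icer", 300_000.0),
        (-900.0, -0.01, "icer", 90_000.0),    # south-west quadrant
        (500.0, 0.0, "dominated", None),      # cost-minimisation tie rule
        (-500.0, 0.0, "dominant", None),
    ])
    def test_quadrants(self, dc, de, label, value):
        got_label, got_value = classify_icer(dc, de)
        assert got_label == label
        if value is None:
            assert got_value is None
        else:
            assert got_value == pytest.approx(value)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_icer(np.nan, 0.1)


class TestBootstrapCeac:
    def test_zero_variance_draws_equal_point_estimate(self):
        frame = random_frame(np.random.default_rng(11))
        frame["cost"] = 1000.0 + 500.0 * frame["arm"]
        frame["qaly"] = 1.5
        frame["base_utility"] = 0.8
        draws = bootstrap_ce(frame, B=150, seed=1, regressors=("arm",))
        assert np.allclose(draws[:, 0], 500.0)
        assert np.allclose(draws[:, 1], 0.0)

    def test_fixed_seed_reproducible(self):
        frame = random_frame(np.random.default_rng(12))
        d1 = bootstrap_ce(frame, B=120, seed=42)
        d2 = bootstrap_ce(frame, B=120, seed=42)
        assert np.array_equal(d1, d2)

    def test_small_B_warns(self):
        frame = random_frame(np.random.default_rng(13))
        with pytest.warns(UserWarning, match="resamples"):
            bootstrap_ce(frame, B=50, seed=0)

    def test_ceac_probabilities_sum_to_one(self):
        draws = np.random.default_rng(1).normal([1000, 0.0], [800, 0.1], (500, 2))
        tab = ceac(draws)
        assert np.allclose(tab["p_urethroplasty"] + tab["p_urethrotomy"], 1.0)

    def test_ceac_at_zero_threshold_is_cheaper_fraction(self):
        draws = np.random.default_rng(2).normal([200, 0.0], [800, 0.1], (400, 2))
        tab = ceac(draws, lambda_grid=[0.0])
        assert tab["p_urethroplasty"][0] == pytest.approx(np.mean(draws[:, 0] < 0))

    def test_all_dominant_draws_probability_one_everywhere(self):
        draws = np.column_stack([-np.abs(np.random.default_rng(3).normal(500, 100, 200)),
                                 np.abs(np.random.default_rng(4).normal(0.1, 0.02, 200))])
        tab = ceac(draws)
        assert (tab["p_urethroplasty"] == 1.0).all()

    def test_hand_nmb_comparison(self):
        draws = np.array([[1000.0, 0.1], [1000.0, -0.1]])
        tab = ceac(draws, lambda_grid=[0.0, 20_000.0])
        assert tab["p_urethroplasty"].tolist() == [0.0, 0.5]

    def test_ceac_monotone_when_effect_always_positive(self):
        rng = np.random.default_rng(5)
        draws = np.column_stack([rng.normal(500, 800, 600),
                                 np.abs(rng.normal(0.05, 0.02, 600))])
        tab = ceac(draws, lambda_grid=np.linspace(0, 50_000, 26))
        assert (np.diff(tab["p_urethroplasty"]) >= -1e-12).all()

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            ceac(np.empty((0, 2)))


class TestImputation:
    def wide(self):
        rng = np.random.default_rng(21)
        n = 40
        df = pd.DataFrame({
            "id": [f"p{i}" for i in range(n)],
            "arm": np.repeat([0, 1], n // 2),
            "stratum": rng.integers(0, 2, n),
            "cost": rng.normal(3000, 500, n),
            "u_baseline": rng.normal(0.8, 0.1, n),
            "u_m6_post_surgery": rng.normal(0.85, 0.1, n),
            "u_m24_post_rand": rng.normal(0.9, 0.1, n),
        })
        return df

    def test_no_missing_data_returns_identical_copies(self):
        df = self.wide()
        out = impute(df, MISpec(m=3, seed=0))
        assert len(out) == 3
        for c in out:
            pd.testing.assert_frame_equal(c, df)

    def test_single_donor_pmm_copies_donor_value(self):
        df = self.wide().iloc[:6].copy()
        df.loc[df.index[-1], "u_m6_post_surgery"] = np.nan
        out = impute(df, MISpec(m=2, k_pmm=1, seed=0))
        donors = df["u_m6_post_surgery"].dropna().to_numpy()
        for c in out:
            assert c["u_m6_post_surgery"].iloc[-1] in donors

    def test_fully_missing_column_rejected(self):
        df = self.wide()
        df["u_m6_post_surgery"] = np.nan
        with pytest.raises(ValueError, match="u_m6_post_surgery"):
            impute(df, MISpec(m=2, seed=0))

    def test_observed_values_shared_across_imputations(self):
        df = self.wide()
        df.loc[df.index[:8], "u_m24_post_rand"] = np.nan
        out = impute(df, MISpec(m=4, seed=1))
        obs_mask = df["u_m24_post_rand"].notna()
        for c in out:
            assert np.allclose(c.loc[obs_mask, "u_m24_post_rand"],
                               df.loc[obs_mask, "u_m24_post_rand"])
        imputed = np.array([c.loc[~obs_mask, "u_m24_post_rand"].to_numpy()
                            for c in out])
        assert not np.allclose(imputed[0], imputed[1])  # draws differ


class TestRubin:
    def test_identical_estimates_zero_between_variance(self):
        est, var, _ = pool_rubin([2.0, 2.0, 2.0], [1.5, 1.5, 1.5])
        assert est == 2.0
        assert var == pytest.approx(1.5)

    def test_hand_formula_two_imputations(self):
        est, var, _ = pool_rubin([1.0, 3.0], [1.0, 1.0])
        assert est == 2.0
        assert var == pytest.approx(1.0 + 1.5 * 2.0)  # within + (1+1/m)*between

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            pool_rubin([1.0], [1.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="matching"):
            pool_rubin([1.0, 2.0], [1.0])

    def test_ci_contains_pooled_estimate(self):
        est, _, (lo, hi) = pool_rubin([1.0, 1.4, 0.9], [0.2, 0.25, 0.22])
        assert lo < est < hi


class TestPipeline:
    def test_no_noise_pipeline_reproduces_truth_exactly(
            self, exact_config, unit_costs, toy_tariff):
        delta_min = 2000.0 / unit_costs.unit_cost("theatre_minute")
        cfg = exact_config(n_per_arm=100, delta_theatre_min=delta_min, seed=17)
        records, truth = simulate_trial(cfg, unit_costs, toy_tariff)
        frame = build_analysis_frame(records, unit_costs, toy_tariff,
                                     discount_costs=False)
        fit = sur_adjusted_increments(frame, regressors=("arm", "stratum"))
        assert fit.delta_cost == pytest.approx(truth.incremental_cost, abs=1e-8)
        assert fit.delta_qaly == pytest.approx(truth.incremental_qaly, abs=1e-8)

    def test_dominated_in_all_draws_gives_zero_ceac(
            self, small_trial, unit_costs, toy_tariff):
        _, records, _ = small_trial
        res = run_within_trial(records, unit_costs, toy_tariff, B=150, seed=2)
        if (res.draws[:, 0] > 0).all() and (res.draws[:, 1] < 0).all():
            assert (res.ceac_table["p_urethroplasty"] == 0.0).all()
        assert res.ci_cost[0] <= res.fit.delta_cost <= res.ci_cost[1]

    def test_mi_noop_equals_complete_case_without_missingness(
            self, unit_costs, toy_tariff):
        cfg = default_config(seed=88, n_per_arm=40, missing=MissingSpec(rates=0.0))
        records, _ = simulate_trial(cfg, unit_costs, toy_tariff)
        frame = build_analysis_frame(records, unit_costs, toy_tariff)
        cc = sur_adjusted_increments(frame)
        mi = mi_within_trial(records, unit_costs, toy_tariff, MISpec(m=3, seed=0))
        assert mi["delta_cost"] == pytest.approx(cc.delta_cost, abs=1e-8)
        assert mi["delta_qaly"] == pytest.approx(cc.delta_qaly, abs=1e-8)
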
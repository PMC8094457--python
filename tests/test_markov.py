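"""Cohort Markov engine: transition structure, closed forms, scenario
policies, PSA distributions and a patient-level micro-simulation oracle."""

import numpy as np
import pytest

from uroecon.markov import (
    MarkovSpec, PSASpec, ProcModelParams, beta_mm, build_transition_matrix,
    gamma_mm, load_markov_spec, load_psa_spec, psa, run_cohort, run_scenarios,
    run_strategies,
)

from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "uroecon" / "data"


def make_spec(rp=0.2, ro=0.2, d=0.01, u_sf=1.0, u_sym=1.0, cp=0.0, co=0.0,
              reint_p=None, reint_o=None, fup=0.0, cl=1.0, horizon=10.0,
              policy="observed_mix", p_switch=0.5, rate_c=0.0, rate_q=0.0):
    procs = {
        "urethroplasty": ProcModelParams(cp, rp, reint_p if reint_p is not None else cp),
        "urethrotomy": ProcModelParams(co, ro, reint_o if reint_o is not None else co),
    }
    return MarkovSpec(procedures=procs, death_prob=d, u_symptom_free=u_sf,
                      u_symptomatic=u_sym, followup_cost_per_cycle=fup,
                      cycle_length=cl, horizon=horizon,
                      discount_rate_costs=rate_c, discount_rate_qalys=rate_q,
                      recurrence_policy=policy, p_switch=p_switch)


class TestTransitionMatrix:
    def test_absorbing_symptom_free_without_recurrence_or_death(self):
        M = build_transition_matrix(make_spec(rp=0.0, ro=0.0, d=0.0),
                                    "urethroplasty", "urethroplasty")
        assert np.allclose(M[0], [1.0, 0.0, 0.0])
        assert np.allclose(M[2], [0.0, 0.0, 1.0])

    def test_multiplicative_competing_risks_hand_values(self):
        M = build_transition_matrix(make_spec(rp=0.2, d=0.01),
                                    "urethroplasty", "urethroplasty")
        assert np.allclose(M[0], [0.792, 0.198, 0.01])
        assert np.allclose(M.sum(axis=1), 1.0)

    def test_deceased_row_absorbing(self):
        M = build_transition_matrix(make_spec(), "urethrotomy", "urethrotomy")
        assert np.allclose(M[2], [0.0, 0.0, 1.0])

    def test_recurrence_depends_on_last_procedure(self):
        spec = make_spec(rp=0.05, ro=0.3)
        Mp = build_transition_matrix(spec, "urethroplasty", "urethroplasty")
        Mo = build_transition_matrix(spec, "urethroplasty", "urethrotomy")
        assert Mp[0, 1] < Mo[0, 1]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="recurrence_prob"):
            build_transition_matrix(make_spec(rp=1.2), "urethroplasty",
                                    "urethroplasty")


class TestCohortClosedForms:
    def test_full_health_decade_undiscounted(self):
        _, q, _ = run_cohort(make_spec(rp=0.0, ro=0.0, d=0.0), "urethroplasty")
        assert q == pytest.approx(10.0)

    def test_full_health_decade_discounted_geometric_series(self):
        spec = make_spec(rp=0.0, ro=0.0, d=0.0, rate_q=0.035)
        _, q, _ = run_cohort(spec, "urethroplasty")
        assert q == pytest.approx(sum(1.035 ** -t for t in range(10)), abs=5e-5)
        assert round(q, 4) == 8.6077

    def test_zero_utilities_zero_qalys(self):
        spec = make_spec(rp=0.3, ro=0.3, d=0.02, u_sf=0.0, u_sym=0.0)
        _, q, _ = run_cohort(spec, "urethrotomy")
        assert q == 0.0

    def test_occupancy_sums_to_one_every_cycle(self):
        spec = make_spec(rp=0.25, ro=0.4, d=0.03, cl=0.5, p_switch=0.3)
        for strat in ("urethroplasty", "urethrotomy"):
            _, _, trace = run_cohort(spec, strat)
            assert np.allclose(trace.occupancy_sums(), 1.0, atol=1e-12)

    def test_mortality_only_matches_survival_closed_form(self):
        d, rate = 0.05, 0.035
        spec = make_spec(rp=0.0, ro=0.0, d=d, rate_q=rate)
        _, q, _ = run_cohort(spec, "urethroplasty")
        expected = sum((1 - d) ** t * (1 + rate) ** -t for t in range(10))
        assert q == pytest.approx(expected, abs=1e-12)

    def test_zero_discount_equals_trace_sum(self):
        spec = make_spec(rp=0.2, ro=0.2, d=0.02, u_sf=0.9, u_sym=0.7)
        _, q, trace = run_cohort(spec, "urethroplasty")
        assert q == pytest.approx(trace.table["cycle_qaly"].sum())

    def test_horizon_must_divide_by_cycle_length(self):
        with pytest.raises(ValueError, match="divisible"):
            run_cohort(make_spec(cl=0.7), "urethroplasty")


class TestPolicies:
    def test_identical_parameters_give_zero_increments(self):
        res = run_strategies(make_spec(rp=0.1, ro=0.1, cp=1000.0, co=1000.0,
                                       u_sf=0.9, u_sym=0.7, d=0.01))
        assert res["delta_cost"] == pytest.approx(0.0)
        assert res["delta_qaly"] == pytest.approx(0.0)

    def test_lower_recurrence_gives_weakly_more_qalys(self):
        res = run_strategies(make_spec(rp=0.02, ro=0.3, cp=4000.0, co=1000.0,
                                       u_sf=0.9, u_sym=0.6, d=0.01))
        assert res["delta_qaly"] >= 0.0

    def test_always_other_reintervenes_with_other_procedure(self):
        # urethrotomy strategy, always_other: every re-intervention is a
        # (costly) urethroplasty, so strategy cost exceeds the always_same run
        base = dict(rp=0.0, ro=0.5, cp=5000.0, co=100.0, u_sf=0.9, u_sym=0.7,
                    d=0.0)
        same = run_strategies(make_spec(policy="always_same", **base))
        other = run_strategies(make_spec(policy="always_other", **base))
        assert other["urethrotomy"]["cost"] > same["urethrotomy"]["cost"]

    def test_scenario_table_has_all_four_analyses(self):
        spec = load_markov_spec(DATA / "markov_params.yaml")
        df = run_scenarios(spec)
        assert sorted(df["analysis"].unique()) == sorted(
            ["base_case", "treatment_received", "always_same", "always_other"])
        assert len(df) == 8


class TestMicroSimOracle:
    def test_cohort_matches_individual_trajectories(self):
        """The deterministic cohort engine must agree with a brute-force
        simulation of 10^5 individual patient paths."""
        spec = make_spec(rp=0.08, ro=0.25, d=0.01, u_sf=0.9, u_sym=0.7,
                         cp=4000.0, co=1200.0, fup=50.0, cl=0.5,
                         p_switch=0.4, rate_c=0.035, rate_q=0.035)
        for strat in ("urethroplasty", "urethrotomy"):
            c, q, _ = run_cohort(spec, strat)
            mc, mq, se_c, se_q = micro_sim(spec, strat, n=100_000, seed=99)
            assert abs(c - mc) < 3 * se_c, (strat, c, mc, se_c)
            assert abs(q - mq) < 3 * se_q, (strat, q, mq, se_q)


def micro_sim(spec, strategy, n, seed):
    """Vectorised patient-level re-implementation of the model rules."""
    rng = np.random.default_rng(seed)
    procs = spec.active_procedures()
    other = {"urethroplasty": "urethrotomy", "urethrotomy": "urethroplasty"}
    r_by = {p: procs[p].recurrence_prob for p in procs}
    rc_by = {p: procs[p].reintervention_cost for p in procs}
    n_cycles = spec.n_cycles
    alive = np.ones(n, bool)
    symptomatic = np.zeros(n, bool)
    last = np.full(n, strategy == "urethroplasty")  # True = urethroplasty
    cost = np.full(n, procs[strategy].initial_cost)
    qaly = np.zeros(n)
    for t in range(n_cycles):
        df_c = (1 + spec.discount_rate_costs) ** (-t * spec.cycle_length)
        df_q = (1 + spec.discount_rate_qalys) ** (-t * spec.cycle_length)
        u = np.where(symptomatic, spec.u_symptomatic, spec.u_symptom_free)
        qaly += np.where(alive, u * spec.cycle_length * df_q, 0.0)
        cost += np.where(alive, spec.followup_cost_per_cycle * df_c, 0.0)
        dies = alive & (rng.random(n) < spec.death_prob)
        survives = alive & ~dies
        # symptomatic survivors are re-treated this cycle
        treated = survives & symptomatic
        if spec.recurrence_policy == "always_same":
            new_last = last
        elif spec.recurrence_policy == "always_other":
            new_last = ~last
        else:
            switch = rng.random(n) < spec.p_switch
            new_last = np.where(switch, ~last, last)
        cost += np.where(
            treated,
            np.where(np.where(treated, new_last, last),
                     rc_by["urethroplasty"], rc_by["urethrotomy"]) * df_c,
            0.0)
        last = np.where(treated, new_last, last)
        symptomatic = np.where(treated, False, symptomatic)
        # symptom-free survivors may recur
        r = np.where(last, r_by["urethroplasty"], r_by["urethrotomy"])
        recurs = survives & ~treated & ~symptomatic & (rng.random(n) < r)
        symptomatic = symptomatic | recurs
        alive = survives
    return (cost.mean(), qaly.mean(),
            cost.std() / np.sqrt(n), qaly.std() / np.sqrt(n))


class TestPsa:
    def test_beta_moment_matching_hand_values(self):
        a, b = beta_mm(0.2, 0.05)
        assert a == pytest.approx(12.6)
        assert b == pytest.approx(50.4)

    def test_gamma_moment_matching_recovers_moments(self):
        shape, scale = gamma_mm(4000.0, 400.0)
        assert shape * scale == pytest.approx(4000.0)
        assert np.sqrt(shape) * scale == pytest.approx(400.0)

    def test_infeasible_beta_se_names_parameter(self):
        pspec = PSASpec(params={"death_prob": ("beta", 0.01, 0.5)}, n_draws=10)
        with pytest.raises(ValueError, match="death_prob"):
            pspec.validate()

    def test_degenerate_distributions_reproduce_deterministic_result(self):
        spec = load_markov_spec(DATA / "markov_params.yaml")
        pspec = load_psa_spec(DATA / "psa.yaml")
        pinned = PSASpec(params={k: (f, m, 0.0) for k, (f, m, s)
                                 in pspec.params.items()},
                         n_draws=5, seed=1)
        res = psa(spec, pinned)
        det = run_strategies(spec)
        for strat in ("urethroplasty", "urethrotomy"):
            assert np.allclose(res["per_strategy"][strat][:, 0],
                               det[strat]["cost"])
            assert np.allclose(res["per_strategy"][strat][:, 1],
                               det[strat]["qaly"])

    def test_fixed_seed_reproducible_ceac(self):
        spec = load_markov_spec(DATA / "markov_params.yaml")
        pspec = load_psa_spec(DATA / "psa.yaml")
        pspec.n_draws, pspec.seed = 40, 7
        c1 = psa(spec, pspec)["ceac"]
        c2 = psa(spec, pspec)["ceac"]
        assert c1.equals(c2)

    def test_psa_mean_approaches_deterministic_as_se_shrinks(self):
        spec = load_markov_spec(DATA / "markov_params.yaml")
        pspec = load_psa_spec(DATA / "psa.yaml")
        det = run_strategies(spec)
        tiny = PSASpec(params={k: (f, m, s * 1e-3) for k, (f, m, s)
                               in pspec.params.items()},
                       n_draws=60, seed=3)
        res = psa(spec, tiny)
        for strat in ("urethroplasty", "urethrotomy"):
            assert res["per_strategy"][strat][:, 0].mean() == pytest.approx(
                det[strat]["cost"], rel=1e-3)
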
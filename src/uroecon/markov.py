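"""Three-state cohort Markov model over a 10-year horizon.

States are symptom-free, symptomatic and deceased.  A cohort enters
symptom-free immediately after its strategy's initial procedure (whose
cost is incurred at time zero).  Each cycle, death is applied first as a
flat background rate; among survivors, symptom-free patients may recur
(per-cycle probability specific to the procedure they last received) and
symptomatic patients undergo a re-intervention — whose procedure type is
set by the recurrence policy — returning them to the symptom-free state.
Because the recurrence probability depends on the last procedure, the
engine internally tracks the symptom states crossed with the last
procedure (five sub-states) while reporting the three aggregate states.

Rewards (state utilities weighted by cycle length, per-cycle follow-up
cost, re-intervention costs at the cycle they occur) accrue at cycle
start times and are discounted at 3.5% per annum by default; a half-cycle
correction is available but off in the base configuration.  Probabilistic
sensitivity analysis samples probabilities and utilities from beta and
costs from gamma distributions, parameterised by method of moments from a
mean and standard error.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .cea import ceac, classify_icer, DEFAULT_LAMBDA_GRID

__all__ = [
    "STATES",
    "STRATEGIES",
    "ProcModelParams",
    "MarkovSpec",
    "PSASpec",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "run_strategies",
    "run_scenarios",
    "psa",
    "beta_mm",
    "gamma_mm",
    "load_markov_spec",
    "load_psa_spec",
]

STATES = ("symptom_free", "symptomatic", "deceased")
STRATEGIES = ("urethroplasty", "urethrotomy")
_OTHER = {"urethroplasty": "urethrotomy", "urethrotomy": "urethroplasty"}

RECURRENCE_POLICIES = ("observed_mix", "always_same", "always_other")
SCENARIOS = ("base_case", "treatment_received", "always_same", "always_other")


@dataclass
class ProcModelParams:
    """Strategy-level parameters: initial procedure cost, per-cycle
    recurrence probability after this procedure, and its re-intervention
    cost (same micro-costed procedure performed at recurrence)."""

    initial_cost: float
    recurrence_prob: float
    reintervention_cost: float


@dataclass
class MarkovSpec:
    """Model structure and parameters.

    ``procedures`` maps each procedure to its parameters; when the model
    is parameterised from "treatment received" rather than allocation,
    supply that variant via ``received_procedures`` and select it with
    ``treatment_effect_source``.
    """

    procedures: dict[str, ProcModelParams]
    death_prob: float  # per cycle, age-independent background rate
    u_symptom_free: float
    u_symptomatic: float
    followup_cost_per_cycle: float = 0.0
    recurrence_utility_decrement: float = 0.0
    cycle_length: float = 0.5  # years
    horizon: float = 10.0  # years
    discount_rate_costs: float = 0.035
    discount_rate_qalys: float = 0.035
    recurrence_policy: str = "observed_mix"
    p_switch: float = 0.5
    treatment_effect_source: str = "allocated_and_received"
    received_procedures: dict[str, ProcModelParams] | None = None
    half_cycle_correction: bool = False

    def validate(self) -> None:
        if set(self.procedures) != set(STRATEGIES):
            raise ValueError(f"procedures must be given for exactly {STRATEGIES}")
        for name, pp in self.active_procedures().items():
            if not 0.0 <= pp.recurrence_prob <= 1.0:
                raise ValueError(f"{name}.recurrence_prob outside [0, 1]")
            if pp.initial_cost < 0 or pp.reintervention_cost < 0:
                raise ValueError(f"{name}: costs must be >= 0")
        if not 0.0 <= self.death_prob <= 1.0:
            raise ValueError("death_prob outside [0, 1]")
        for nm, u in [("u_symptom_free", self.u_symptom_free),
                      ("u_symptomatic", self.u_symptomatic)]:
            if u > 1.0:
                raise ValueError(f"{nm} must be <= 1")
        if self.recurrence_policy not in RECURRENCE_POLICIES:
            raise ValueError(f"unknown recurrence policy {self.recurrence_policy!r}")
        if not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_switch outside [0, 1]")
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            raise ValueError("discount rates must be >= 0")
        n = self.horizon / self.cycle_length
        if abs(n - round(n)) > 1e-9:
            raise ValueError("horizon must be divisible by cycle_length")

    def active_procedures(self) -> dict[str, ProcModelParams]:
        if self.treatment_effect_source == "treatment_received":
            if self.received_procedures is None:
                raise ValueError("treatment_received source needs received_procedures")
            return self.received_procedures
        return self.procedures

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon / self.cycle_length))


def build_transition_matrix(spec: MarkovSpec, strategy: str,
                            last_procedure: str) -> np.ndarray:
    """3x3 row-stochastic matrix conditional on the last procedure.

    Competing risks apply multiplicatively: death first, then recurrence
    among survivors, so rows are stochastic without renormalisation.
    Symptomatic patients who survive the cycle receive a re-intervention
    and return to the symptom-free state.
    """
    spec.validate()
    if last_procedure not in STRATEGIES:
        raise ValueError(f"unknown procedure {last_procedure!r}")
    d = spec.death_prob
    r = spec.active_procedures()[last_procedure].recurrence_prob
    M = np.array([
        [(1 - d) * (1 - r), (1 - d) * r, d],
        [1 - d, 0.0, d],
        [0.0, 0.0, 1.0],
    ])
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition rows must sum to 1")
    return M


def _reint_procedure_mix(spec: MarkovSpec, last: str) -> dict[str, float]:
    if spec.recurrence_policy == "always_same":
        return {last: 1.0}
    if spec.recurrence_policy == "always_other":
        return {_OTHER[last]: 1.0}
    return {last: 1.0 - spec.p_switch, _OTHER[last]: spec.p_switch}


@dataclass
class CohortTrace:
    """Per-cycle occupancy and rewards."""

    table: pd.DataFrame

    def occupancy_sums(self) -> np.ndarray:
        return self.table[list(STATES)].sum(axis=1).to_numpy()


def run_cohort(spec: MarkovSpec, strategy: str
               ) -> tuple[float, float, CohortTrace]:
    """Propagate the cohort; return discounted cost, discounted QALY, trace.

    The expanded occupancy vector is [SF after plasty, SF after otomy,
    symptomatic last plasty, symptomatic last otomy, deceased].
    """
    spec.validate()
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    procs = spec.active_procedures()
    d = spec.death_prob
    sf_ix = {"urethroplasty": 0, "urethrotomy": 1}
    sym_ix = {"urethroplasty": 2, "urethrotomy": 3}
    occ = np.zeros(5)
    occ[sf_ix[strategy]] = 1.0
    cl = spec.cycle_length
    n_cycles = spec.n_cycles
    disc_cost = procs[strategy].initial_cost  # time zero
    disc_qaly = 0.0
    undisc_qaly = 0.0
    rows = []
    for t in range(n_cycles):
        time = t * cl
        df_c = (1.0 + spec.discount_rate_costs) ** (-time)
        df_q = (1.0 + spec.discount_rate_qalys) ** (-time)
        nxt = np.zeros(5)
        cycle_reint_cost = 0.0
        cycle_recur_frac = 0.0
        for proc in STRATEGIES:
            w_sf = occ[sf_ix[proc]]
            r = procs[proc].recurrence_prob
            nxt[sf_ix[proc]] += w_sf * (1 - d) * (1 - r)
            nxt[sym_ix[proc]] += w_sf * (1 - d) * r
            nxt[4] += w_sf * d
            w_sym = occ[sym_ix[proc]]
            if w_sym > 0:
                treated = w_sym * (1 - d)
                cycle_recur_frac += treated
                for q, wq in _reint_procedure_mix(spec, proc).items():
                    nxt[sf_ix[q]] += treated * wq
                    cycle_reint_cost += treated * wq * procs[q].reintervention_cost
                nxt[4] += w_sym * d
        nxt[4] += occ[4]
        alive = occ[:4].sum()
        sf = occ[0] + occ[1]
        sym = occ[2] + occ[3]
        if spec.half_cycle_correction:
            alive_n = nxt[:4].sum()
            sf_n, sym_n = nxt[0] + nxt[1], nxt[2] + nxt[3]
            q_cycle = cl * 0.5 * ((sf + sf_n) * spec.u_symptom_free
                                  + (sym + sym_n) * spec.u_symptomatic)
            fup_base = 0.5 * (alive + alive_n)
        else:
            q_cycle = cl * (sf * spec.u_symptom_free + sym * spec.u_symptomatic)
            fup_base = alive
        q_cycle -= cycle_recur_frac * spec.recurrence_utility_decrement
        c_cycle = fup_base * spec.followup_cost_per_cycle + cycle_reint_cost
        disc_cost += df_c * c_cycle
        disc_qaly += df_q * q_cycle
        undisc_qaly += q_cycle
        rows.append({
            "cycle": t, "time_years": time,
            "symptom_free": sf, "symptomatic": sym, "deceased": occ[4],
            "cycle_cost": c_cycle, "cycle_qaly": q_cycle,
            "disc_cum_cost": disc_cost, "disc_cum_qaly": disc_qaly,
            "undisc_cum_qaly": undisc_qaly,
        })
        occ = nxt
    return float(disc_cost), float(disc_qaly), CohortTrace(pd.DataFrame(rows))


def run_strategies(spec: MarkovSpec) -> dict:
    """Both strategies plus the incremental classification
    (urethroplasty minus urethrotomy)."""
    out: dict = {}
    for strat in STRATEGIES:
        c, q, trace = run_cohort(spec, strat)
        out[strat] = {"cost": c, "qaly": q, "trace": trace}
    dc = out["urethroplasty"]["cost"] - out["urethrotomy"]["cost"]
    de = out["urethroplasty"]["qaly"] - out["urethrotomy"]["qaly"]
    label, icer = classify_icer(dc, de)
    out["delta_cost"], out["delta_qaly"] = dc, de
    out["label"], out["icer"] = label, icer
    return out


def _scenario_spec(spec: MarkovSpec, scenario: str) -> MarkovSpec:
    s = copy.deepcopy(spec)
    if scenario == "base_case":
        s.treatment_effect_source = "allocated_and_received"
        s.recurrence_policy = "observed_mix"
    elif scenario == "treatment_received":
        s.treatment_effect_source = "treatment_received"
        s.recurrence_policy = "observed_mix"
    elif scenario in ("always_same", "always_other"):
        s.treatment_effect_source = "allocated_and_received"
        s.recurrence_policy = scenario
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return s


def run_scenarios(spec: MarkovSpec,
                  scenarios: Iterable[str] = SCENARIOS) -> pd.DataFrame:
    """Deterministic scenario table: one row per strategy per analysis."""
    rows = []
    for sc in scenarios:
        res = run_strategies(_scenario_spec(spec, sc))
        for strat in STRATEGIES:
            rows.append({
                "analysis": sc, "strategy": strat,
                "cost": res[strat]["cost"], "qaly": res[strat]["qaly"],
                "delta_cost": res["delta_cost"] if strat == "urethroplasty" else np.nan,
                "delta_qaly": res["delta_qaly"] if strat == "urethroplasty" else np.nan,
                "label": res["label"], "icer": res["icer"],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def beta_mm(mean: float, se: float) -> tuple[float, float]:
    """Beta hyperparameters by moment matching a mean and standard error."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if se < 0:
        raise ValueError("standard error must be >= 0")
    if se ** 2 >= mean * (1.0 - mean):
        raise ValueError(
            f"standard error {se} too large for a beta with mean {mean}")
    nu = mean * (1.0 - mean) / se ** 2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_mm(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) by moment matching a mean and standard error."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if se <= 0:
        raise ValueError("standard error must be > 0")
    shape = (mean / se) ** 2
    return shape, se ** 2 / mean


@dataclass
class PSASpec:
    """Parameter distributions for probabilistic sensitivity analysis.

    ``params`` maps a dotted attribute path on :class:`MarkovSpec`
    (e.g. ``procedures.urethroplasty.recurrence_prob``) to a
    ``(family, mean, se)`` triple with family ``beta`` (probabilities and
    utilities) or ``gamma`` (costs).  ``se = 0`` pins the parameter at its
    mean.
    """

    params: dict[str, tuple[str, float, float]]
    n_draws: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for path, (family, mean, se) in self.params.items():
            try:
                if family == "beta":
                    if se > 0:
                        beta_mm(mean, se)
                elif family == "gamma":
                    if se > 0:
                        gamma_mm(mean, se)
                else:
                    raise ValueError(f"unknown family {family!r}")
            except ValueError as exc:
                raise ValueError(f"infeasible PSA distribution for {path!r}: {exc}") from exc


def _set_path(spec: MarkovSpec, path: str, value: float) -> None:
    parts = path.split(".")
    obj: object = spec
    for p in parts[:-1]:
        obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = value
    else:
        setattr(obj, last, value)


def psa(spec: MarkovSpec, psa_spec: PSASpec,
        lambda_grid: Iterable[float] = DEFAULT_LAMBDA_GRID) -> dict:
    """Sample all parameters, run both strategies per draw, build the CEAC.

    Returns per-strategy (cost, QALY) draws, the incremental draws and the
    acceptability table; reproducible under the PSA seed.
    """
    spec.validate()
    psa_spec.validate()
    rng = np.random.default_rng(psa_spec.seed)
    n = psa_spec.n_draws
    per_strategy = {s: np.empty((n, 2)) for s in STRATEGIES}
    deltas = np.empty((n, 2))
    for i in range(n):
        s = copy.deepcopy(spec)
        for path, (family, mean, se) in psa_spec.params.items():
            if se == 0:
                val = mean
            elif family == "beta":
                a, b = beta_mm(mean, se)
                val = float(rng.beta(a, b))
            else:
                shape, scale = gamma_mm(mean, se)
                val = float(rng.gamma(shape, scale))
            _set_path(s, path, val)
        for strat in STRATEGIES:
            c, q, _ = run_cohort(s, strat)
            per_strategy[strat][i] = (c, q)
        deltas[i] = (per_strategy["urethroplasty"][i] - per_strategy["urethrotomy"][i])
    return {
        "per_strategy": per_strategy,
        "deltas": deltas,
        "ceac": ceac(deltas, lambda_grid),
    }


# ---------------------------------------------------------------------------
# yaml config
# ---------------------------------------------------------------------------

def load_markov_spec(path: str | Path) -> MarkovSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    procs = {k: ProcModelParams(**v) for k, v in raw.pop("procedures").items()}
    received = raw.pop("received_procedures", None)
    if received is not None:
        received = {k: ProcModelParams(**v) for k, v in received.items()}
    spec = MarkovSpec(procedures=procs, received_procedures=received, **raw)
    spec.validate()
    return spec


def load_psa_spec(path: str | Path) -> PSASpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    params = {k: (v["family"], float(v["mean"]), float(v["se"]))
              for k, v in raw.pop("params").items()}
    spec = PSASpec(params=params, **raw)
    spec.validate()
    return spec
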
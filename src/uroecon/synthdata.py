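"""Synthetic two-arm trial generator with an analytic truth record.

Emulates a 1:1 randomised surgical trial comparing open urethroplasty with
endoscopic urethrotomy for recurrent bulbar urethral stricture: a binary
stratum (time since last procedure < 12 vs >= 12 months), per-patient
procedure resource use (theatre and staff minutes, consumables, bed-days),
re-intervention events over 24 months with possible switching to the other
procedure, follow-up service contacts and out-of-pocket spend, and
EQ-5D-5L profiles at the scheduled assessment points with configurable
(MAR) missingness.

Alongside each simulated dataset a :class:`TruthRecord` is computed
analytically from the same configuration — expected per-arm costs and
QALYs by exact enumeration over the waiting-time distribution and a
dynamic program over monthly recurrence — so parameter-recovery tests can
compare estimates against ground truth rather than against a second
simulation.

Generated utilities live on the 0.05 grid of the package's synthetic toy
tariff (one EQ-5D level step = 0.05 utility), so profiles scored back
through that tariff reproduce the configured trajectory means exactly in
the no-noise case.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .costing import UnitCostTable, CpiIndex, YEAR2_START_DAY
from .qaly import Eq5dProfile, Tariff, TIMEPOINTS, load_tariff

__all__ = [
    "ARMS",
    "ProcParams",
    "MissingSpec",
    "SimConfig",
    "Reintervention",
    "PatientRecord",
    "TruthRecord",
    "ConfigError",
    "default_config",
    "default_unit_costs",
    "default_tariff",
    "simulate_trial",
    "apply_missingness",
    "compute_truth",
    "profile_from_units",
    "quantize_utility",
    "write_patient_tables",
]

ARMS = ("urethroplasty", "urethrotomy")

DAYS_PER_MONTH = 730.0 / 24.0  # 30.416̄ days; 24 monthly recurrence checks

#: Scheduled days from randomisation that do not depend on surgery timing.
FIXED_DAYS = {"baseline": 0.0, "m18_post_rand": 548.0, "m24_post_rand": 730.0,
              "end_of_study": 745.0}

#: Nominal day of each six-monthly follow-up resource recall period.
FOLLOWUP_PERIOD_DAYS = (91.0, 274.0, 456.0, 639.0)

UTILITY_STEP = 0.05

_DATA_DIR = Path(__file__).parent / "data"


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ProcParams:
    """Per-procedure resource, waiting-time and outcome parameters.

    Quantity distributions: theatre/staff minutes and bed-days are
    zero-rectified normals, consumable packs and follow-up contacts are
    Poisson, out-of-pocket spend is gamma (shape 2).  The waiting time
    from randomisation to surgery is a uniform integer number of days.
    ``utility_traj`` gives the arm's mean utility at every scheduled
    assessment label; values are snapped to the toy-tariff 0.05 grid at
    generation time.  ``recurrence_hazard`` is the per-month probability
    of a re-intervention while stricture-free after this procedure.
    """

    theatre_minutes: tuple[float, float]
    staff_minutes: tuple[float, float]
    bed_days: tuple[float, float]
    consumable_packs: float
    catheter_days: float
    wait_days: tuple[int, int]
    followup_rate: float
    oop_mean: float
    utility_traj: dict[str, float]
    recurrence_hazard: float


@dataclass
class MissingSpec:
    """MAR missingness for scheduled EQ-5D-5L responses.

    The probability that a non-baseline response is missing follows a
    logistic model::

        logit(p) = logit(rate[label]) + arm_coef * 1[urethroplasty]
                   + baseline_coef * (u_baseline - 0.8)
                   + last_coef * (u_last_observed - 0.8)

    where ``u_last_observed`` is the most recent non-missing utility, so
    the mechanism conditions only on observed values (missing at random).
    ``rates`` may be a scalar or a per-label mapping.
    """

    rates: float | dict[str, float] = 0.0
    arm_coef: float = 0.0
    baseline_coef: float = 0.0
    last_coef: float = 0.0
    preserve_baseline: bool = True

    def rate_for(self, label: str) -> float:
        if isinstance(self.rates, dict):
            return float(self.rates.get(label, 0.0))
        return float(self.rates)


@dataclass
class SimConfig:
    """Full specification of one synthetic trial."""

    n_per_arm: int = 110
    seed: int = 2025
    stratum_prob: float = 0.5
    crossover_prob: float = 0.05
    switch_prob: float = 0.5
    no_surgery_prob: float = 0.05
    between_sd: float = 0.12
    within_sd: float = 0.08
    arms: dict[str, ProcParams] = field(default_factory=dict)
    missing: MissingSpec = field(default_factory=MissingSpec)

    def validate(self) -> None:
        if self.n_per_arm < 1:
            raise ConfigError("n_per_arm must be >= 1")
        for name, val in [
            ("stratum_prob", self.stratum_prob),
            ("crossover_prob", self.crossover_prob),
            ("switch_prob", self.switch_prob),
            ("no_surgery_prob", self.no_surgery_prob),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be a probability in [0, 1], got {val}")
        for name, sd in [("between_sd", self.between_sd), ("within_sd", self.within_sd)]:
            if sd < 0:
                raise ConfigError(f"{name} must be >= 0, got {sd}")
        if set(self.arms) != set(ARMS):
            raise ConfigError(f"arms must be configured for exactly {ARMS}")
        for arm, p in self.arms.items():
            for fld in ("theatre_minutes", "staff_minutes", "bed_days"):
                mean, sd = getattr(p, fld)
                if sd < 0:
                    raise ConfigError(f"{arm}.{fld} sd must be >= 0, got {sd}")
            if p.consumable_packs < 0 or p.followup_rate < 0 or p.oop_mean < 0:
                raise ConfigError(f"{arm}: rates and means must be >= 0")
            if not 0.0 <= p.recurrence_hazard <= 1.0:
                raise ConfigError(
                    f"{arm}.recurrence_hazard must be a probability in [0, 1]")
            lo, hi = p.wait_days
            if not (0 <= lo <= hi):
                raise ConfigError(f"{arm}.wait_days must satisfy 0 <= lo <= hi")
            missing_lbls = set(TIMEPOINTS) - set(p.utility_traj)
            if missing_lbls:
                raise ConfigError(f"{arm}.utility_traj missing labels {sorted(missing_lbls)}")
            for lbl, u in p.utility_traj.items():
                if not -1.0 <= u <= 1.0:
                    raise ConfigError(f"{arm}.utility_traj[{lbl}] must be in [-1, 1]")
        for lbl in TIMEPOINTS:
            r = self.missing.rate_for(lbl)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"missing rate for {lbl} must be in [0, 1], got {r}")


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass
class Reintervention:
    day: float
    procedure: str
    resources: list[tuple[str, float]]


@dataclass
class PatientRecord:
    """One trial participant."""

    id: str
    arm_allocated: str
    arm_received: str
    stratum: str  # "lt12m" | "ge12m"
    had_index_surgery: bool
    surgery_day: float | None
    index_resources: list[tuple[str, float]]
    reinterventions: list[Reintervention]
    followup_resources: list[tuple[str, float, float]]  # (item, qty, day)
    oop_items: list[tuple[str, float, float]]  # (description, amount, day)
    eq5d_obs: list[tuple[str, float, Eq5dProfile | None]]


@dataclass
class TruthRecord:
    """Analytic expectations implied by a :class:`SimConfig`.

    Costs are societal-perspective 2017 pounds without second-year
    discounting; QALYs are the randomisation-anchored raw AUC variant.
    Incrementals are urethroplasty minus urethrotomy.
    """

    mean_cost: dict[str, float]
    mean_qaly: dict[str, float]
    mean_qaly_rescaled: dict[str, float]
    incremental_cost: float
    incremental_qaly: float
    recurrence_prob: dict[str, float]


# ---------------------------------------------------------------------------
# defaults (shipped study conditions)
# ---------------------------------------------------------------------------

def _traj(baseline, pre, cath, post):
    d = {"baseline": baseline, "pre_surgery": pre, "cath_1wk": cath}
    for lbl in ("m3_post_surgery", "m6_post_surgery", "m9_post_surgery",
                "m12_post_surgery", "m18_post_rand", "m24_post_rand",
                "m24_post_surgery", "end_of_study"):
        d[lbl] = post
    return d


def default_config(**overrides) -> SimConfig:
    """Study-scale defaults: n = 110/arm, urethroplasty costlier with a
    longer wait and catheterisation but a lower recurrence hazard, both
    arms converging to similar long-run utility (~0.9)."""
    arms = {
        "urethroplasty": ProcParams(
            theatre_minutes=(120.0, 20.0),
            staff_minutes=(300.0, 50.0),
            bed_days=(1.34, 0.95),
            consumable_packs=2.0,
            catheter_days=21.0,
            wait_days=(60, 150),
            followup_rate=1.2,
            oop_mean=25.0,
            utility_traj=_traj(0.80, 0.80, 0.75, 0.90),
            recurrence_hazard=0.006,
        ),
        "urethrotomy": ProcParams(
            theatre_minutes=(35.0, 10.0),
            staff_minutes=(90.0, 20.0),
            bed_days=(0.52, 1.0),
            consumable_packs=1.0,
            catheter_days=3.0,
            wait_days=(20, 80),
            followup_rate=1.2,
            oop_mean=73.0,
            utility_traj=_traj(0.80, 0.80, 0.85, 0.90),
            recurrence_hazard=0.02,
        ),
    }
    missing = MissingSpec(
        rates={lbl: 0.15 if lbl in ("pre_surgery", "cath_1wk", "m3_post_surgery")
               else 0.25 for lbl in TIMEPOINTS},
        arm_coef=0.4, baseline_coef=-1.0, last_coef=-2.0,
    )
    cfg = SimConfig(arms=arms, missing=missing)
    return replace(cfg, **overrides) if overrides else cfg


def default_unit_costs() -> UnitCostTable:
    cpi = CpiIndex.from_csv(_DATA_DIR / "cpi.csv")
    return UnitCostTable.from_csv(_DATA_DIR / "unit_costs.csv", cpi=cpi)


def default_tariff() -> Tariff:
    return load_tariff(_DATA_DIR / "tariff.csv")


# ---------------------------------------------------------------------------
# utility grid helpers
# ---------------------------------------------------------------------------

def quantize_utility(u: float) -> float:
    """Snap a utility to the toy-tariff grid 1 - 0.05 k, k in 0..20."""
    k = int(np.clip(np.round((1.0 - u) / UTILITY_STEP), 0, 20))
    return 1.0 - UTILITY_STEP * k


def profile_from_units(k: int) -> Eq5dProfile:
    """Build a profile whose toy-tariff decrement is exactly ``k`` steps.

    Decrement units are spread greedily across dimensions (each dimension
    absorbs up to four level steps).
    """
    if not 0 <= k <= 20:
        raise ValueError("decrement units must be in 0..20")
    levels = []
    rem = k
    for _ in range(5):
        take = min(rem, 4)
        levels.append(1 + take)
        rem -= take
    return Eq5dProfile(*levels)


_PROFILE_CACHE: dict[int, Eq5dProfile] = {}


def _profile_for_units_cached(k: int) -> Eq5dProfile:
    prof = _PROFILE_CACHE.get(k)
    if prof is None:
        prof = _PROFILE_CACHE[k] = profile_from_units(k)
    return prof


def _profile_for_utility(u: float) -> Eq5dProfile:
    k = int(np.clip(np.round((1.0 - u) / UTILITY_STEP), 0, 20))
    return _profile_for_units_cached(k)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _schedule(surgery_day: float | None, catheter_days: float) -> dict[str, float]:
    """Scheduled observation day for every label this patient gets."""
    sched = dict(FIXED_DAYS)
    if surgery_day is not None:
        s = surgery_day
        sched.update({
            "pre_surgery": s,
            "cath_1wk": s + catheter_days + 7.0,
            "m3_post_surgery": s + 91.0,
            "m6_post_surgery": s + 183.0,
            "m9_post_surgery": s + 274.0,
            "m12_post_surgery": s + 365.0,
            "m24_post_surgery": min(s + 730.0, 760.0),
        })
    return sched


def _rect(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(max(0.0, rng.normal(mean, sd) if sd > 0 else mean))


def _index_resources(rng: np.random.Generator, p: ProcParams) -> list[tuple[str, float]]:
    return [
        ("theatre_minute", _rect(rng, *p.theatre_minutes)),
        ("staff_minute", _rect(rng, *p.staff_minutes)),
        ("bed_day", _rect(rng, *p.bed_days)),
        ("consumable_pack", float(rng.poisson(p.consumable_packs))),
    ]


def simulate_trial(
    config: SimConfig,
    unit_costs: UnitCostTable | None = None,
    tariff: Tariff | None = None,
    apply_missing: bool = True,
) -> tuple[list[PatientRecord], TruthRecord]:
    """Generate one synthetic trial and its analytic truth record.

    Identical configurations (including seed) reproduce identical datasets.
    Missingness is applied per ``config.missing`` unless ``apply_missing``
    is false (a seed derived from the configuration seed keeps the two
    stages independently reproducible).
    """
    config.validate()
    if unit_costs is None:
        unit_costs = default_unit_costs()
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    other = {ARMS[0]: ARMS[1], ARMS[1]: ARMS[0]}
    for arm in ARMS:
        n = config.n_per_arm
        strata = rng.random(n) < config.stratum_prob
        cross = rng.random(n) < config.crossover_prob
        nosurg = rng.random(n) < config.no_surgery_prob
        uwait = rng.random(n)
        recur_u = rng.random((n, 24))
        switch_u = rng.random((n, 24))
        b = rng.normal(0.0, config.between_sd, n) if config.between_sd > 0 else np.zeros(n)
        eps = (rng.normal(0.0, config.within_sd, (n, len(TIMEPOINTS)))
               if config.within_sd > 0 else np.zeros((n, len(TIMEPOINTS))))
        traj_row = np.array([config.arms[arm].utility_traj[lbl] for lbl in TIMEPOINTS])
        units = np.clip(np.round(
            (1.0 - np.clip(traj_row[None, :] + b[:, None] + eps, -1.0, 1.0))
            / UTILITY_STEP), 0, 20).astype(int)
        for i in range(n):
            received = other[arm] if cross[i] else arm
            pr = config.arms[received]
            pa = config.arms[arm]
            had_surgery = not nosurg[i]
            if had_surgery:
                lo, hi = pr.wait_days
                s = float(lo + int(uwait[i] * (hi - lo + 1)))
                index_res = _index_resources(rng, pr)
            else:
                received = arm
                s = None
                index_res = []
            # recurrence walk: monthly hazard after surgery, hazard and
            # switching follow the most recent procedure
            reints: list[Reintervention] = []
            if had_surgery:
                cur = received
                for m in range(1, 25):
                    day = s + DAYS_PER_MONTH * m
                    if day > 730.0:
                        break
                    if recur_u[i, m - 1] < config.arms[cur].recurrence_hazard:
                        q = other[cur] if switch_u[i, m - 1] < config.switch_prob else cur
                        reints.append(Reintervention(
                            day=day, procedure=q,
                            resources=_index_resources(rng, config.arms[q])))
                        cur = q
            fup_proc = received if had_surgery else arm
            rate = config.arms[fup_proc].followup_rate
            fup = []
            for day in FOLLOWUP_PERIOD_DAYS:
                cnt = float(rng.poisson(rate)) if rate > 0 else 0.0
                if cnt > 0:
                    fup.append(("followup_contact", cnt, day))
            oop_mean = config.arms[fup_proc].oop_mean
            oop = []
            if oop_mean > 0:
                amount = float(rng.gamma(2.0, oop_mean / 2.0))
                oop_day = float(rng.integers(0, 730))
                oop.append(("travel_and_items", amount, oop_day))
            sched = _schedule(s, pr.catheter_days if had_surgery else 0.0)
            obs = []
            for j, lbl in enumerate(TIMEPOINTS):
                if lbl not in sched:
                    continue
                obs.append((lbl, sched[lbl],
                            _profile_for_units_cached(int(units[i, j]))))
            obs.sort(key=lambda t: t[1])
            records.append(PatientRecord(
                id=f"{'UP' if arm == 'urethroplasty' else 'UT'}-{i:04d}",
                arm_allocated=arm,
                arm_received=received,
                stratum="lt12m" if strata[i] else "ge12m",
                had_index_surgery=had_surgery,
                surgery_day=s,
                index_resources=index_res,
                reinterventions=reints,
                followup_resources=fup,
                oop_items=oop,
                eq5d_obs=obs,
            ))
    if apply_missing:
        records = apply_missingness(records, config.missing, seed=config.seed + 1,
                                    tariff=tariff)
    truth = compute_truth(config, unit_costs)
    return records, truth


def apply_missingness(
    records: Sequence[PatientRecord],
    missing: MissingSpec,
    seed: int,
    tariff: Tariff | None = None,
) -> list[PatientRecord]:
    """Blank out scheduled responses under the MAR logistic mechanism.

    Observations are processed in day order so the "last observed utility"
    covariate reflects missingness already applied to earlier points.
    Returns new records; the input is untouched.
    """
    if tariff is None:
        tariff = default_tariff()
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        rec = copy.deepcopy(rec)
        base = next((tariff.value(p) for lbl, _, p in rec.eq5d_obs
                     if lbl == "baseline" and p is not None), 0.8)
        last = base
        new_obs = []
        for lbl, day, prof in sorted(rec.eq5d_obs, key=lambda t: t[1]):
            rate = missing.rate_for(lbl)
            if prof is None or (lbl == "baseline" and missing.preserve_baseline):
                new_obs.append((lbl, day, prof))
                if prof is not None:
                    last = tariff.value(prof)
                continue
            if rate <= 0.0:
                p_miss = 0.0
            elif rate >= 1.0:
                p_miss = 1.0
            else:
                logit = (np.log(rate / (1.0 - rate))
                         + missing.arm_coef * (rec.arm_allocated == "urethroplasty")
                         + missing.baseline_coef * (base - 0.8)
                         + missing.last_coef * (last - 0.8))
                p_miss = 1.0 / (1.0 + np.exp(-logit))
            if rng.random() < p_miss:
                new_obs.append((lbl, day, None))
            else:
                new_obs.append((lbl, day, prof))
                last = tariff.value(prof)
        rec.eq5d_obs = new_obs
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# analytic truth
# ---------------------------------------------------------------------------

def _rect_mean(mean: float, sd: float) -> float:
    """Expectation of max(0, Normal(mean, sd))."""
    if sd == 0:
        return max(0.0, mean)
    z = mean / sd
    return float(mean * norm.cdf(z) + sd * norm.pdf(z))


def _proc_cost_mean(p: ProcParams, uc: UnitCostTable) -> float:
    return (_rect_mean(*p.theatre_minutes) * uc.unit_cost("theatre_minute")
            + _rect_mean(*p.staff_minutes) * uc.unit_cost("staff_minute")
            + _rect_mean(*p.bed_days) * uc.unit_cost("bed_day")
            + p.consumable_packs * uc.unit_cost("consumable_pack"))


def _reint_dp(config: SimConfig, received: str, s: float, uc: UnitCostTable,
              discount_rate: float = 0.0) -> tuple[float, float]:
    """Expected re-intervention cost and P(>=1 re-intervention) given the
    surgery day, by a month-by-month dynamic program over the procedure
    whose hazard currently applies."""
    other = {ARMS[0]: ARMS[1], ARMS[1]: ARMS[0]}
    cost_mean = {a: _proc_cost_mean(config.arms[a], uc) for a in ARMS}
    w = {received: 1.0, other[received]: 0.0}
    surv = 1.0  # P(no re-intervention yet); hazard fixed at `received` until first event
    exp_cost = 0.0
    for m in range(1, 25):
        day = s + DAYS_PER_MONTH * m
        if day > 730.0:
            break
        df = 1.0 / (1.0 + discount_rate) if (discount_rate and day >= YEAR2_START_DAY) else 1.0
        w_new = {a: 0.0 for a in ARMS}
        for p, wp in w.items():
            h = config.arms[p].recurrence_hazard
            ev = wp * h
            q_other, q_same = ev * config.switch_prob, ev * (1 - config.switch_prob)
            exp_cost += df * (q_same * cost_mean[p] + q_other * cost_mean[other[p]])
            w_new[p] += wp * (1 - h) + q_same
            w_new[other[p]] += q_other
        w = w_new
        surv *= 1.0 - config.arms[received].recurrence_hazard
    return exp_cost, 1.0 - surv


def _expected_grid_utility(mu: float, sd: float) -> float:
    """E[quantize(clip(mu + Z, -1, 1))] for Z ~ Normal(0, sd).

    The generated utility is a normal draw clipped to [-1, 1] and snapped
    to the 0.05 toy-tariff grid; the expectation follows from the normal
    CDF over the grid bins (exact, so the truth record stays exact under
    between- and within-patient noise).
    """
    if sd == 0:
        return quantize_utility(mu)
    grid = 1.0 - UTILITY_STEP * np.arange(21)  # 1.00, 0.95, ..., 0.00
    # bin k collects u in (g_k - step/2, g_k + step/2]; clipping folds the
    # tails into the first and last bins
    upper = np.concatenate(([np.inf], grid[:-1] - UTILITY_STEP / 2.0))
    lower = np.concatenate((grid[1:] + UTILITY_STEP / 2.0, [-np.inf]))
    p = norm.cdf((upper - mu) / sd) - norm.cdf((lower - mu) / sd)
    return float(np.sum(grid * p))


def _truth_qaly(traj: dict[str, float], s: float | None, catheter_days: float,
                rescaled: bool, noise_sd: float = 0.0) -> float:
    sched = _schedule(s, catheter_days)
    pts = sorted((day, _expected_grid_utility(traj[lbl], noise_sd))
                 for lbl, day in sched.items())
    days, utils = [], []
    for day, u in pts:
        day = min(day, 760.0)
        if days and day <= days[-1]:
            if day == days[-1]:
                utils[-1] = 0.5 * (utils[-1] + u)
            continue
        days.append(day)
        utils.append(u)
    area = float(np.trapezoid(utils, days)) / 365.25
    if rescaled:
        area *= 730.0 / (days[-1] - days[0])
    return area


def compute_truth(config: SimConfig, unit_costs: UnitCostTable | None = None) -> TruthRecord:
    """Expected per-arm societal cost and post-randomisation QALY.

    Exact enumeration over the uniform waiting-time support, the crossover
    and no-surgery mixtures, and the monthly recurrence dynamic program.
    QALY expectations account for the clipping to [-1, 1] and the
    snapping to the toy-tariff grid of noisy utilities via the exact
    normal-bin expectation, with total noise sd sqrt(between^2 + within^2).
    """
    config.validate()
    if unit_costs is None:
        unit_costs = default_unit_costs()
    other = {ARMS[0]: ARMS[1], ARMS[1]: ARMS[0]}
    noise_sd = float(np.hypot(config.between_sd, config.within_sd))
    mean_cost, mean_qaly, mean_qaly_resc, recur_p = {}, {}, {}, {}
    for arm in ARMS:
        pa = config.arms[arm]
        cost_acc = qaly_acc = qaly_resc_acc = rec_acc = 0.0
        mixtures = [(arm, (1 - config.crossover_prob)), (other[arm], config.crossover_prob)]
        for received, w_recv in mixtures:
            if w_recv == 0.0:
                continue
            pr = config.arms[received]
            lo, hi = pr.wait_days
            waits = range(lo, hi + 1)
            w_s = 1.0 / len(waits)
            for s in waits:
                s = float(s)
                reint_cost, p_rec = _reint_dp(config, received, s, unit_costs)
                fup = sum(pr.followup_rate * unit_costs.unit_cost("followup_contact")
                          for _d in FOLLOWUP_PERIOD_DAYS)
                cost = _proc_cost_mean(pr, unit_costs) + reint_cost + fup + pr.oop_mean
                q = _truth_qaly(pa.utility_traj, s, pr.catheter_days,
                                rescaled=False, noise_sd=noise_sd)
                qr = _truth_qaly(pa.utility_traj, s, pr.catheter_days,
                                 rescaled=True, noise_sd=noise_sd)
                wgt = w_recv * w_s * (1 - config.no_surgery_prob)
                cost_acc += wgt * cost
                qaly_acc += wgt * q
                qaly_resc_acc += wgt * qr
                rec_acc += wgt * p_rec
        if config.no_surgery_prob > 0:
            pr = config.arms[arm]
            fup = sum(pr.followup_rate * unit_costs.unit_cost("followup_contact")
                      for _d in FOLLOWUP_PERIOD_DAYS)
            cost = fup + pr.oop_mean
            q = _truth_qaly(pa.utility_traj, None, 0.0, rescaled=False,
                            noise_sd=noise_sd)
            qr = _truth_qaly(pa.utility_traj, None, 0.0, rescaled=True,
                             noise_sd=noise_sd)
            cost_acc += config.no_surgery_prob * cost
            qaly_acc += config.no_surgery_prob * q
            qaly_resc_acc += config.no_surgery_prob * qr
        mean_cost[arm] = cost_acc
        mean_qaly[arm] = qaly_acc
        mean_qaly_resc[arm] = qaly_resc_acc
        recur_p[arm] = rec_acc / max(1e-300, 1.0 - config.no_surgery_prob) \
            if config.no_surgery_prob < 1 else 0.0
    return TruthRecord(
        mean_cost=mean_cost,
        mean_qaly=mean_qaly,
        mean_qaly_rescaled=mean_qaly_resc,
        incremental_cost=mean_cost["urethroplasty"] - mean_cost["urethrotomy"],
        incremental_qaly=mean_qaly["urethroplasty"] - mean_qaly["urethrotomy"],
        recurrence_prob=recur_p,
    )


# ---------------------------------------------------------------------------
# external tables
# ---------------------------------------------------------------------------

def write_patient_tables(records: Sequence[PatientRecord], out_dir: str | Path) -> None:
    """Write ``patients.csv`` (one row per patient) and ``observations.csv``
    (long format: one row per scheduled EQ-5D-5L response)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prow, orow = [], []
    for r in records:
        prow.append({
            "id": r.id, "arm_allocated": r.arm_allocated, "arm_received": r.arm_received,
            "stratum": r.stratum, "had_index_surgery": r.had_index_surgery,
            "surgery_day": r.surgery_day,
            "n_reinterventions": len(r.reinterventions),
            "oop_total": sum(a for _, a, _ in r.oop_items),
        })
        for lbl, day, prof in r.eq5d_obs:
            row = {"id": r.id, "timepoint": lbl, "day": day}
            for d in ("mobility", "self_care", "usual_activities",
                      "pain_discomfort", "anxiety_depression"):
                row[d] = getattr(prof, d) if prof is not None else ""
            orow.append(row)
    pd.DataFrame(prow).to_csv(out / "patients.csv", index=False)
    pd.DataFrame(orow).to_csv(out / "observations.csv", index=False)
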
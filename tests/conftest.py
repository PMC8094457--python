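import numpy as np
import pytest

from uroecon.costing import CpiIndex, UnitCostTable
from uroecon.qaly import Tariff, DIMENSIONS
from uroecon.synthdata import (
    SimConfig, ProcParams, MissingSpec, _traj,
    default_config, default_unit_costs, default_tariff,
)


@pytest.fixture(scope="session")
def cpi():
    return CpiIndex({2014: 96.5, 2015: 98.0, 2016: 100.0, 2017: 102.9})


@pytest.fixture(scope="session")
def unit_costs():
    return default_unit_costs()


@pytest.fixture(scope="session")
def toy_tariff():
    """Each level above 1 subtracts 0.05 per step per dimension."""
    return default_tariff()


@pytest.fixture(scope="session")
def flat_costs():
    """Round unit costs, all in the target year, for hand arithmetic."""
    return UnitCostTable({
        "theatre_minute": (10.0, 2017, "per-minute"),
        "staff_minute": (1.0, 2017, "per-minute"),
        "bed_day": (300.0, 2017, "per-day"),
        "consumable_pack": (100.0, 2017, "per-item"),
        "followup_contact": (50.0, 2017, "per-contact"),
    })


def make_exact_config(n_per_arm=20, delta_theatre_min=0.0, seed=11,
                      recurrence=(0.0, 0.0), followup_rate=0.0, oop=(0.0, 0.0),
                      between_sd=0.0, within_sd=0.0, missing=None,
                      wait=((40, 40), (40, 40)), crossover=0.0, no_surgery=0.0,
                      traj=None):
    """Degenerate or near-degenerate configurations for oracle tests.

    By default: no noise, no missingness, fixed waits, no crossover and no
    recurrence, with an optional built-in theatre-minute difference so the
    incremental cost is known exactly from the unit-cost table.
    """
    arms = {}
    for i, arm in enumerate(("urethroplasty", "urethrotomy")):
        arms[arm] = ProcParams(
            theatre_minutes=(100.0 + (delta_theatre_min if i == 0 else 0.0), 0.0),
            staff_minutes=(0.0, 0.0),
            bed_days=(0.0, 0.0),
            consumable_packs=0.0,
            catheter_days=5.0,
            wait_days=wait[i],
            followup_rate=followup_rate,
            oop_mean=oop[i],
            utility_traj=traj[i] if traj else _traj(0.80, 0.80, 0.75, 0.90),
            recurrence_hazard=recurrence[i],
        )
    return SimConfig(
        n_per_arm=n_per_arm, seed=seed, stratum_prob=0.5,
        crossover_prob=crossover, no_surgery_prob=no_surgery,
        between_sd=between_sd, within_sd=within_sd, arms=arms,
        missing=missing or MissingSpec(),
    )


@pytest.fixture
def exact_config():
    return make_exact_config


@pytest.fixture(scope="session")
def small_trial(unit_costs, toy_tariff):
    """One realistic default-condition trial, shared across read-only tests."""
    from uroecon.synthdata import simulate_trial
    cfg = default_config(seed=314)
    records, truth = simulate_trial(cfg, unit_costs, toy_tariff)
    return cfg, records, truth
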
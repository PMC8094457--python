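"""Micro-costing with price-year conversion and perspective selection.

Bottom-up per-patient costing: itemised resource quantities (theatre
minutes, staff minutes, bed-days, consumables, follow-up contacts) are
multiplied by unit costs drawn from an external table, converted to a
common price year (default 2017) with a Consumer Price Index series, and
aggregated into nested perspectives:

    intervention  — index procedure plus re-interventions
    nhs           — intervention plus follow-up NHS service use
    societal      — nhs plus patients' out-of-pocket expenses

Costs attach to recall periods rather than calendar dates and are never
rescaled across follow-up; discounting of second-year components happens
downstream in the within-trial analysis, keeping this module purely
additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthdata import PatientRecord

__all__ = [
    "CpiIndex",
    "UnitCostTable",
    "CostBreakdown",
    "PERSPECTIVES",
    "adjust_price_year",
    "procedure_cost",
    "total_cost",
    "costs_frame",
]

PERSPECTIVES = ("intervention", "nhs", "societal")

#: Day-offset boundary between the first and second follow-up year.
YEAR2_START_DAY = 365.25


class CpiIndex:
    """Consumer Price Index series: calendar year -> index value."""

    def __init__(self, values: Mapping[int, float]):
        self._values = {int(y): float(v) for y, v in values.items()}
        if any(v <= 0 for v in self._values.values()):
            raise ValueError("CPI index values must be strictly positive")

    def __getitem__(self, year: int) -> float:
        try:
            return self._values[int(year)]
        except KeyError:
            raise KeyError(f"year {year} not present in the CPI index") from None

    def __contains__(self, year: int) -> bool:
        return int(year) in self._values

    @classmethod
    def from_csv(cls, path: str | Path) -> "CpiIndex":
        df = pd.read_csv(path)
        return cls(dict(zip(df["year"].astype(int), df["index"].astype(float))))


def adjust_price_year(amount: float, from_year: int, cpi: CpiIndex,
                      target_year: int = 2017) -> float:
    """Convert an amount between price years by the CPI ratio."""
    return amount * cpi[target_year] / cpi[from_year]


class UnitCostTable:
    """Resource item -> unit cost, normalised to a target price year."""

    def __init__(self, entries: Mapping[str, tuple[float, int, str]],
                 cpi: CpiIndex | None = None, target_year: int = 2017):
        self.target_year = int(target_year)
        self._raw = dict(entries)
        self._cost: dict[str, float] = {}
        for item, (cost, year, _unit) in self._raw.items():
            if cost < 0:
                raise ValueError(f"negative unit cost for {item!r}")
            if int(year) != self.target_year:
                if cpi is None:
                    raise ValueError(
                        f"unit cost for {item!r} is in price year {year}; "
                        f"a CPI index is required to convert to {self.target_year}"
                    )
                cost = adjust_price_year(cost, int(year), cpi, self.target_year)
            self._cost[item] = float(cost)

    def unit_cost(self, item: str) -> float:
        try:
            return self._cost[item]
        except KeyError:
            raise KeyError(f"no unit cost for resource item {item!r}") from None

    def __contains__(self, item: str) -> bool:
        return item in self._cost

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(self._cost)

    @classmethod
    def from_csv(cls, path: str | Path, cpi: CpiIndex | None = None,
                 target_year: int = 2017) -> "UnitCostTable":
        df = pd.read_csv(path)
        entries = {
            str(r.item): (float(r.unit_cost), int(r.price_year), str(r.unit))
            for r in df.itertuples()
        }
        return cls(entries, cpi=cpi, target_year=target_year)


def procedure_cost(resources: Iterable[tuple[str, float]],
                   unit_costs: UnitCostTable) -> float:
    """Cost of one procedure: sum of quantity x unit cost over its items."""
    total = 0.0
    missing = []
    for item, qty in resources:
        if item not in unit_costs:
            missing.append(item)
            continue
        total += qty * unit_costs.unit_cost(item)
    if missing:
        raise KeyError(f"unpriced resource items: {sorted(set(missing))}")
    return total


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient cost components in target-price-year pounds.

    ``*_year2`` fields carry the part of each component that falls in the
    second follow-up year (day >= 365.25), so the analysis layer can apply
    discounting without re-walking resource items.
    """

    intervention_cost: float
    reintervention_cost: float
    followup_nhs_cost: float
    oop_cost: float
    reintervention_year2: float = 0.0
    followup_year2: float = 0.0
    oop_year2: float = 0.0

    @property
    def intervention_total(self) -> float:
        return self.intervention_cost + self.reintervention_cost

    @property
    def nhs_total(self) -> float:
        return self.intervention_total + self.followup_nhs_cost

    @property
    def societal_total(self) -> float:
        return self.nhs_total + self.oop_cost

    def perspective_total(self, perspective: str) -> float:
        if perspective == "intervention":
            return self.intervention_total
        if perspective == "nhs":
            return self.nhs_total
        if perspective == "societal":
            return self.societal_total
        raise ValueError(f"unknown perspective {perspective!r}; use one of {PERSPECTIVES}")

    def discounted_total(self, perspective: str, rate: float = 0.035) -> float:
        """Perspective total with second-year components discounted one year."""
        df = 1.0 / (1.0 + rate)
        adj = (df - 1.0) * self.reintervention_year2
        if perspective in ("nhs", "societal"):
            adj += (df - 1.0) * self.followup_year2
        if perspective == "societal":
            adj += (df - 1.0) * self.oop_year2
        return self.perspective_total(perspective) + adj


def total_cost(patient: "PatientRecord", unit_costs: UnitCostTable,
               perspective: str = "societal") -> CostBreakdown:
    """Micro-cost one patient; ``perspective`` is validated here so callers
    fail fast, but the full breakdown is always returned."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}; use one of {PERSPECTIVES}")
    index_cost = procedure_cost(patient.index_resources, unit_costs)
    reint = reint_y2 = 0.0
    for r in patient.reinterventions:
        c = procedure_cost(r.resources, unit_costs)
        reint += c
        if r.day >= YEAR2_START_DAY:
            reint_y2 += c
    fup = fup_y2 = 0.0
    for item, qty, day in patient.followup_resources:
        c = qty * unit_costs.unit_cost(item) if item in unit_costs else None
        if c is None:
            raise KeyError(f"unpriced resource items: [{item!r}]")
        fup += c
        if day >= YEAR2_START_DAY:
            fup_y2 += c
    oop = oop_y2 = 0.0
    for _desc, amount, day in patient.oop_items:
        oop += amount
        if day >= YEAR2_START_DAY:
            oop_y2 += amount
    return CostBreakdown(
        intervention_cost=index_cost,
        reintervention_cost=reint,
        followup_nhs_cost=fup,
        oop_cost=oop,
        reintervention_year2=reint_y2,
        followup_year2=fup_y2,
        oop_year2=oop_y2,
    )


def costs_frame(patients: Iterable["PatientRecord"],
                unit_costs: UnitCostTable) -> pd.DataFrame:
    """One row per patient with every cost component and perspective total."""
    rows = []
    for p in patients:
        b = total_cost(p, unit_costs)
        rows.append(
            {
                "id": p.id,
                "arm_allocated": p.arm_allocated,
                "intervention_cost": b.intervention_cost,
                "reintervention_cost": b.reintervention_cost,
                "followup_nhs_cost": b.followup_nhs_cost,
                "oop_cost": b.oop_cost,
                "intervention_total": b.intervention_total,
                "nhs_total": b.nhs_total,
                "societal_total": b.societal_total,
            }
        )
    return pd.DataFrame(rows)
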
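"""EQ-5D-5L scoring and QALY construction.

Scores five-dimension, five-level health profiles to utilities via a
pluggable tariff (value set), assembles per-patient utility time series
anchored at randomisation or at the pre-surgery assessment, applies the
trial's complete-case inclusion rules, and integrates utilities over time
(trapezoidal area under the curve) to quality-adjusted life years, with
optional rescaling to the nominal 730-day follow-up window and optional
discounting at 3.5% per annum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "TIMEPOINTS",
    "Eq5dProfile",
    "Tariff",
    "UtilitySeries",
    "InclusionSpec",
    "load_tariff",
    "score_profile",
    "build_utility_series",
    "is_complete_case",
    "qaly_auc",
    "rescale_qaly",
    "discount_qaly_series",
]

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

#: Scheduled assessment labels, in nominal chronological order.
TIMEPOINTS = (
    "baseline",
    "pre_surgery",
    "cath_1wk",
    "m3_post_surgery",
    "m6_post_surgery",
    "m9_post_surgery",
    "m12_post_surgery",
    "m18_post_rand",
    "m24_post_rand",
    "m24_post_surgery",
    "end_of_study",
)

#: Observations beyond this many days from the series anchor are truncated.
MAX_FOLLOWUP_DAYS = 760.0

#: Nominal follow-up window in days (two years of scheduled collection).
NOMINAL_DAYS = 730.0

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class Eq5dProfile:
    """One EQ-5D-5L response: a level in 1..5 on each of five dimensions."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            lvl = getattr(self, dim)
            if not (isinstance(lvl, (int, np.integer)) and 1 <= lvl <= 5):
                raise ValueError(
                    f"EQ-5D-5L level for {dim!r} must be an integer in 1..5, got {lvl!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(int(getattr(self, d)) for d in DIMENSIONS)


class Tariff:
    """Value set mapping EQ-5D-5L profiles to utilities.

    Stored as an additive decrement per (dimension, level): the utility of a
    profile is ``1 - sum(decrement[dim, level])``.  Full health (11111)
    always scores 1; utilities may be negative (states worse than dead).
    A complete 3125-row lookup can also be supplied and is converted to the
    additive form only if it is exactly additive; otherwise it is kept as a
    lookup table.
    """

    def __init__(self, decrements: dict[tuple[str, int], float] | None = None,
                 lookup: dict[tuple[int, ...], float] | None = None):
        if (decrements is None) == (lookup is None):
            raise ValueError("provide exactly one of decrements or lookup")
        self._decrements = dict(decrements) if decrements is not None else None
        self._lookup = dict(lookup) if lookup is not None else None
        if self._decrements is not None:
            for (dim, lvl), dec in self._decrements.items():
                if dim not in DIMENSIONS:
                    raise ValueError(f"unknown dimension {dim!r} in tariff")
                if not 2 <= lvl <= 5:
                    raise ValueError(f"tariff decrements apply to levels 2..5, got {lvl}")
                if dec < 0:
                    raise ValueError(f"negative decrement for ({dim}, {lvl})")
        else:
            full = self._lookup.get((1, 1, 1, 1, 1))
            if full is None or abs(full - 1.0) > 1e-12:
                raise ValueError("lookup tariff must score full health (11111) as 1")
            if any(v > 1.0 + 1e-12 for v in self._lookup.values()):
                raise ValueError("tariff values must not exceed 1")

    def value(self, profile: Eq5dProfile) -> float:
        if self._lookup is not None:
            try:
                return self._lookup[profile.levels]
            except KeyError:
                raise KeyError(f"profile {profile.levels} not in tariff lookup") from None
        total = 0.0
        for dim, lvl in zip(DIMENSIONS, profile.levels):
            if lvl > 1:
                total += self._decrements.get((dim, lvl), 0.0)
        return 1.0 - total


def load_tariff(path: str | Path) -> Tariff:
    """Read a tariff from a delimited file.

    Additive form has columns ``dimension, level, decrement``; full-lookup
    form has the five dimension columns plus ``value``.
    """
    df = pd.read_csv(path)
    if {"dimension", "level", "decrement"} <= set(df.columns):
        dec = {
            (str(r.dimension), int(r.level)): float(r.decrement)
            for r in df.itertuples()
        }
        return Tariff(decrements=dec)
    if set(DIMENSIONS) | {"value"} <= set(df.columns):
        lookup = {
            tuple(int(r[d]) for d in DIMENSIONS): float(r["value"])
            for _, r in df.iterrows()
        }
        return Tariff(lookup=lookup)
    raise ValueError(f"unrecognised tariff file layout: columns {list(df.columns)}")


def score_profile(profile: Eq5dProfile, tariff: Tariff) -> float:
    """Utility of one EQ-5D-5L profile under the given tariff (≤ 1)."""
    return tariff.value(profile)


@dataclass
class UtilitySeries:
    """Ordered (day-offset, utility) pairs anchored at day 0."""

    anchor: str  # "randomisation" | "surgery"
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.anchor not in ("randomisation", "surgery"):
            raise ValueError(f"unknown anchor {self.anchor!r}")
        days = [d for d, _ in self.points]
        if days:
            if days[0] != 0:
                raise ValueError("first point must be at day 0")
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("days must be strictly increasing")
        if any(u > 1.0 + 1e-12 for _, u in self.points):
            raise ValueError("utilities must not exceed 1")

    @property
    def span_days(self) -> float:
        return self.points[-1][0] if self.points else 0.0


def build_utility_series(
    observations: Sequence[tuple[str, float, Eq5dProfile | None]],
    tariff: Tariff,
    anchor: str = "randomisation",
    surgery_day: float | None = None,
) -> UtilitySeries:
    """Assemble a utility series from labelled EQ-5D-5L observations.

    ``observations`` are (timepoint label, day from randomisation, profile)
    triples; a ``None`` profile is a missing response and is skipped.  For
    the surgery anchor, day offsets are taken relative to the pre-surgery
    assessment (falling back to ``surgery_day``) and earlier observations
    are dropped.  The first observation used defines time zero.
    Observations beyond 760 days from the anchor are truncated to day 760.
    Coincident days are merged by averaging.
    """
    scored = [
        (lbl, float(day), score_profile(prof, tariff))
        for lbl, day, prof in observations
        if prof is not None
    ]
    if anchor == "surgery":
        pre = [day for lbl, day, _ in scored if lbl == "pre_surgery"]
        origin = pre[0] if pre else surgery_day
        if origin is None:
            raise ValueError("surgery anchor requires a pre-surgery observation or surgery_day")
        scored = [(lbl, day - origin, u) for lbl, day, u in scored if day >= origin]
    scored.sort(key=lambda t: t[1])
    if not scored:
        return UtilitySeries(anchor=anchor, points=[])
    origin = scored[0][1]
    pts: list[tuple[float, float]] = []
    for _, day, u in scored:
        off = min(day - origin, MAX_FOLLOWUP_DAYS)
        if pts and off <= pts[-1][0]:
            if off == pts[-1][0]:
                pts[-1] = (off, 0.5 * (pts[-1][1] + u))
            continue  # a later truncated point collapsing onto an earlier one
        pts.append((off, u))
    return UtilitySeries(anchor=anchor, points=pts)


@dataclass(frozen=True)
class InclusionSpec:
    """Which complete-case rule set applies.

    ``analysis`` selects the assessment window: ``post_randomisation``
    (baseline to 24 months after randomisation, the base case) or
    ``post_surgery`` (pre-surgery to 24 months after surgery).  Patients
    who never had their index procedure are always judged by the
    no-surgery rule regardless of ``analysis``.
    """

    analysis: str = "post_randomisation"

    def __post_init__(self) -> None:
        if self.analysis not in ("post_randomisation", "post_surgery"):
            raise ValueError(f"unknown analysis {self.analysis!r}")


# Mid-range labels accepted by each rule set.
_MID_POST_RAND = frozenset(
    {"m3_post_surgery", "m6_post_surgery", "m9_post_surgery", "m12_post_surgery",
     "m18_post_rand"}
)
_MID_POST_SURG = _MID_POST_RAND | {"m24_post_rand"}


def is_complete_case(
    observations: Sequence[tuple[str, float, Eq5dProfile | None]],
    had_surgery: bool,
    spec: InclusionSpec,
) -> bool:
    """Apply the trial's three complete-case rule sets.

    A participant qualifies with at least three observations: one at the
    start of the assessment window, one at the end, and one mid-range.
    Patients without an index procedure need baseline plus both the 18- and
    24-month post-randomisation assessments.
    """
    present = {lbl for lbl, _, prof in observations if prof is not None}
    if not had_surgery:
        return {"baseline", "m18_post_rand", "m24_post_rand"} <= present
    if spec.analysis == "post_randomisation":
        return (
            "baseline" in present
            and "m24_post_rand" in present
            and bool(present & _MID_POST_RAND)
        )
    return (
        "pre_surgery" in present
        and "m24_post_surgery" in present
        and bool(present & _MID_POST_SURG)
    )


def qaly_auc(series: UtilitySeries, days_per_year: float = DAYS_PER_YEAR) -> float:
    """Trapezoidal area under the utility curve, in QALYs."""
    if len(series.points) < 2:
        raise ValueError("QALY area is undefined for fewer than two observations")
    total = 0.0
    for (d0, u0), (d1, u1) in zip(series.points, series.points[1:]):
        total += (d1 - d0) * (u0 + u1) / 2.0
    return total / days_per_year


def rescale_qaly(qaly: float, observed_span_days: float,
                 nominal_days: float = NOMINAL_DAYS) -> float:
    """Rescale a QALY to the nominal collection window (default 730 days).

    Compensates for between-arm differences in waiting time: the observed
    area is stretched or shrunk multiplicatively to the nominal span.
    """
    if observed_span_days <= 0:
        raise ValueError("observed span must be positive")
    return qaly * nominal_days / observed_span_days


def discount_qaly_series(series: UtilitySeries, rate: float = 0.035,
                         days_per_year: float = DAYS_PER_YEAR) -> float:
    """Discounted QALY area at an annual rate.

    Each trapezoid segment is split at year boundaries and weighted by the
    yearly-compounded discount factor of the year its midpoint falls in, so
    a rate of zero reproduces :func:`qaly_auc` exactly.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    if len(series.points) < 2:
        raise ValueError("QALY area is undefined for fewer than two observations")
    total = 0.0
    for (d0, u0), (d1, u1) in zip(series.points, series.points[1:]):
        t0, t1 = d0 / days_per_year, d1 / days_per_year
        if t1 == t0:
            continue
        slope = (u1 - u0) / (t1 - t0)
        # split [t0, t1] at integer year boundaries
        cuts = [t0] + [float(y) for y in range(int(np.floor(t0)) + 1, int(np.ceil(t1)))] + [t1]
        cuts = sorted(set(c for c in cuts if t0 <= c <= t1))
        for a, b in zip(cuts, cuts[1:]):
            ua = u0 + slope * (a - t0)
            ub = u0 + slope * (b - t0)
            mid = 0.5 * (a + b)
            df = (1.0 + rate) ** (-np.floor(mid))
            total += df * (b - a) * (ua + ub) / 2.0
    return float(total)
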
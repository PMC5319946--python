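"""Scalar behavioural indices computed from raw per-rat measurements.

Covers the two-bottle sucrose-preference percentage and the 50%
mechanical withdrawal threshold estimated from von Frey filament
response series, plus small helpers for weekly weight series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_FORCE_SET",
    "VonFreySeries",
    "ThresholdEstimate",
    "BehaviouralRecord",
    "NoIntakeError",
    "DataIntegrityError",
    "sucrose_preference",
    "fifty_percent_threshold",
    "weekly_weight_series",
]

#: calibrated filament forces in grams, strongest first as supplied
DEFAULT_FORCE_SET: tuple[float, ...] = (15.0, 10.0, 8.0, 6.0, 4.0, 2.0)


class NoIntakeError(ValueError):
    """The rat drank nothing; the preference ratio is undefined."""


class DataIntegrityError(ValueError):
    """Duplicate or contradictory raw measurements."""


@dataclass(frozen=True)
class VonFreySeries:
    """Ordered filament applications with their withdrawal outcomes."""

    forces: tuple[float, ...]
    responses: tuple[bool, ...]

    def __post_init__(self):
        if len(self.forces) != len(self.responses):
            raise ValueError(
                f"forces ({len(self.forces)}) and responses "
                f"({len(self.responses)}) differ in length"
            )

    def __len__(self) -> int:
        return len(self.forces)


@dataclass(frozen=True)
class ThresholdEstimate:
    grams: float
    flag: str | None = None  # None | 'ceiling' | 'floor'


@dataclass
class BehaviouralRecord:
    """One rat's raw measurements at one assessment day."""

    rat_id: str
    group: str
    day: int
    weight_g: float | None = None
    sucrose_g: float | None = None
    water_g: float | None = None
    rearing_count: int | None = None
    of_trajectory: str | None = None
    epm_trajectory: str | None = None
    von_frey: VonFreySeries | None = None
    flags: tuple[str, ...] = ()

    VALID_GROUPS = ("CON", "IS", "IS_AMI", "AMI")

    def __post_init__(self):
        if self.group not in self.VALID_GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {self.VALID_GROUPS}"
            )
        for name in ("weight_g", "sucrose_g", "water_g"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if self.rearing_count is not None and self.rearing_count < 0:
            raise ValueError(f"rearing_count must be >= 0, got {self.rearing_count!r}")


def sucrose_preference(sucrose_g: float, water_g: float) -> float:
    """Percent preference: 100 * sucrose / (sucrose + water).

    Raises :class:`NoIntakeError` when both consumptions are zero.
    """
    if sucrose_g < 0 or water_g < 0:
        raise ValueError("consumptions must be non-negative")
    total = sucrose_g + water_g
    if total == 0:
        raise NoIntakeError("zero total intake: preference undefined")
    return 100.0 * sucrose_g / total


def _ascending_threshold(series: VonFreySeries, force_set) -> ThresholdEstimate:
    forces = np.asarray(series.forces, dtype=float)
    resp = np.asarray(series.responses, dtype=bool)
    lo, hi = min(force_set), max(force_set)
    if not resp.any():
        return ThresholdEstimate(hi, "ceiling")
    if resp.all():
        return ThresholdEstimate(lo, "floor")
    for f in sorted(set(series.forces)):
        mask = forces == f
        if mask.any() and resp[mask].mean() >= 0.5:
            return ThresholdEstimate(float(f), None)
    # responses exist but no filament reaches a 50% positive fraction
    return ThresholdEstimate(hi, "ceiling")


def _updown_threshold(series: VonFreySeries, force_set) -> ThresholdEstimate:
    """Staircase-style estimate: mean of filament midpoints at response
    reversals.  Useful only when the series was collected up-down; the
    ascending rule is the default because it needs no protocol structure.
    """
    lo, hi = min(force_set), max(force_set)
    resp = series.responses
    if not any(resp):
        return ThresholdEstimate(hi, "ceiling")
    if all(resp):
        return ThresholdEstimate(lo, "floor")
    mids = [
        0.5 * (series.forces[i - 1] + series.forces[i])
        for i in range(1, len(series))
        if resp[i] != resp[i - 1]
    ]
    est = float(np.mean(mids))
    return ThresholdEstimate(min(max(est, lo), hi), None)


def fifty_percent_threshold(
    series: VonFreySeries,
    method: str = "ascending",
    force_set: Sequence[float] = DEFAULT_FORCE_SET,
) -> ThresholdEstimate:
    """Estimate the force (g) evoking withdrawal on half of applications.

    ``method="ascending"``: lowest filament whose empirical positive
    fraction is >= 0.5, scanning weakest to strongest.  All-negative
    series return the strongest force flagged ``ceiling``; all-positive
    return the weakest flagged ``floor``.  ``method="updown"`` applies a
    staircase reversal-midpoint estimator instead.
    """
    if len(series) == 0:
        raise ValueError("empty von Frey series")
    known = set(force_set)
    stray = [f for f in series.forces if f not in known]
    if stray:
        raise ValueError(f"forces {sorted(set(stray))} not in force set {sorted(known)}")
    if method == "ascending":
        return _ascending_threshold(series, force_set)
    if method == "updown":
        return _updown_threshold(series, force_set)
    raise ValueError(f"unknown method {method!r}")


def weekly_weight_series(
    records: Iterable[BehaviouralRecord],
) -> list[tuple[int, float]]:
    """(day, weight) pairs for one rat, sorted by day.

    Rejects duplicate weights for the same day and mixed rat ids.
    """
    recs = [r for r in records if r.weight_g is not None]
    if not recs:
        raise ValueError("no weight measurements supplied")
    ids = {r.rat_id for r in recs}
    if len(ids) > 1:
        raise DataIntegrityError(f"records from multiple rats: {sorted(ids)}")
    seen: dict[int, float] = {}
    for r in recs:
        if r.day in seen:
            raise DataIntegrityError(
                f"duplicate weight for rat {r.rat_id!r} on day {r.day}"
            )
        seen[r.day] = r.weight_g
    return sorted(seen.items())
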
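"""Open-field and elevated-plus-maze metrics from tracked trajectories.

A trajectory is a time-stamped sequence of planar positions (cm) for one
300-s trial, together with the arena it was recorded in.  Zone
membership uses the tracked centre point.  Open-field segments that
cross the inner-circle boundary are split at the exact geometric
intersection, so inner time/distance do not depend on the sampling rate.

The percentage denominators follow the published definitions verbatim:
IT% and OT% divide by the nominal 300-s trial even if the trace is
shorter (``strict=True`` rejects truncated traces instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "OpenFieldArena",
    "EPMArena",
    "Trajectory",
    "OFMetrics",
    "EPMMetrics",
    "path_length",
    "of_metrics",
    "epm_metrics",
    "epm_zone_labels",
    "count_entries",
]

TRIAL_DURATION_S = 300.0


@dataclass(frozen=True)
class OpenFieldArena:
    """Circular arena with a concentric inner zone (diameters in cm)."""

    outer_diameter: float = 90.0
    inner_diameter: float = 60.0

    kind = "open_field"

    def __post_init__(self):
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError(
                "need 0 < inner_diameter < outer_diameter, got "
                f"{self.inner_diameter} / {self.outer_diameter}"
            )

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2.0

    @property
    def inner_radius(self) -> float:
        return self.inner_diameter / 2.0

    def contains(self, xy: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        r = np.hypot(xy[..., 0], xy[..., 1])
        return r <= self.outer_radius + tol


@dataclass(frozen=True)
class EPMArena:
    """Four axis-aligned arms around a central square (cm).

    The two arms along ``open_axis`` are the open arms.  Arm dimensions
    are configuration, not constants: apparatus descriptions often state
    only wall height and elevation.
    """

    arm_length: float = 50.0
    arm_width: float = 10.0
    open_axis: str = "x"
    wall_height: float = 22.0  # metadata only
    elevation: float = 70.0  # metadata only

    kind = "epm"

    def __post_init__(self):
        if self.arm_length <= 0 or self.arm_width <= 0:
            raise ValueError("arm dimensions must be positive")
        if self.open_axis not in ("x", "y"):
            raise ValueError(f"open_axis must be 'x' or 'y', got {self.open_axis!r}")

    @property
    def half_width(self) -> float:
        return self.arm_width / 2.0

    def contains(self, xy: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        x, y = np.abs(xy[..., 0]), np.abs(xy[..., 1])
        h = self.half_width + tol
        reach = self.half_width + self.arm_length + tol
        return ((x <= h) & (y <= reach)) | ((y <= h) & (x <= reach))


@dataclass
class Trajectory:
    """Time-stamped planar positions for one trial."""

    times: np.ndarray  # (n,) seconds
    xy: np.ndarray  # (n, 2) cm
    arena: OpenFieldArena | EPMArena
    trial_duration: float = TRIAL_DURATION_S

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.times.ndim != 1 or self.xy.shape != (self.times.size, 2):
            raise ValueError(
                f"shape mismatch: times {self.times.shape}, xy {self.xy.shape}"
            )
        if self.times.size and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.times.size and (
            self.times[0] < 0 or self.times[-1] > self.trial_duration + 1e-9
        ):
            raise ValueError(
                f"times must lie in [0, {self.trial_duration}], got "
                f"[{self.times[0]}, {self.times[-1]}]"
            )

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class OFMetrics:
    total_distance_m: float
    inner_distance_m: float
    inner_time_s: float
    id_pct: float
    it_pct: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class EPMMetrics:
    open_time_s: float
    closed_time_s: float
    centre_time_s: float
    open_entries: int
    closed_entries: int
    ot_pct: float
    oe_pct: float | None
    flags: tuple[str, ...] = ()


def path_length(traj: Trajectory) -> float:
    """Total path length in metres (sum of segment chords, cm -> m)."""
    if len(traj) < 2:
        warnings.warn("trajectory has fewer than 2 samples; path length is 0")
        return 0.0
    seg = np.diff(traj.xy, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum() / 100.0)


def _inner_fraction(p0: np.ndarray, p1: np.ndarray, radius: float) -> np.ndarray:
    """Fraction of each segment's parameter interval [0,1] lying inside
    the circle of ``radius`` centred at the origin (exact split)."""
    d = p1 - p0
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", p0, d)
    c = np.einsum("ij,ij->i", p0, p0) - radius * radius

    frac = np.zeros(len(p0))
    # degenerate (stationary) segments: in or out by the point itself
    stat = a == 0
    frac[stat] = (c[stat] <= 0).astype(float)

    mov = ~stat
    disc = b[mov] ** 2 - 4 * a[mov] * c[mov]
    sq = np.sqrt(np.maximum(disc, 0.0))
    t1 = (-b[mov] - sq) / (2 * a[mov])
    t2 = (-b[mov] + sq) / (2 * a[mov])
    inside_len = np.clip(np.minimum(t2, 1.0) - np.maximum(t1, 0.0), 0.0, 1.0)
    # no real intersection: segment entirely on one side; midpoint decides
    mid_inside = (a[mov] * 0.25 + b[mov] * 0.5 + c[mov]) <= 0
    frac[mov] = np.where(disc > 0, inside_len, mid_inside.astype(float))
    return frac


def of_metrics(traj: Trajectory, strict: bool = False) -> OFMetrics:
    """Open-field distances, inner-zone time, ID% and IT%."""
    arena = traj.arena
    if arena.kind != "open_field":
        raise ValueError(f"expected an open-field arena, got {arena.kind!r}")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    flags: list[str] = []
    covered = traj.times[-1] - traj.times[0] if len(traj) else 0.0
    if covered < traj.trial_duration - 1e-6:
        if strict:
            raise ValueError(
                f"trace covers {covered:.1f} s of a {traj.trial_duration:.0f}-s trial"
            )
        flags.append("truncated_trace")

    if len(traj) < 2:
        inside = float(np.hypot(*traj.xy[0]) <= arena.inner_radius)
        inner_time = inside * covered
        return OFMetrics(0.0, 0.0, inner_time, 0.0,
                         100.0 * inner_time / traj.trial_duration,
                         tuple(flags + ["stationary"]))

    p0, p1 = traj.xy[:-1], traj.xy[1:]
    seg_cm = np.hypot(*(p1 - p0).T)
    seg_dt = np.diff(traj.times)
    frac = _inner_fraction(p0, p1, arena.inner_radius)

    total_m = float(seg_cm.sum() / 100.0)
    inner_m = float((frac * seg_cm).sum() / 100.0)
    inner_s = float((frac * seg_dt).sum())
    it_pct = 100.0 * inner_s / traj.trial_duration
    if total_m == 0.0:
        flags.append("stationary")
        id_pct = 0.0
    else:
        id_pct = 100.0 * inner_m / total_m
    return OFMetrics(total_m, inner_m, inner_s, id_pct, it_pct, tuple(flags))


def epm_zone_labels(xy: np.ndarray, arena: EPMArena, tol: float = 1e-6) -> np.ndarray:
    """Classify positions as ``centre``, ``open`` or ``closed``."""
    xy = np.asarray(xy, dtype=float)
    ax, ay = np.abs(xy[..., 0]), np.abs(xy[..., 1])
    h = arena.half_width
    along_open, along_closed = (ax, ay) if arena.open_axis == "x" else (ay, ax)
    labels = np.full(xy.shape[:-1], "", dtype="<U6")
    centre = (ax <= h + tol) & (ay <= h + tol)
    open_arm = ~centre & (along_closed <= h + tol)
    closed_arm = ~centre & (along_open <= h + tol)
    labels[centre] = "centre"
    labels[open_arm] = "open"
    labels[closed_arm] = "closed"
    if not arena.contains(xy, tol).all() or (labels == "").any():
        bad = np.argwhere(~arena.contains(xy, tol) | (labels == ""))[:1]
        raise ValueError(f"position outside the maze at sample index {bad.ravel()}")
    return labels


def _runs(labels: Sequence[str], times: np.ndarray) -> list[tuple[str, float]]:
    """Run-length encode labels into (label, duration) pairs."""
    runs: list[tuple[str, float]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[i - 1]:
            end_t = times[i] if i < len(labels) else times[-1]
            runs.append((labels[start], float(end_t - times[start])))
            start = i
    return runs


def count_entries(
    labels: Sequence[str],
    times: Sequence[float],
    debounce: float = 0.5,
) -> dict[str, int]:
    """Entry counts per zone from a labelled time sequence.

    An entry is a transition from a different zone into the zone.  Label
    runs shorter than ``debounce`` seconds are treated as tracking
    jitter and merged into the preceding run (``debounce=0`` counts
    every transition).
    """
    times = np.asarray(times, dtype=float)
    if len(labels) != times.size:
        raise ValueError("labels and times differ in length")
    if len(labels) == 0:
        return {}
    runs = _runs(list(labels), times)
    filtered: list[tuple[str, float]] = []
    for lab, dur in runs:
        if filtered and dur < debounce:
            filtered[-1] = (filtered[-1][0], filtered[-1][1] + dur)
        elif filtered and filtered[-1][0] == lab:
            filtered[-1] = (lab, filtered[-1][1] + dur)
        else:
            filtered.append((lab, dur))
    counts = {z: 0 for z in dict.fromkeys(labels)}
    for (prev, _), (cur, _) in zip(filtered, filtered[1:]):
        if cur != prev:
            counts[cur] = counts.get(cur, 0) + 1
    return counts


def epm_metrics(
    traj: Trajectory, debounce: float = 0.5, strict: bool = False
) -> EPMMetrics:
    """EPM zone times, arm entries, OT% and OE%.

    Interval time is attributed to the zone of its left sample, so zone
    times are exact up to one sampling interval.  OE% is ``None`` (with
    a ``no_entries`` flag) when the rat never entered any arm; the
    scoring layer decides how to treat that.
    """
    arena = traj.arena
    if arena.kind != "epm":
        raise ValueError(f"expected an EPM arena, got {arena.kind!r}")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    flags: list[str] = []
    covered = traj.times[-1] - traj.times[0]
    if covered < traj.trial_duration - 1e-6:
        if strict:
            raise ValueError(
                f"trace covers {covered:.1f} s of a {traj.trial_duration:.0f}-s trial"
            )
        flags.append("truncated_trace")

    labels = epm_zone_labels(traj.xy, arena)
    if len(traj) == 1:
        durs = {labels[0]: 0.0}
    else:
        seg_dt = np.diff(traj.times)
        durs = {
            z: float(seg_dt[labels[:-1] == z].sum()) for z in ("open", "closed", "centre")
        }
    entries = count_entries(labels, traj.times, debounce=debounce)
    open_e = entries.get("open", 0)
    closed_e = entries.get("closed", 0)
    ot_pct = 100.0 * durs.get("open", 0.0) / traj.trial_duration
    total_e = open_e + closed_e
    if total_e == 0:
        oe_pct = None
        flags.append("no_entries")
    else:
        oe_pct = 100.0 * open_e / total_e
    return EPMMetrics(
        open_time_s=durs.get("open", 0.0),
        closed_time_s=durs.get("closed", 0.0),
        centre_time_s=durs.get("centre", 0.0),
        open_entries=open_e,
        closed_entries=closed_e,
        ot_pct=ot_pct,
        oe_pct=oe_pct,
        flags=tuple(flags),
    )
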
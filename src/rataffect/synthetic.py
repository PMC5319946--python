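"""Synthetic cohort generation.

Produces four-group rat cohorts (CON, IS, IS_AMI, AMI) with raw
observables — weekly bottle masses, daily von Frey response series,
day-21 open-field and plus-maze trajectories and rearing counts — whose
group structure follows a configurable :class:`CohortDesign`.  This is
an emission model only: it makes the downstream pipeline testable, it
does not model any neurobiology.

Seeding: a single master seed plus a structural key (group index, rat
index, purpose code, day) feeds ``numpy.random.SeedSequence``, so every
rat/trial has its own substream and adding a rat never perturbs the
draws of another.

Two trajectory generators coexist:

* :func:`simulate_trajectory` — a biased correlated random walk
  (open field) or a skeleton walk over the maze arms (EPM), driven by a
  :class:`LocomotionProfile`.  Zone occupancy is controlled only
  indirectly through ``inner_zone_bias``.
* :func:`build_of_trajectory` / :func:`build_epm_trajectory` —
  choreographed paths that realise explicit target metrics (total
  distance, ID%, IT%, OT%, OE%) almost exactly while keeping a
  stochastic texture.  :func:`simulate_cohort` uses these, because a
  constant-speed random walk cannot dissociate ID% from IT% and the
  published group effects require exactly that dissociation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .indices import DEFAULT_FORCE_SET, BehaviouralRecord, VonFreySeries
from .trajectories import EPMArena, OpenFieldArena, Trajectory

__all__ = [
    "EndpointParams",
    "GroupSpec",
    "CohortDesign",
    "LocomotionProfile",
    "DrinkingResult",
    "Cohort",
    "simulate_cohort",
    "simulate_drinking",
    "simulate_trajectory",
    "simulate_von_frey",
    "build_of_trajectory",
    "build_epm_trajectory",
    "null_design",
    "reference_design",
    "ENDPOINTS",
]

#: endpoint names a group spec may parameterise
ENDPOINTS = (
    "weight",
    "sucrose_pref",
    "distance_m",
    "rearing",
    "id_pct",
    "it_pct",
    "ot_pct",
    "oe_pct",
    "threshold_g",
)

# purpose codes for seed-substream derivation
_P_WEIGHT, _P_SUCROSE, _P_DRINK, _P_THRESH, _P_VF, _P_REAR, _P_OF, _P_EPM = range(8)


class EndpointParams(BaseModel):
    """Generative parameters for one endpoint in one group.

    The latent per-rat value on day ``d`` is
    ``mean + day_slope * d + sd * z`` with ``z`` standard normal.
    """

    mean: float
    sd: float = Field(ge=0.0)
    day_slope: float = 0.0


class GroupSpec(BaseModel):
    name: str
    n: int = Field(ge=1)
    endpoints: dict[str, EndpointParams]

    @field_validator("endpoints")
    @classmethod
    def _known_endpoints(cls, v):
        unknown = set(v) - set(ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints: {sorted(unknown)}")
        return v


class CohortDesign(BaseModel):
    """Full generative design for one cohort."""

    groups: list[GroupSpec]
    days: int = Field(default=21, ge=1)
    seed: int = 0
    weigh_days: Optional[list[int]] = None  # default: weekly
    sucrose_days: Optional[list[int]] = None  # default: weekly
    threshold_days: Optional[list[int]] = None  # default: daily
    of_epm_day: Optional[int] = None  # default: final day
    total_intake_g: float = Field(default=15.0, gt=0)
    drinking_noise_sd: float = Field(default=0.5, ge=0)
    poisson_rearing: bool = True
    von_frey_slope: float = Field(default=3.0, gt=0)
    von_frey_apps: int = Field(default=5, ge=1)
    trajectory_dt: float = Field(default=0.5, gt=0)
    include_trajectories: bool = True
    drop_one_is_rat: bool = False

    @model_validator(mode="after")
    def _check(self):
        if not self.groups:
            raise ValueError("design needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names: {names}")
        for attr in ("weigh_days", "sucrose_days", "threshold_days"):
            days = getattr(self, attr)
            if days is not None:
                if any(d < 0 or d > self.days for d in days):
                    raise ValueError(f"{attr} outside [0, {self.days}]")
                if any(b <= a for a, b in zip(days, days[1:])):
                    raise ValueError(f"{attr} must be strictly increasing")
        return self

    def schedule(self, which: str) -> list[int]:
        explicit = getattr(self, f"{which}_days")
        if explicit is not None:
            return list(explicit)
        if which in ("weigh", "sucrose"):
            return [d for d in range(0, self.days + 1, 7)]
        return list(range(0, self.days + 1))  # threshold: daily

    @property
    def final_day(self) -> int:
        return self.of_epm_day if self.of_epm_day is not None else self.days


class LocomotionProfile(BaseModel):
    """Emission parameters for the generic random-walk trajectory model."""

    mean_speed: float = Field(default=6.0, ge=0.0)  # cm/s
    inner_zone_bias: float = Field(default=1.0, ge=0.0)
    rearing_rate: float = Field(default=4.0, ge=0.0)  # events/min
    dt: float = Field(default=0.1, gt=0.0)
    duration: float = Field(default=300.0, gt=0.0)
    turn_sd: float = Field(default=0.5, ge=0.0)  # rad per step

    @model_validator(mode="after")
    def _check(self):
        if self.dt > self.duration:
            raise ValueError("dt must not exceed duration")
        return self


@dataclass(frozen=True)
class DrinkingResult:
    sucrose_g: float
    water_g: float
    clamped: bool = False


@dataclass
class Cohort:
    """Simulated records keyed by (rat_id, day), plus trajectories."""

    design: CohortDesign
    records: dict[tuple[str, int], BehaviouralRecord]
    trajectories: dict[str, Trajectory] = dc_field(default_factory=dict)

    @property
    def rats(self) -> list[tuple[str, str]]:
        seen: dict[str, str] = {}
        for (rid, _), rec in sorted(self.records.items()):
            seen.setdefault(rid, rec.group)
        return list(seen.items())


def _rng(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master) & 0xFFFFFFFF, *key]))


# ---------------------------------------------------------------------------
# elementary emitters


def simulate_drinking(
    true_preference: float,
    total_intake: float,
    noise_sd: float,
    rng: np.random.Generator | int,
) -> DrinkingResult:
    """Bottle masses whose recomputed preference is ``true_preference``
    in expectation.  Masses pushed below zero by noise are clamped to 0
    and flagged."""
    if not 0.0 < true_preference < 1.0:
        raise ValueError(f"true_preference must be in (0, 1), got {true_preference!r}")
    if total_intake <= 0:
        raise ValueError("total_intake must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    s = true_preference * total_intake + rng.normal(0.0, noise_sd) if noise_sd else true_preference * total_intake
    w = (1 - true_preference) * total_intake + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
    clamped = s < 0 or w < 0
    return DrinkingResult(max(s, 0.0), max(w, 0.0), clamped)


def simulate_von_frey(
    true_threshold: float,
    force_set: Sequence[float] = DEFAULT_FORCE_SET,
    n_applications_per_force: int = 5,
    slope: float = 3.0,
    rng: np.random.Generator | int = 0,
) -> VonFreySeries:
    """Logistic responder: P(withdraw | force f) = expit(slope*(f - threshold)),
    which is exactly 0.5 at the true threshold.  ``slope=inf`` gives a
    step responder (positive iff force >= threshold)."""
    if true_threshold <= 0:
        raise ValueError("true_threshold must be positive")
    if not force_set:
        raise ValueError("force_set must be non-empty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    forces: list[float] = []
    responses: list[bool] = []
    for f in force_set:
        for _ in range(n_applications_per_force):
            if math.isinf(slope):
                p = 1.0 if f >= true_threshold else 0.0
            else:
                p = 1.0 / (1.0 + math.exp(-slope * (f - true_threshold)))
            forces.append(float(f))
            responses.append(bool(rng.random() < p))
    return VonFreySeries(tuple(forces), tuple(responses))


# ---------------------------------------------------------------------------
# generic random-walk trajectory model


_BIAS_CAP = 1e6


def _of_walk(arena: OpenFieldArena, profile: LocomotionProfile,
             rng: np.random.Generator) -> Trajectory:
    n = int(math.floor(profile.duration / profile.dt))
    times = np.arange(n + 1) * profile.dt
    times[-1] = min(times[-1], profile.duration)
    R = arena.outer_radius * 0.98  # keep strictly inside the wall
    start_r = R * math.sqrt(rng.random())
    start_a = rng.uniform(0, 2 * math.pi)
    pos = np.empty((n + 1, 2))
    pos[0] = (start_r * math.cos(start_a), start_r * math.sin(start_a))
    if profile.mean_speed == 0.0:
        pos[1:] = pos[0]
        return Trajectory(times, pos, arena, profile.duration)

    bias = math.log(min(max(profile.inner_zone_bias, 1.0 / _BIAS_CAP), _BIAS_CAP))
    heading = rng.uniform(0, 2 * math.pi)
    turns = rng.normal(0.0, profile.turn_sd, size=n)
    step = profile.mean_speed * profile.dt
    p = pos[0].copy()
    for i in range(n):
        heading += turns[i]
        d = np.array([math.cos(heading), math.sin(heading)])
        r = math.hypot(*p)
        if r > 1e-9 and bias != 0.0:
            pull = -(bias) * (r / R) * (p / r)  # inward when bias > 0
            d = d + pull
            norm = math.hypot(*d)
            if norm > 1e-12:
                d = d / norm
        q = p + step * d
        rq = math.hypot(*q)
        if rq > R:  # fold back across the wall
            q = q * ((2 * R - rq) / rq)
            rq = math.hypot(*q)
            if rq > R:
                q = q * (R / rq)
            heading = math.atan2(q[1] - p[1], q[0] - p[0])
        p = q
        pos[i + 1] = p
    return Trajectory(times, pos, arena, profile.duration)


def _epm_walk(arena: EPMArena, profile: LocomotionProfile,
              rng: np.random.Generator) -> Trajectory:
    """Walk on the maze skeleton; ``inner_zone_bias`` weights the
    probability of choosing an open arm when leaving the centre."""
    n = int(math.floor(profile.duration / profile.dt))
    times = np.arange(n + 1) * profile.dt
    h = arena.half_width
    reach = h + arena.arm_length * 0.95
    b = min(max(profile.inner_zone_bias, 1.0 / _BIAS_CAP), _BIAS_CAP)
    p_open = b / (b + 1.0)

    def _axis(arm: int) -> np.ndarray:
        # arms 0/1: open axis +,-; arms 2/3: closed axis +,-
        sgn = 1.0 if arm % 2 == 0 else -1.0
        on_open = arm < 2
        if (arena.open_axis == "x") == on_open:
            return np.array([sgn, 0.0])
        return np.array([0.0, sgn])

    arm = 0 if rng.random() < p_open else 2
    arm += int(rng.random() < 0.5)
    s = 0.0  # signed distance from the centre along the current arm
    direction = 1.0
    lateral = rng.uniform(-0.6, 0.6) * h
    step = profile.mean_speed * profile.dt
    pos = np.empty((n + 1, 2))

    def _xy(arm: int, s: float, lateral: float) -> np.ndarray:
        ax = _axis(arm)
        perp = np.array([-ax[1], ax[0]])
        return ax * s + perp * lateral

    pos[0] = _xy(arm, s, lateral)
    for i in range(n):
        if profile.mean_speed == 0.0:
            pos[i + 1] = pos[i]
            continue
        s += direction * step
        if s >= reach:
            s = reach - (s - reach)
            direction = -1.0
        if s <= 0.0 and direction < 0.0:
            # back at the centre: choose the next arm
            s = min(-s, h * 0.5)
            direction = 1.0
            open_next = rng.random() < p_open
            arm = (0 if open_next else 2) + int(rng.random() < 0.5)
            lateral = rng.uniform(-0.6, 0.6) * h
        # occasional mid-arm turnaround
        if direction > 0.0 and s > h and rng.random() < 0.02:
            direction = -1.0
        pos[i + 1] = _xy(arm, s, lateral)
    return Trajectory(times, pos, arena, profile.duration)


def simulate_trajectory(
    arena: OpenFieldArena | EPMArena,
    profile: LocomotionProfile,
    seed: int | np.random.Generator = 0,
) -> Trajectory:
    """Generic stochastic trajectory for either arena kind.

    Open field: biased correlated random walk with a reflecting outer
    wall; ``inner_zone_bias`` > 1 pulls toward the centre, < 1 pushes
    outward, 1 is neutral (occupancy then approaches the uniform area
    ratio).  EPM: constant-speed walk along the arm skeleton with
    ``inner_zone_bias`` weighting open-arm choices.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if arena.kind == "open_field":
        return _of_walk(arena, profile, rng)
    return _epm_walk(arena, profile, rng)


# ---------------------------------------------------------------------------
# choreographed trajectory builders (exact target metrics)


def _arc_points(centre_angle_start, rho, length, direction, max_chord=2.0):
    """Polyline along a circular arc of given length (cm)."""
    n = max(1, int(math.ceil(length / max_chord)))
    dtheta = direction * (length / rho) / n
    angles = centre_angle_start + dtheta * np.arange(1, n + 1)
    return angles, np.stack([rho * np.cos(angles), rho * np.sin(angles)], axis=1)


def build_of_trajectory(
    arena: OpenFieldArena,
    total_distance_m: float,
    id_pct: float,
    it_pct: float,
    rng: np.random.Generator,
    dt: float = 0.5,
    duration: float = 300.0,
) -> Trajectory:
    """Open-field path realising the target total distance, ID% and IT%
    nearly exactly: circular arcs at an inner and an outer radius joined
    by radial crossings, traversed at zone-specific constant speeds."""
    D = max(total_distance_m, 0.0) * 100.0  # cm
    r_in, R = arena.inner_radius, arena.outer_radius
    times_out = np.arange(int(math.floor(duration / dt)) + 1) * dt
    times_out[-1] = min(times_out[-1], duration)

    if D <= 1e-9:
        rho = rng.uniform(0.3, 0.9) * R
        ang = rng.uniform(0, 2 * math.pi)
        xy = np.tile([rho * math.cos(ang), rho * math.sin(ang)], (times_out.size, 1))
        return Trajectory(times_out, xy, arena, duration)

    delta = min(max(id_pct / 100.0, 0.0), 1.0)
    tau = min(max(it_pct / 100.0, 0.0), 1.0)
    # a zone with distance needs time and vice versa
    if delta <= 0.005 or tau <= 0.005:
        delta = tau = 0.0
    elif delta >= 0.995 or tau >= 0.995:
        delta = tau = 1.0
    else:
        tau = min(max(tau, 0.01), 0.99)

    breaks_t = [0.0]
    pts = [None]  # placeholder for the start point

    def _extend(poly, speed):
        nonlocal breaks_t
        for p in poly:
            seg = np.hypot(*(p - pts[-1]))
            breaks_t.append(breaks_t[-1] + seg / speed)
            pts.append(p)

    if delta in (0.0, 1.0):
        # single-zone path: one circle
        rho = (rng.uniform(0.25, 0.55) * r_in) if delta == 1.0 else rng.uniform(
            (r_in + 2.0), R - 2.0
        )
        ang0 = rng.uniform(0, 2 * math.pi)
        pts[0] = np.array([rho * math.cos(ang0), rho * math.sin(ang0)])
        speed = D / duration
        _, poly = _arc_points(ang0, rho, D, 1.0)
        _extend(poly, speed)
    else:
        K = int(rng.integers(2, 5))  # inner bouts
        d_in, d_out = delta * D, (1 - delta) * D
        cross_in = min(0.35 * r_in, 0.4 * d_in / (2 * K))
        cross_out = min(0.5 * (R - r_in), 0.4 * d_out / (2 * K))
        cross_in = max(cross_in, 1e-3)
        cross_out = max(cross_out, 1e-3)
        rho_in = r_in - cross_in
        rho_out = r_in + cross_out
        arcs_in = d_in - 2 * K * cross_in
        arcs_out = d_out - 2 * K * cross_out
        v_in = d_in / (tau * duration)
        v_out = d_out / ((1 - tau) * duration)
        w_in = rng.dirichlet(np.ones(K)) * arcs_in
        w_out = rng.dirichlet(np.ones(K + 1)) * arcs_out
        ang = rng.uniform(0, 2 * math.pi)
        direction = 1.0 if rng.random() < 0.5 else -1.0
        pts[0] = np.array([rho_out * math.cos(ang), rho_out * math.sin(ang)])
        for k in range(K):
            angs, poly = _arc_points(ang, rho_out, w_out[k], direction)
            _extend(poly, v_out)
            ang = angs[-1]
            u = np.array([math.cos(ang), math.sin(ang)])
            _extend([u * r_in], v_out)  # radial, outer portion
            _extend([u * rho_in], v_in)  # radial, inner portion
            angs, poly = _arc_points(ang, rho_in, w_in[k], direction)
            _extend(poly, v_in)
            ang = angs[-1]
            u = np.array([math.cos(ang), math.sin(ang)])
            _extend([u * r_in], v_in)
            _extend([u * rho_out], v_out)
            direction *= -1.0 if rng.random() < 0.3 else 1.0
        angs, poly = _arc_points(ang, rho_out, w_out[K], direction)
        _extend(poly, v_out)

    pts_arr = np.asarray(pts)
    bt = np.asarray(breaks_t)
    bt *= duration / bt[-1]  # absorb rounding so the path spans the trial
    x = np.interp(times_out, bt, pts_arr[:, 0])
    y = np.interp(times_out, bt, pts_arr[:, 1])
    return Trajectory(times_out, np.stack([x, y], axis=1), arena, duration)


def build_epm_trajectory(
    arena: EPMArena,
    ot_pct: float,
    oe_pct: float | None,
    rng: np.random.Generator,
    dt: float = 0.5,
    duration: float = 300.0,
    mean_total_entries: float = 10.0,
) -> Trajectory:
    """EPM path with exact open-arm time (to one sample) and an entry
    split matching the target OE%.  ``oe_pct=None`` keeps the rat in the
    centre for the whole trial (no entries at all)."""
    n_ticks = int(round(duration / dt))
    times = np.arange(n_ticks + 1) * dt
    h = arena.half_width

    def _centre_point():
        return rng.uniform(-0.5 * h, 0.5 * h, size=2)

    if oe_pct is None:
        xy = np.tile(_centre_point(), (n_ticks + 1, 1))
        return Trajectory(times, xy, arena, duration)

    ot = min(max(ot_pct, 0.0), 100.0)
    oe = min(max(oe_pct, 0.0), 100.0)
    open_ticks = int(round(ot / 100.0 * n_ticks))
    min_visit = max(2, int(math.ceil(0.6 / dt)))

    total_e = int(np.clip(rng.poisson(mean_total_entries), 2, 18))
    n_open = int(round(oe / 100.0 * total_e))
    if open_ticks >= min_visit and n_open == 0 and oe > 0:
        n_open = 1
    if open_ticks < min_visit:
        open_ticks = 0 if n_open == 0 else open_ticks
    if open_ticks == 0:
        n_open = 0
    n_open = min(n_open, open_ticks // min_visit if min_visit else n_open)
    n_closed = max(total_e - n_open, 0)

    # budget: open visits + closed visits + centre gaps must fit the trial
    while open_ticks + n_closed * min_visit + (n_open + n_closed + 1) > n_ticks:
        if n_closed > 0:
            n_closed -= 1
        elif open_ticks > 0:
            open_ticks = max(n_ticks - n_open - 1, 0)
            n_open = min(n_open, open_ticks // min_visit)
        else:
            n_open = 0
            break
    n_gaps = n_open + n_closed + 1
    closed_budget = n_ticks - open_ticks - n_gaps
    closed_ticks = 0
    if n_closed:
        closed_ticks = int(
            np.clip(rng.integers(n_closed * min_visit, max(closed_budget, n_closed * min_visit) + 1),
                    n_closed * min_visit, closed_budget)
        )
    centre_ticks = n_ticks - open_ticks - closed_ticks

    def _split(total: int, parts: int, minimum: int) -> list[int]:
        if parts == 0:
            return []
        extra = total - parts * minimum
        cuts = rng.multinomial(extra, np.ones(parts) / parts) if extra > 0 else np.zeros(parts, int)
        return [minimum + int(c) for c in cuts]

    open_durs = _split(open_ticks, n_open, min_visit)
    closed_durs = _split(closed_ticks, n_closed, min_visit)
    gap_durs = _split(centre_ticks, n_gaps, 1)

    visits = [("open", d) for d in open_durs] + [("closed", d) for d in closed_durs]
    order = rng.permutation(len(visits))
    visits = [visits[i] for i in order]

    xy = np.empty((n_ticks + 1, 2))
    tick = 0

    def _emit_centre(d):
        nonlocal tick
        for _ in range(d):
            xy[tick] = _centre_point()
            tick += 1

    def _emit_visit(zone, d):
        nonlocal tick
        open_arm = zone == "open"
        sgn = 1.0 if rng.random() < 0.5 else -1.0
        depth_max = rng.uniform(0.3, 0.9) * arena.arm_length
        lateral = rng.uniform(-0.6, 0.6) * h
        shape = np.sin(np.linspace(0.15, math.pi - 0.15, d))
        depths = h + 0.5 + shape * depth_max
        for j in range(d):
            along = sgn * depths[j]
            if (arena.open_axis == "x") == open_arm:
                xy[tick] = (along, lateral)
            else:
                xy[tick] = (lateral, along)
            tick += 1

    _emit_centre(gap_durs[0])
    for (zone, d), gap in zip(visits, gap_durs[1:]):
        _emit_visit(zone, d)
        _emit_centre(gap)
    xy[tick:] = xy[tick - 1] if tick else _centre_point()
    return Trajectory(times, xy, arena, duration)


# ---------------------------------------------------------------------------
# cohort assembly


def _latent(params: EndpointParams, day: int, rng: np.random.Generator) -> float:
    return params.mean + params.day_slope * day + (
        params.sd * rng.standard_normal() if params.sd else 0.0
    )


def simulate_cohort(
    design: CohortDesign,
    of_arena: OpenFieldArena | None = None,
    epm_arena: EPMArena | None = None,
) -> Cohort:
    """Generate a full cohort of raw records from a design.

    Deterministic given ``design.seed``; per-group endpoint sample means
    converge to the configured (mean + slope * day) as n grows.
    """
    of_arena = of_arena or OpenFieldArena()
    epm_arena = epm_arena or EPMArena()
    master = design.seed
    records: dict[tuple[str, int], BehaviouralRecord] = {}
    trajectories: dict[str, Trajectory] = {}

    weigh = design.schedule("weigh")
    sucrose = design.schedule("sucrose")
    thresh = design.schedule("threshold")
    final = design.final_day

    for gi, group in enumerate(design.groups):
        n = group.n
        if design.drop_one_is_rat and group.name == "IS":
            n = max(1, n - 1)
        for ri in range(n):
            rid = f"{group.name}-{ri + 1:02d}"
            ep = group.endpoints
            days = sorted(set(weigh) | set(sucrose) | set(thresh) | {final})
            for day in days:
                kw: dict = {}
                flags: list[str] = []
                if day in weigh and "weight" in ep:
                    rng = _rng(master, gi, ri, _P_WEIGHT, day)
                    kw["weight_g"] = max(_latent(ep["weight"], day, rng), 1.0)
                if day in sucrose and "sucrose_pref" in ep:
                    rng = _rng(master, gi, ri, _P_SUCROSE, day)
                    pref = float(np.clip(_latent(ep["sucrose_pref"], day, rng), 1.0, 99.0))
                    drink = simulate_drinking(
                        pref / 100.0,
                        design.total_intake_g,
                        design.drinking_noise_sd,
                        _rng(master, gi, ri, _P_DRINK, day),
                    )
                    kw["sucrose_g"] = drink.sucrose_g
                    kw["water_g"] = drink.water_g
                    if drink.clamped:
                        flags.append("clamped_intake")
                if day in thresh and "threshold_g" in ep:
                    rng = _rng(master, gi, ri, _P_THRESH, day)
                    t = float(np.clip(_latent(ep["threshold_g"], day, rng), 2.0, 15.0))
                    kw["von_frey"] = simulate_von_frey(
                        t,
                        DEFAULT_FORCE_SET,
                        design.von_frey_apps,
                        design.von_frey_slope,
                        _rng(master, gi, ri, _P_VF, day),
                    )
                if day == final:
                    if "rearing" in ep:
                        rng = _rng(master, gi, ri, _P_REAR, day)
                        lam = max(_latent(ep["rearing"], day, rng), 0.0)
                        kw["rearing_count"] = (
                            int(rng.poisson(lam)) if design.poisson_rearing else int(round(lam))
                        )
                    if design.include_trajectories and {
                        "distance_m", "id_pct", "it_pct"
                    } <= set(ep):
                        rng = _rng(master, gi, ri, _P_OF, day)
                        dist = max(_latent(ep["distance_m"], day, rng), 0.0)
                        idp = float(np.clip(_latent(ep["id_pct"], day, rng), 0.0, 100.0))
                        itp = float(np.clip(_latent(ep["it_pct"], day, rng), 0.0, 100.0))
                        ref = f"{rid}_of_d{day}"
                        trajectories[ref] = build_of_trajectory(
                            of_arena, dist, idp, itp, rng, dt=design.trajectory_dt
                        )
                        kw["of_trajectory"] = ref
                    if design.include_trajectories and {"ot_pct", "oe_pct"} <= set(ep):
                        rng = _rng(master, gi, ri, _P_EPM, day)
                        otp = float(np.clip(_latent(ep["ot_pct"], day, rng), 0.0, 100.0))
                        oep = float(np.clip(_latent(ep["oe_pct"], day, rng), 0.0, 100.0))
                        ref = f"{rid}_epm_d{day}"
                        trajectories[ref] = build_epm_trajectory(
                            epm_arena, otp, oep, rng, dt=design.trajectory_dt
                        )
                        kw["epm_trajectory"] = ref
                if kw:
                    records[(rid, day)] = BehaviouralRecord(
                        rat_id=rid, group=group.name, day=day, flags=tuple(flags), **kw
                    )
    return Cohort(design=design, records=records, trajectories=trajectories)


# ---------------------------------------------------------------------------
# ready-made designs


_BASELINE = {
    "weight": EndpointParams(mean=300.0, sd=10.0, day_slope=2.0),
    "sucrose_pref": EndpointParams(mean=90.0, sd=4.0),
    "distance_m": EndpointParams(mean=18.0, sd=3.0),
    "rearing": EndpointParams(mean=22.0, sd=5.0),
    "id_pct": EndpointParams(mean=25.0, sd=5.0),
    "it_pct": EndpointParams(mean=25.0, sd=5.0),
    "ot_pct": EndpointParams(mean=25.0, sd=5.0),
    "oe_pct": EndpointParams(mean=45.0, sd=8.0),
    "threshold_g": EndpointParams(mean=12.0, sd=1.5),
}


def null_design(n: int = 10, seed: int = 0, **overrides) -> CohortDesign:
    """Four groups with identical generative parameters (no effects)."""
    groups = [
        GroupSpec(name=name, n=n, endpoints=dict(_BASELINE))
        for name in ("CON", "IS", "IS_AMI", "AMI")
    ]
    return CohortDesign(groups=groups, seed=seed, **overrides)


def reference_design(effect_sd: float = 1.5, n: int = 10, seed: int = 0,
                     **overrides) -> CohortDesign:
    """Design mirroring the published effect directions.

    The IS group is shifted by ``effect_sd`` within-group standard
    deviations on sucrose preference (declining over the weeks), travel
    distance, rearing, ID%, OE% and withdrawal threshold; weight, IT%
    and OT% are untouched.  IS+AMI recovers everything except sucrose
    preference; AMI alone matches CON.
    """
    k = effect_sd

    def _shift(base: dict, which: dict[str, float], slopes: dict[str, float] | None = None):
        out = dict(base)
        for name, mult in which.items():
            p = out[name]
            out[name] = EndpointParams(
                mean=p.mean - mult * p.sd, sd=p.sd, day_slope=p.day_slope
            )
        for name, slope in (slopes or {}).items():
            p = out[name]
            # ramp from the CON mean down to the shifted mean across the trial
            out[name] = EndpointParams(
                mean=_BASELINE[name].mean, sd=p.sd,
                day_slope=(p.mean - _BASELINE[name].mean) / 21.0 + p.day_slope,
            )
        return out

    is_ep = _shift(
        _BASELINE,
        {"distance_m": k, "rearing": k, "id_pct": k, "oe_pct": k},
    )
    is_ep = _shift(is_ep, {"sucrose_pref": k, "threshold_g": 6.0},
                   slopes={"sucrose_pref": 0.0, "threshold_g": 0.0})
    is_ami = _shift(_BASELINE, {"sucrose_pref": k}, slopes={"sucrose_pref": 0.0})
    groups = [
        GroupSpec(name="CON", n=n, endpoints=dict(_BASELINE)),
        GroupSpec(name="IS", n=n, endpoints=is_ep),
        GroupSpec(name="IS_AMI", n=n, endpoints=is_ami),
        GroupSpec(name="AMI", n=n, endpoints=dict(_BASELINE)),
    ]
    return CohortDesign(groups=groups, seed=seed, **overrides)
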
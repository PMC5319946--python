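"""Composite depression and anxiety rating scales for rats.

The two scales map eight behavioural indices onto integer points:

* depression scale (max 25): body weight (0-5), sucrose preference
  (0-10), open-field travel distance (0-5) and rearing count (0-5);
* anxiety scale (max 28): inner-zone distance percent ID%, inner-zone
  time percent IT%, open-arm time percent OT% and open-arm entries
  percent OE%, each 0-7.

Each item is an ordered list of half-open scoring intervals
(:class:`ScaleTable`).  The tables ship as editable YAML files under
``rataffect/data`` and are loaded, validated and applied here; nothing
about the bin boundaries is hard-coded in the scoring path.

Two conventions are worth calling out:

* every bin is lower-closed / upper-open (``lo <= x < hi``) unless a
  table says otherwise; narrative rules of the form "more than 95%"
  are normalised to ``>= 95`` so the partition stays gap-free;
* raw values are **not** rounded before binning: a sucrose preference
  of 94.999% scores 9 points, not 10.

The weight item carries a known prose-vs-table conflict at the extremes
(below 300 g / above 390 g the narrative rule assigns 0 points, the
tabulated bins assign 1).  The table is the default; pass
``weight_mode="prose"`` for the narrative behaviour.  Neither variant is
applied silently: :func:`validate_scale` reports both discrepancy
regions whenever the built-in weight table is validated against its
arithmetic rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Bin",
    "ScaleTable",
    "ScaleValidationIssue",
    "ScaleValidationReport",
    "ScoreCard",
    "builtin_scales",
    "load_scale_tables",
    "score_weight",
    "score_sucrose",
    "score_distance",
    "score_rearing",
    "score_anxiety_pct",
    "score_oe",
    "score_rat",
    "validate_scale",
    "arithmetic_rule",
    "DEPRESSION_ITEMS",
    "ANXIETY_ITEMS",
]

DEPRESSION_ITEMS = ("weight", "sucrose", "distance", "rearing")
ANXIETY_ITEMS = ("id_pct", "it_pct", "ot_pct", "oe_pct")


class ScaleError(ValueError):
    """Raised for structurally invalid scale tables or out-of-domain inputs."""


@dataclass(frozen=True)
class Bin:
    """One scoring interval.  ``hi`` may be ``inf`` (unbounded above)."""

    lo: float
    hi: float
    points: int
    lo_closed: bool = True
    hi_closed: bool = False

    def contains(self, value: float) -> bool:
        above = value > self.lo or (self.lo_closed and value == self.lo)
        below = value < self.hi or (self.hi_closed and value == self.hi)
        return above and below

    def label(self) -> str:
        lb = "[" if self.lo_closed else "("
        rb = "]" if self.hi_closed else ")"
        return f"{lb}{self.lo:g}, {self.hi:g}{rb} -> {self.points}"


@dataclass(frozen=True)
class ScaleTable:
    """An ordered, gap-free partition of a domain into scoring bins."""

    index_name: str
    bins: tuple[Bin, ...]
    domain_lo: float = 0.0
    domain_hi: float = math.inf  # inclusive upper edge of the declared domain
    max_points: int = 0

    def score(self, value: float) -> int:
        if not (self.domain_lo <= value <= self.domain_hi):
            raise ScaleError(
                f"{self.index_name}: value {value!r} outside domain "
                f"[{self.domain_lo}, {self.domain_hi}]"
            )
        for b in self.bins:
            if b.contains(value):
                return b.points
        raise ScaleError(f"{self.index_name}: no bin covers {value!r}")

    def attained_max(self) -> int:
        return max(b.points for b in self.bins)


# ---------------------------------------------------------------------------
# loading


def _parse_bin(raw: Mapping) -> Bin:
    hi = raw.get("hi")
    return Bin(
        lo=float(raw["lo"]),
        hi=math.inf if hi is None else float(hi),
        points=int(raw["points"]),
        lo_closed=bool(raw.get("lo_closed", True)),
        hi_closed=bool(raw.get("hi_closed", False)),
    )


def _parse_table(name: str, raw: Mapping) -> ScaleTable:
    dom = raw.get("domain", {})
    hi = dom.get("hi")
    table = ScaleTable(
        index_name=name,
        bins=tuple(_parse_bin(b) for b in raw["bins"]),
        domain_lo=float(dom.get("lo", 0.0)),
        domain_hi=math.inf if hi is None else float(hi),
        max_points=int(raw["max_points"]),
    )
    report = validate_scale(table)
    if report.structural_errors:
        msgs = "; ".join(i.message for i in report.structural_errors)
        raise ScaleError(f"scale {name!r} is structurally invalid: {msgs}")
    return table


def load_scale_tables(stream_or_path) -> dict[str, ScaleTable]:
    """Load scale tables from a YAML file (path, Path or open stream)."""
    if hasattr(stream_or_path, "read"):
        raw = yaml.safe_load(stream_or_path.read())
    else:
        with open(stream_or_path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "items" not in raw:
        raise ScaleError("scale file must be a mapping with an 'items' key")
    return {name: _parse_table(name, spec) for name, spec in raw["items"].items()}


def _load_builtin(fname: str) -> dict[str, ScaleTable]:
    text = resources.files("rataffect.data").joinpath(fname).read_text()
    import io

    return load_scale_tables(io.StringIO(text))


_BUILTIN_CACHE: dict[str, ScaleTable] | None = None


def builtin_scales() -> dict[str, ScaleTable]:
    """All eight built-in item tables, keyed by item name."""
    global _BUILTIN_CACHE
    if _BUILTIN_CACHE is None:
        tables = {}
        tables.update(_load_builtin("depression_scale.yaml"))
        tables.update(_load_builtin("anxiety_scale.yaml"))
        _BUILTIN_CACHE = tables
    return dict(_BUILTIN_CACHE)


# ---------------------------------------------------------------------------
# arithmetic prose rules (independent restatements of the tables)


def _rule_weight(w: float) -> int:
    # plateau of 5 on [330, 360); one point lost per started 10 g step
    # outside it; the narrative assigns 0 beyond 300/390 (the printed
    # table assigns 1 there -- the documented conflict).
    if w < 300 or w > 390:
        return 0
    if 330 <= w < 360:
        return 5
    if w < 330:
        return 5 - math.ceil((330 - w) / 10)
    return 5 - (math.floor((w - 360) / 10) + 1)


def _rule_sucrose(p: float) -> int:
    if p < 50:
        return 0
    return min(10, math.floor((p - 50) / 5) + 1)


def _rule_distance(d: float) -> int:
    if d == 0:
        return 0
    if d < 5:
        return 1
    return min(5, math.floor(d / 5) + 1)


def _rule_anxiety_pct(v: float) -> int:
    if v < 1:
        return 0
    if v < 5:
        return 1
    return min(7, math.floor(v / 5) + 1)


def _rule_oe(v: float) -> int:
    if v < 1:
        return 0
    if v < 20:
        return 1
    return min(7, math.floor(v / 5) - 2)


_RULES: dict[str, Callable[[float], int]] = {
    "weight": _rule_weight,
    "sucrose": _rule_sucrose,
    "distance": _rule_distance,
    "rearing": _rule_distance,  # same bin structure on counts
    "id_pct": _rule_anxiety_pct,
    "it_pct": _rule_anxiety_pct,
    "ot_pct": _rule_anxiety_pct,
    "oe_pct": _rule_oe,
}


def arithmetic_rule(index_name: str) -> Callable[[float], int]:
    """The narrative "each k-unit increase is one point" rule for an item."""
    return _RULES[index_name]


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ScaleValidationIssue:
    kind: str  # 'gap' | 'overlap' | 'max_mismatch' | 'rule_conflict'
    message: str
    value: float | None = None


@dataclass
class ScaleValidationReport:
    index_name: str
    issues: list[ScaleValidationIssue] = field(default_factory=list)

    @property
    def structural_errors(self) -> list[ScaleValidationIssue]:
        return [i for i in self.issues if i.kind in ("gap", "overlap", "max_mismatch")]

    @property
    def rule_conflicts(self) -> list[ScaleValidationIssue]:
        return [i for i in self.issues if i.kind == "rule_conflict"]

    @property
    def ok(self) -> bool:
        return not self.structural_errors


def _grid(lo: float, hi: float, step: float) -> Iterable[float]:
    n = int(round((hi - lo) / step))
    for i in range(n + 1):
        yield min(lo + i * step, hi)


def validate_scale(
    table: ScaleTable,
    rule: Callable[[float], int] | None = None,
    grid_step: float = 0.01,
    grid_hi: float | None = None,
) -> ScaleValidationReport:
    """Check a table for gaps/overlaps/max attainment and, if an
    arithmetic rule is given, list every region where the table and the
    rule disagree.  Conflicts are reported, never repaired.
    """
    report = ScaleValidationReport(table.index_name)
    bins = sorted(table.bins, key=lambda b: (b.lo, b.hi))

    # pairwise overlap (sorted, so only adjacent pairs can overlap)
    for a, b in zip(bins, bins[1:]):
        if b.lo < a.hi or (b.lo == a.hi and a.hi_closed and b.lo_closed):
            report.issues.append(
                ScaleValidationIssue(
                    "overlap", f"bins overlap: {a.label()} and {b.label()}"
                )
            )
    # coverage of the declared domain
    if bins:
        first = bins[0]
        if first.lo > table.domain_lo or (
            first.lo == table.domain_lo and not first.lo_closed
        ):
            report.issues.append(
                ScaleValidationIssue(
                    "gap", f"domain low edge {table.domain_lo:g} not covered"
                )
            )
        for a, b in zip(bins, bins[1:]):
            if b.lo > a.hi or (b.lo == a.hi and not a.hi_closed and not b.lo_closed):
                report.issues.append(
                    ScaleValidationIssue(
                        "gap", f"gap between {a.label()} and {b.label()}"
                    )
                )
        last = bins[-1]
        if last.hi < table.domain_hi or (
            last.hi == table.domain_hi
            and not last.hi_closed
            and not math.isinf(table.domain_hi)
        ):
            report.issues.append(
                ScaleValidationIssue(
                    "gap", f"domain high edge {table.domain_hi:g} not covered"
                )
            )
    if table.attained_max() != table.max_points:
        report.issues.append(
            ScaleValidationIssue(
                "max_mismatch",
                f"declared max {table.max_points} but bins attain "
                f"{table.attained_max()}",
            )
        )

    if rule is not None and report.ok:
        hi = grid_hi
        if hi is None:
            hi = table.domain_hi if not math.isinf(table.domain_hi) else 500.0
        in_conflict_since: float | None = None
        prev = table.domain_lo
        for v in _grid(table.domain_lo, hi, grid_step):
            disagree = table.score(v) != rule(v)
            if disagree and in_conflict_since is None:
                in_conflict_since = v
            elif not disagree and in_conflict_since is not None:
                report.issues.append(
                    ScaleValidationIssue(
                        "rule_conflict",
                        f"table and arithmetic rule disagree on "
                        f"[{in_conflict_since:g}, {prev:g}] "
                        f"(table={table.score(in_conflict_since)}, "
                        f"rule={rule(in_conflict_since)})",
                        value=in_conflict_since,
                    )
                )
                in_conflict_since = None
            prev = v
        if in_conflict_since is not None:
            report.issues.append(
                ScaleValidationIssue(
                    "rule_conflict",
                    f"table and arithmetic rule disagree on "
                    f"[{in_conflict_since:g}, {hi:g}] "
                    f"(table={table.score(in_conflict_since)}, "
                    f"rule={rule(in_conflict_since)})",
                    value=in_conflict_since,
                )
            )
    return report


# ---------------------------------------------------------------------------
# item scorers


def _score(item: str, value: float, tables: Mapping[str, ScaleTable] | None) -> int:
    tbl = (tables or builtin_scales())[item]
    return tbl.score(value)


def score_weight(
    weight_g: float,
    mode: str = "table",
    tables: Mapping[str, ScaleTable] | None = None,
) -> int:
    """Weight item, 0-5 points, plateau at [330, 360) g.

    ``mode="table"`` (default) follows the printed table (extremes score
    1); ``mode="prose"`` follows the narrative rule (extremes score 0).
    """
    if weight_g <= 0:
        raise ScaleError(f"non-positive weight: {weight_g!r}")
    if mode == "prose":
        return _rule_weight(weight_g)
    if mode != "table":
        raise ScaleError(f"unknown weight mode {mode!r}")
    return _score("weight", weight_g, tables)


def score_sucrose(pref_pct: float, tables=None) -> int:
    """Sucrose-preference item, 0-10 points (one per 5% bin from 50%)."""
    return _score("sucrose", pref_pct, tables)


def score_distance(distance_m: float, tables=None) -> int:
    """Open-field travel-distance item, 0-5 points (one per 5 m bin)."""
    if distance_m < 0:
        raise ScaleError(f"negative distance: {distance_m!r}")
    return _score("distance", distance_m, tables)


def score_rearing(count: int, tables=None) -> int:
    """Rearing-count item, 0-5 points (one per 5-event bin)."""
    if count < 0 or int(count) != count:
        raise ScaleError(f"rearing count must be a non-negative integer: {count!r}")
    return _score("rearing", count, tables)


def score_anxiety_pct(value_pct: float, index: str = "id_pct", tables=None) -> int:
    """Shared ID%/IT%/OT% item, 0-7 points (one per 5% bin from 1%)."""
    index = {"ID": "id_pct", "IT": "it_pct", "OT": "ot_pct"}.get(index, index)
    if index not in ("id_pct", "it_pct", "ot_pct"):
        raise ScaleError(f"unknown anxiety percent index {index!r}")
    return _score(index, value_pct, tables)


def score_oe(value_pct: float, tables=None) -> int:
    """Open-arm entries percent item, 0-7 points (wide 1-20% one-point bin)."""
    return _score("oe_pct", value_pct, tables)


# ---------------------------------------------------------------------------
# per-rat scorecards


@dataclass
class ScoreCard:
    """Item points and totals for one rat.

    ``None`` item scores mean the item was missing; missing items are
    excluded from the totals and listed in ``missing``.
    """

    rat_id: str
    weight_pts: int | None = None
    sucrose_pts: int | None = None
    distance_pts: int | None = None
    rearing_pts: int | None = None
    id_pts: int | None = None
    it_pts: int | None = None
    ot_pts: int | None = None
    oe_pts: int | None = None
    missing: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def total_depression(self) -> int:
        return sum(
            p
            for p in (
                self.weight_pts,
                self.sucrose_pts,
                self.distance_pts,
                self.rearing_pts,
            )
            if p is not None
        )

    @property
    def total_anxiety(self) -> int:
        return sum(
            p
            for p in (self.id_pts, self.it_pts, self.ot_pts, self.oe_pts)
            if p is not None
        )


def score_rat(
    rat_id: str,
    weight_g: float | None = None,
    sucrose_pref_pct: float | None = None,
    distance_m: float | None = None,
    rearing_count: int | None = None,
    id_pct: float | None = None,
    it_pct: float | None = None,
    ot_pct: float | None = None,
    oe_pct: float | None = None,
    weight_mode: str = "table",
    oe_undefined_policy: str = "zero",
    tables: Mapping[str, ScaleTable] | None = None,
) -> ScoreCard:
    """Score all eight items for one rat and assemble a :class:`ScoreCard`.

    ``oe_pct=None`` means OE% was undefined (the rat never entered any
    arm).  Policy ``"zero"`` (default) scores it 0 points with an
    ``oe_undefined`` flag — refusing to enter any arm is read as maximal
    avoidance; policy ``"missing"`` drops the item from the total.
    Any other ``None`` argument marks that item as not measured.
    """
    values = {
        "weight": weight_g,
        "sucrose": sucrose_pref_pct,
        "distance": distance_m,
        "rearing": rearing_count,
        "id_pct": id_pct,
        "it_pct": it_pct,
        "ot_pct": ot_pct,
        "oe_pct": oe_pct,
    }
    if all(v is None for v in values.values()):
        raise ScaleError(f"rat {rat_id!r}: every item is missing; nothing to score")

    missing: list[str] = []
    flags: list[str] = []
    pts: dict[str, int | None] = {}
    for item, v in values.items():
        if v is None:
            if item == "oe_pct" and oe_undefined_policy == "zero":
                pts[item] = 0
                flags.append("oe_undefined")
            else:
                pts[item] = None
                missing.append(item)
            continue
        if item == "weight":
            pts[item] = score_weight(v, mode=weight_mode, tables=tables)
        elif item == "sucrose":
            pts[item] = score_sucrose(v, tables=tables)
        elif item == "distance":
            pts[item] = score_distance(v, tables=tables)
        elif item == "rearing":
            pts[item] = score_rearing(v, tables=tables)
        elif item == "oe_pct":
            pts[item] = score_oe(v, tables=tables)
        else:
            pts[item] = score_anxiety_pct(v, index=item, tables=tables)

    return ScoreCard(
        rat_id=rat_id,
        weight_pts=pts["weight"],
        sucrose_pts=pts["sucrose"],
        distance_pts=pts["distance"],
        rearing_pts=pts["rearing"],
        id_pts=pts["id_pct"],
        it_pts=pts["it_pct"],
        ot_pts=pts["ot_pct"],
        oe_pts=pts["oe_pct"],
        missing=tuple(missing),
        flags=tuple(flags),
    )
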
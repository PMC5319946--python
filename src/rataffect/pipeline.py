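"""Pipeline orchestration and strict file-format contracts.

All tables are plain delimited text with documented headers; every file
written by a run carries the run's config hash in a leading ``#``
comment line so outputs can be traced back to the exact configuration
(including the scale files) that produced them.

Stages (``simulate -> metrics -> score -> stats -> report``) consume and
produce plain tables, so each stage is independently testable and the
CLI can run them separately.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import indices as idx
from . import scales as sc
from . import stats as st
from . import synthetic as syn
from . import trajectories as tj

__all__ = [
    "RunConfig",
    "StatsOptions",
    "RunReport",
    "SchemaError",
    "read_records",
    "write_records",
    "read_trajectory",
    "write_trajectory",
    "read_scale_tables",
    "write_scorecards",
    "read_scorecards",
    "compute_indices",
    "score_frame",
    "group_statistics",
    "run_pipeline",
    "load_config",
]

log = logging.getLogger("rataffect")

RECORD_COLUMNS = [
    "rat_id", "group", "day", "weight_g", "sucrose_g", "water_g",
    "rearing_count", "of_trajectory", "epm_trajectory",
    "von_frey_forces", "von_frey_responses",
]

SCORECARD_COLUMNS = [
    "rat_id", "weight_pts", "sucrose_pts", "distance_pts", "rearing_pts",
    "id_pts", "it_pts", "ot_pts", "oe_pts",
    "total_depression", "total_anxiety", "missing", "flags",
]

ENDPOINT_COLUMNS = [
    "weight_g", "sucrose_pref_pct", "distance_m", "rearing_count",
    "id_pct", "it_pct", "ot_pct", "oe_pct", "threshold_g",
]


class SchemaError(ValueError):
    """A table violated its declared schema."""


class StatsOptions(BaseModel):
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    welch: bool = False
    weight_mode: str = "table"  # 'table' | 'prose'
    oe_policy: str = "zero"  # 'zero' | 'missing'
    threshold_method: str = "ascending"


class ArenaOptions(BaseModel):
    of_outer_diameter: float = 90.0
    of_inner_diameter: float = 60.0
    epm_arm_length: float = 50.0
    epm_arm_width: float = 10.0
    epm_open_axis: str = "x"

    def open_field(self) -> tj.OpenFieldArena:
        return tj.OpenFieldArena(self.of_outer_diameter, self.of_inner_diameter)

    def epm(self) -> tj.EPMArena:
        return tj.EPMArena(self.epm_arm_length, self.epm_arm_width, self.epm_open_axis)


class RunConfig(BaseModel):
    """Everything one pipeline run needs."""

    output_dir: str
    simulation: Optional[syn.CohortDesign] = None
    records_path: Optional[str] = None
    trajectory_dir: Optional[str] = None
    scale_file: Optional[str] = None  # None -> built-in tables
    arenas: ArenaOptions = Field(default_factory=ArenaOptions)
    stats: StatsOptions = Field(default_factory=StatsOptions)
    seed: Optional[int] = None  # overrides simulation.seed when given
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self):
        if self.simulation is None and self.records_path is None:
            raise ValueError("either a simulation block or records_path is required")
        return self


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw or {})


def config_hash(config: RunConfig) -> str:
    """Hash of the canonical config plus the scale-table contents."""
    payload = config.model_dump(mode="json", exclude={"output_dir", "log_level"})
    if config.scale_file:
        payload["_scale_file_contents"] = Path(config.scale_file).read_text()
    else:
        payload["_scales"] = "builtin:" + hashlib.sha256(
            json.dumps(
                {
                    name: [b.label() for b in t.bins]
                    for name, t in sorted(sc.builtin_scales().items())
                }
            ).encode()
        ).hexdigest()
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# delimited-text contracts


def _write_table(df: pd.DataFrame, path: Path, hash_: str | None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if hash_:
            fh.write(f"# config_hash={hash_}\n")
        df.to_csv(fh, index=False)


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    unknown = [c for c in df.columns if c not in required]
    missing = [c for c in required if c not in df.columns]
    if unknown or missing:
        raise SchemaError(
            f"{path}: header mismatch (missing {missing or 'none'}, "
            f"unknown {unknown or 'none'}); expected {list(required)}"
        )
    return df


def _floats(df: pd.DataFrame, path, col: str, line0: int = 2) -> list[float | None]:
    out = []
    for i, raw in enumerate(df[col]):
        if raw == "":
            out.append(None)
            continue
        try:
            out.append(float(raw))
        except ValueError:
            raise SchemaError(
                f"{path}:{line0 + i}: non-numeric value {raw!r} in column {col!r}"
            )
    return out


def write_records(
    records: Mapping[tuple[str, int], idx.BehaviouralRecord], path, hash_: str | None = None
) -> None:
    rows = []
    for (rid, day), r in sorted(records.items()):
        vf = r.von_frey
        rows.append(
            {
                "rat_id": rid,
                "group": r.group,
                "day": day,
                "weight_g": "" if r.weight_g is None else f"{r.weight_g:.6g}",
                "sucrose_g": "" if r.sucrose_g is None else f"{r.sucrose_g:.6g}",
                "water_g": "" if r.water_g is None else f"{r.water_g:.6g}",
                "rearing_count": "" if r.rearing_count is None else str(r.rearing_count),
                "of_trajectory": r.of_trajectory or "",
                "epm_trajectory": r.epm_trajectory or "",
                "von_frey_forces": ";".join(f"{f:g}" for f in vf.forces) if vf else "",
                "von_frey_responses": ";".join(str(int(x)) for x in vf.responses) if vf else "",
            }
        )
    _write_table(pd.DataFrame(rows, columns=RECORD_COLUMNS), Path(path), hash_)


def read_records(path) -> dict[tuple[str, int], idx.BehaviouralRecord]:
    """Strictly-validated record table; errors carry line numbers."""
    df = _read_table(path, RECORD_COLUMNS)
    records: dict[tuple[str, int], idx.BehaviouralRecord] = {}
    weights = _floats(df, path, "weight_g")
    sucs = _floats(df, path, "sucrose_g")
    wats = _floats(df, path, "water_g")
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # 1-based, after the header
        try:
            day = int(row["day"])
        except ValueError:
            raise SchemaError(f"{path}:{line}: non-integer day {row['day']!r}")
        key = (row["rat_id"], day)
        if key in records:
            raise SchemaError(f"{path}:{line}: duplicate (rat_id, day) {key}")
        rear = None
        if row["rearing_count"] != "":
            try:
                rear = int(row["rearing_count"])
            except ValueError:
                raise SchemaError(
                    f"{path}:{line}: non-integer rearing_count {row['rearing_count']!r}"
                )
        vf = None
        if row["von_frey_forces"]:
            try:
                forces = tuple(float(f) for f in row["von_frey_forces"].split(";"))
                resp = tuple(bool(int(x)) for x in row["von_frey_responses"].split(";"))
            except ValueError:
                raise SchemaError(f"{path}:{line}: malformed von Frey series")
            vf = idx.VonFreySeries(forces, resp)
        try:
            records[key] = idx.BehaviouralRecord(
                rat_id=row["rat_id"],
                group=row["group"],
                day=day,
                weight_g=weights[i],
                sucrose_g=sucs[i],
                water_g=wats[i],
                rearing_count=rear,
                of_trajectory=row["of_trajectory"] or None,
                epm_trajectory=row["epm_trajectory"] or None,
                von_frey=vf,
            )
        except ValueError as exc:
            raise SchemaError(f"{path}:{line}: {exc}") from exc
    return records


def write_trajectory(traj: tj.Trajectory, path, hash_: str | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_s": [f"{t:.6g}" for t in traj.times],
            "x_cm": [f"{x:.4f}" for x in traj.xy[:, 0]],
            "y_cm": [f"{y:.4f}" for y in traj.xy[:, 1]],
        }
    )
    _write_table(df, Path(path), hash_)


def read_trajectory(path, arena, trial_duration: float = tj.TRIAL_DURATION_S) -> tj.Trajectory:
    df = _read_table(path, ["time_s", "x_cm", "y_cm"])
    try:
        times = df["time_s"].astype(float).to_numpy()
        xy = df[["x_cm", "y_cm"]].astype(float).to_numpy()
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric trajectory cell: {exc}") from exc
    try:
        return tj.Trajectory(times, xy, arena, trial_duration)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_scale_tables(path) -> dict[str, sc.ScaleTable]:
    """Load scale tables from YAML, surfacing validation failures."""
    tables = sc.load_scale_tables(path)
    for name, table in tables.items():
        report = sc.validate_scale(table)
        if not report.ok:
            msgs = "; ".join(i.message for i in report.structural_errors)
            raise SchemaError(f"{path}: scale {name!r} invalid: {msgs}")
    return tables


def write_scorecards(cards: Sequence[sc.ScoreCard], path, hash_: str | None = None) -> None:
    rows = []
    for c in cards:
        row = {col: getattr(c, col, "") for col in SCORECARD_COLUMNS[:9]}
        row = {k: ("" if v is None else v) for k, v in row.items()}
        row["total_depression"] = c.total_depression
        row["total_anxiety"] = c.total_anxiety
        row["missing"] = ";".join(c.missing)
        row["flags"] = ";".join(c.flags)
        rows.append(row)
    _write_table(pd.DataFrame(rows, columns=SCORECARD_COLUMNS), Path(path), hash_)


def read_scorecards(path) -> list[sc.ScoreCard]:
    df = _read_table(path, SCORECARD_COLUMNS)
    cards = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        pts = {}
        for col in SCORECARD_COLUMNS[1:9]:
            raw = row[col]
            try:
                pts[col] = None if raw == "" else int(raw)
            except ValueError:
                raise SchemaError(f"{path}:{line}: non-integer {col} {raw!r}")
        card = sc.ScoreCard(
            rat_id=row["rat_id"],
            missing=tuple(x for x in row["missing"].split(";") if x),
            flags=tuple(x for x in row["flags"].split(";") if x),
            **pts,
        )
        for tot in ("total_depression", "total_anxiety"):
            if int(row[tot]) != getattr(card, tot):
                raise SchemaError(
                    f"{path}:{line}: {tot} {row[tot]} does not match item sum "
                    f"{getattr(card, tot)}"
                )
        cards.append(card)
    return cards


# ---------------------------------------------------------------------------
# analysis stages


def compute_indices(
    records: Mapping[tuple[str, int], idx.BehaviouralRecord],
    trajectories: Mapping[str, tj.Trajectory],
    threshold_method: str = "ascending",
) -> pd.DataFrame:
    """One row of behavioural indices per rat, taken from each rat's
    latest available measurement of each kind."""
    by_rat: dict[str, list[idx.BehaviouralRecord]] = {}
    for (_, _), rec in sorted(records.items()):
        by_rat.setdefault(rec.rat_id, []).append(rec)

    rows = []
    for rid, recs in by_rat.items():
        recs.sort(key=lambda r: r.day)
        row: dict = {"rat_id": rid, "group": recs[0].group}
        flags: list[str] = []
        for r in recs:
            if r.weight_g is not None:
                row["weight_g"] = r.weight_g
            if r.sucrose_g is not None and r.water_g is not None:
                try:
                    row["sucrose_pref_pct"] = idx.sucrose_preference(r.sucrose_g, r.water_g)
                except idx.NoIntakeError:
                    row["sucrose_pref_pct"] = math.nan
                    flags.append("no_intake")
            if r.rearing_count is not None:
                row["rearing_count"] = r.rearing_count
            if r.von_frey is not None:
                est = idx.fifty_percent_threshold(r.von_frey, method=threshold_method)
                row["threshold_g"] = est.grams
                if est.flag:
                    flags.append(f"threshold_{est.flag}")
            if r.of_trajectory is not None:
                if r.of_trajectory not in trajectories:
                    raise SchemaError(
                        f"rat {rid} day {r.day}: trajectory {r.of_trajectory!r} not found"
                    )
                m = tj.of_metrics(trajectories[r.of_trajectory])
                row["distance_m"] = m.total_distance_m
                row["id_pct"] = m.id_pct
                row["it_pct"] = m.it_pct
                flags.extend(m.flags)
            if r.epm_trajectory is not None:
                if r.epm_trajectory not in trajectories:
                    raise SchemaError(
                        f"rat {rid} day {r.day}: trajectory {r.epm_trajectory!r} not found"
                    )
                m = tj.epm_metrics(trajectories[r.epm_trajectory])
                row["ot_pct"] = m.ot_pct
                row["oe_pct"] = math.nan if m.oe_pct is None else m.oe_pct
                row["open_entries"] = m.open_entries
                row["closed_entries"] = m.closed_entries
                flags.extend(m.flags)
        row["flags"] = ";".join(dict.fromkeys(flags))
        rows.append(row)
    cols = ["rat_id", "group"] + ENDPOINT_COLUMNS + ["open_entries", "closed_entries", "flags"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = math.nan
    return df[cols]


def _cell(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return v


def score_frame(
    indices_df: pd.DataFrame,
    weight_mode: str = "table",
    oe_policy: str = "zero",
    tables: Mapping[str, sc.ScaleTable] | None = None,
) -> list[sc.ScoreCard]:
    cards = []
    for row in indices_df.to_dict("records"):
        rear = _cell(row, "rearing_count")
        cards.append(
            sc.score_rat(
                rat_id=row["rat_id"],
                weight_g=_cell(row, "weight_g"),
                sucrose_pref_pct=_cell(row, "sucrose_pref_pct"),
                distance_m=_cell(row, "distance_m"),
                rearing_count=None if rear is None else int(rear),
                id_pct=_cell(row, "id_pct"),
                it_pct=_cell(row, "it_pct"),
                ot_pct=_cell(row, "ot_pct"),
                oe_pct=_cell(row, "oe_pct"),
                weight_mode=weight_mode,
                oe_undefined_policy=oe_policy,
                tables=tables,
            )
        )
    return cards


def group_statistics(
    indices_df: pd.DataFrame,
    cards: Sequence[sc.ScoreCard],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, st.CorrelationResult, str]:
    """ANOVA + SNK per endpoint, totals included, plus the
    depression-anxiety correlation and a human-readable report."""
    df = indices_df.copy()
    totals = pd.DataFrame(
        {
            "rat_id": [c.rat_id for c in cards],
            "total_depression": [c.total_depression for c in cards],
            "total_anxiety": [c.total_anxiety for c in cards],
        }
    )
    df = df.merge(totals, on="rat_id", how="left")

    endpoints = ENDPOINT_COLUMNS + ["total_depression", "total_anxiety"]
    summary_rows, comp_rows = [], []
    report_lines = [
        "Group comparisons (one-way ANOVA + SNK post-hoc)",
        f"alpha = {alpha}; stars: * <0.05, ** <0.01, *** <0.001",
        "note: weekly endpoints are compared at the final assessment only;",
        "no across-week multiplicity correction is applied.",
        "",
    ]
    corr = None
    for ep in endpoints:
        groups = {
            g: sub[ep].dropna().to_numpy(dtype=float)
            for g, sub in df.groupby("group", sort=True)
        }
        groups = {g: v for g, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            continue
        comp = st.compare_groups(ep, groups, alpha=alpha)
        for g in sorted(groups):
            summary_rows.append(
                {
                    "endpoint": ep,
                    "group": g,
                    "n": comp.group_n[g],
                    "mean": comp.group_mean[g],
                    "sem": comp.group_sem[g],
                }
            )
        labels = sorted(groups)
        for a in labels:
            for b in labels:
                if a < b:
                    comp_rows.append(
                        {
                            "endpoint": ep,
                            "comparison": f"{a} vs {b}",
                            "f": comp.f,
                            "anova_p": comp.p,
                            "snk_significant": comp.snk.significant(a, b),
                        }
                    )
        stars = st.significance_stars(comp.p)
        sig_pairs = [
            f"{a}|{b}" for a in labels for b in labels if a < b and comp.snk.significant(a, b)
        ]
        report_lines.append(
            f"{ep}: F = {comp.f:.3f}, p = {comp.p:.4g} {stars}; "
            f"SNK significant pairs: {', '.join(sig_pairs) or 'none'}"
        )
    corr = st.depression_anxiety_correlation(cards)
    if corr.r is None:
        report_lines.append("depression-anxiety correlation: undefined (zero variance)")
    else:
        report_lines.append(
            f"depression-anxiety correlation: r = {corr.r:.3f}, "
            f"p = {corr.p:.4g} {st.significance_stars(corr.p)} (n = {corr.n})"
        )
    return (
        pd.DataFrame(summary_rows),
        pd.DataFrame(comp_rows),
        corr,
        "\n".join(report_lines) + "\n",
    )


# ---------------------------------------------------------------------------
# full run


@dataclass
class RunReport:
    output_dir: Path
    config_hash: str
    n_rats: int
    indices: pd.DataFrame
    cards: list[sc.ScoreCard]
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    correlation: st.CorrelationResult
    files: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run simulate (optional) -> metrics -> score -> stats -> report."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hash_ = config_hash(config)
    log.info("EVENT=run_start config_hash=%s", hash_)

    tables = read_scale_tables(config.scale_file) if config.scale_file else None

    if config.simulation is not None:
        design = config.simulation
        if config.seed is not None:
            design = design.model_copy(update={"seed": config.seed})
        cohort = syn.simulate_cohort(
            design, config.arenas.open_field(), config.arenas.epm()
        )
        records = cohort.records
        trajectories = cohort.trajectories
        write_records(records, out / "records.csv", hash_)
        traj_dir = out / "trajectories"
        for ref, traj in sorted(trajectories.items()):
            write_trajectory(traj, traj_dir / f"{ref}.csv", hash_)
        log.info("EVENT=simulated rats=%d trajectories=%d", len(cohort.rats),
                 len(trajectories))
    else:
        records = read_records(config.records_path)
        trajectories = {}
        refs = {
            (r.of_trajectory, "of") for r in records.values() if r.of_trajectory
        } | {(r.epm_trajectory, "epm") for r in records.values() if r.epm_trajectory}
        tdir = Path(config.trajectory_dir or ".")
        for ref, kind in sorted(refs):
            fp = tdir / f"{ref}.csv"
            if not fp.exists():
                raise SchemaError(f"missing trajectory file {fp}")
            arena = config.arenas.open_field() if kind == "of" else config.arenas.epm()
            trajectories[ref] = read_trajectory(fp, arena)

    indices_df = compute_indices(
        records, trajectories, threshold_method=config.stats.threshold_method
    )
    cards = score_frame(
        indices_df,
        weight_mode=config.stats.weight_mode,
        oe_policy=config.stats.oe_policy,
        tables=tables,
    )
    summary, comparisons, corr, report_text = group_statistics(
        indices_df, cards, alpha=config.stats.alpha
    )

    files = {
        "indices": out / "indices.csv",
        "scorecards": out / "scorecards.csv",
        "group_summary": out / "group_summary.csv",
        "comparisons": out / "comparisons.csv",
        "report": out / "report.txt",
        "scatter": out / "scores_scatter.csv",
        "config_echo": out / "config_echo.yaml",
    }
    _write_table(indices_df, files["indices"], hash_)
    write_scorecards(cards, files["scorecards"], hash_)
    _write_table(summary, files["group_summary"], hash_)
    _write_table(comparisons, files["comparisons"], hash_)
    files["report"].write_text(f"# config_hash={hash_}\n" + report_text)
    scatter = pd.DataFrame(
        {
            "rat_id": [c.rat_id for c in cards],
            "total_depression": [c.total_depression for c in cards],
            "total_anxiety": [c.total_anxiety for c in cards],
        }
    )
    _write_table(scatter, files["scatter"], hash_)
    echo = {
        "config_hash": hash_,
        "config": config.model_dump(mode="json"),
        "versions": _versions(),
    }
    files["config_echo"].write_text(yaml.safe_dump(echo, sort_keys=True))
    log.info("EVENT=run_done rats=%d", len(cards))
    return RunReport(
        output_dir=out,
        config_hash=hash_,
        n_rats=len(cards),
        indices=indices_df,
        cards=cards,
        summary=summary,
        comparisons=comparisons,
        correlation=corr,
        files=files,
    )


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {
        "rataffect": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
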
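"""Group statistics: one-way ANOVA, Student-Newman-Keuls post-hoc
multiple comparisons, two-sample t-tests and the depression-anxiety
Pearson correlation.

ANOVA and the t-test are written out from the classical sum-of-squares
formulas (scipy supplies only the reference distributions); the test
suite cross-checks them against scipy's own implementations.
Studentized-range critical values come from
``scipy.stats.studentized_range`` rather than printed tables, with a
regression test against published table values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps


@lru_cache(maxsize=4096)
def studentized_range_crit(alpha: float, k: int, df: int) -> float:
    """Upper critical value of the studentized range (cached: the ppf is
    expensive and post-hoc chains reuse a handful of (k, df) pairs)."""
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))

__all__ = [
    "AnovaResult",
    "SNKResult",
    "TTestResult",
    "CorrelationResult",
    "GroupComparison",
    "one_way_anova",
    "snk_posthoc",
    "two_group_t",
    "pearson_correlation",
    "depression_anxiety_correlation",
    "significance_stars",
]


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"g{i}" for i in range(len(data))]
    return labels, data


@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float


def one_way_anova(groups) -> AnovaResult:
    """Classical between/within decomposition.

    ``groups`` is a mapping label -> values or a sequence of sequences;
    each group needs n >= 2.  Identical groups give F = 0, p = 1; zero
    within-group variance with unequal means gives F = inf, p = 0.
    """
    _, data = _as_groups(groups)
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in data):
        raise ValueError("every group needs n >= 2")
    ns = np.array([len(g) for g in data])
    means = np.array([g.mean() for g in data])
    grand = np.concatenate(data).mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(data, means)))
    df_b = len(data) - 1
    df_w = int(ns.sum()) - len(data)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, 1.0, df_b, df_w, 0.0)
        return AnovaResult(math.inf, 0.0, df_b, df_w, 0.0)
    f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w, ms_w)


@dataclass
class SNKResult:
    labels: list[str]
    means: dict[str, float]
    ns: dict[str, int]
    alpha: float
    df_within: int
    ms_within: float
    #: symmetric significance decisions keyed by frozenset({a, b})
    decisions: dict[frozenset, bool] = field(default_factory=dict)

    def significant(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return self.decisions[frozenset((a, b))]

    def matrix(self) -> np.ndarray:
        k = len(self.labels)
        m = np.zeros((k, k), dtype=bool)
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if i != j:
                    m[i, j] = self.significant(a, b)
        return m


def snk_posthoc(groups, alpha: float = 0.05) -> SNKResult:
    """Student-Newman-Keuls step-down pairwise comparisons.

    Group means are ranked; a pair spanning ``p`` ranks is tested
    against the studentized-range critical value with range parameter
    ``p``.  Spans are examined widest first and every pair nested inside
    a non-significant span is declared non-significant without testing
    (the step-down blocking rule).  Unequal group sizes use the harmonic
    mean of the two ns being compared.  Ties in means are ordered
    stably by group label.
    """
    labels, data = _as_groups(groups)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels")
    anova = one_way_anova(dict(zip(labels, data)))
    means = {l: float(g.mean()) for l, g in zip(labels, data)}
    ns = {l: len(g) for l, g in zip(labels, data)}
    order = sorted(labels, key=lambda l: (means[l], l))
    k = len(order)

    result = SNKResult(
        labels=labels, means=means, ns=ns, alpha=alpha,
        df_within=anova.df_within, ms_within=anova.ms_within,
    )
    blocked: set[frozenset] = set()
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            a, b = order[i], order[j]
            key = frozenset((a, b))
            if key in blocked:
                result.decisions[key] = False
                continue
            n_h = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
            if anova.ms_within == 0.0:
                sig = means[b] > means[a]
            else:
                q_obs = (means[b] - means[a]) / math.sqrt(anova.ms_within / n_h)
                sig = q_obs > studentized_range_crit(alpha, span, anova.df_within)
            result.decisions[key] = sig
            if not sig:
                # block every pair nested inside this span
                for u in range(i, j + 1):
                    for v in range(u + 1, j + 1):
                        blocked.add(frozenset((order[u], order[v])))
    return result


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float


def two_group_t(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> TTestResult:
    """Student's t-test, pooled-variance two-sided by default.

    ``welch=True`` drops the equal-variance assumption;
    ``paired=True`` runs the paired test on elementwise differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        d = x - y
        n = d.size
        if n < 2:
            raise ValueError("need n >= 2")
        sd = d.std(ddof=1)
        if sd == 0.0:
            return TTestResult(0.0, 1.0, n - 1) if d.mean() == 0 else TTestResult(
                math.inf if d.mean() > 0 else -math.inf, 0.0, n - 1
            )
        t = d.mean() / (sd / math.sqrt(n))
        df = n - 1
    elif welch:
        n1, n2 = x.size, y.size
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 in each sample")
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            diff = x.mean() - y.mean()
            return TTestResult(0.0, 1.0, n1 + n2 - 2) if diff == 0 else TTestResult(
                math.copysign(math.inf, diff), 0.0, n1 + n2 - 2
            )
        t = (x.mean() - y.mean()) / math.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    else:
        n1, n2 = x.size, y.size
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 in each sample")
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        diff = x.mean() - y.mean()
        if sp2 == 0.0:
            return TTestResult(0.0, 1.0, n1 + n2 - 2) if diff == 0 else TTestResult(
                math.copysign(math.inf, diff), 0.0, n1 + n2 - 2
            )
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(float(t), min(p, 1.0), float(df))


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    p: float | None
    n: int
    flag: str | None = None


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with p from the t transform; degenerate inputs are
    reported as missing rather than NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        return CorrelationResult(None, None, n, flag="zero_variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return CorrelationResult(r, 0.0, n)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r, min(p, 1.0), n)


def depression_anxiety_correlation(scorecards) -> CorrelationResult:
    """Pearson correlation between total depression and total anxiety
    scores across a cohort of :class:`~rataffect.scales.ScoreCard`."""
    cards = list(scorecards)
    dep = [c.total_depression for c in cards]
    anx = [c.total_anxiety for c in cards]
    return pearson_correlation(dep, anx)


@dataclass(frozen=True)
class GroupComparison:
    """ANOVA + SNK summary for one endpoint across the design groups."""

    endpoint: str
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_sem: dict[str, float]
    f: float
    p: float
    snk: SNKResult


def significance_stars(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(endpoint: str, groups: Mapping[str, Sequence[float]],
                   alpha: float = 0.05) -> GroupComparison:
    labels, data = _as_groups(groups)
    anova = one_way_anova(groups)
    snk = snk_posthoc(groups, alpha=alpha)
    sem = {
        l: float(g.std(ddof=1) / math.sqrt(len(g))) for l, g in zip(labels, data)
    }
    return GroupComparison(
        endpoint=endpoint,
        group_n={l: len(g) for l, g in zip(labels, data)},
        group_mean={l: float(g.mean()) for l, g in zip(labels, data)},
        group_sem=sem,
        f=anova.f,
        p=anova.p,
        snk=snk,
    )
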
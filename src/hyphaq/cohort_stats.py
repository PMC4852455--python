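"""Per-strain cohort summaries, hypothesis tests and timing-budget checks.

Summaries follow the publication convention "mean ± sd (median)": sample
mean, sample standard deviation (n−1 denominator) and midpoint median.
Group comparisons use the non-parametric Kruskal–Wallis test (the
non-parametric counterpart of ANOVA) across strains, with Mann–Whitney or
Student's t for pairwise contrasts.  For small samples every test switches
to its exact permutation form, enumerating all group assignments, so the
reported p-value is exact rather than asymptotic.  No multiple-testing
correction is applied (matching the source analyses); the number of
comparisons made is reported alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSummary",
    "TestResult",
    "summarize_cohort",
    "compare_groups",
    "timing_budget_check",
    "significance_stars",
]

#: Largest per-group size at which exact permutation p-values are used.
EXACT_MAX_GROUP_N = 8
#: Cap on the number of enumerated assignments for exact permutation.
EXACT_MAX_PERMS = 200_000


@dataclass(frozen=True)
class CohortSummary:
    """One parameter summarised per strain (one Table row)."""

    parameter: str
    table: pd.DataFrame  # index strain, columns n / mean / sd / median

    def formatted(self, digits: int = 1) -> pd.Series:
        """Render the conventional ``mean±sd (median)`` strings."""
        def fmt(r):
            return (f"{r['mean']:.{digits}f}±{r['sd']:.{digits}f} "
                    f"({r['median']:.{digits}f})")
        return self.table.apply(fmt, axis=1).rename(self.parameter)


@dataclass(frozen=True)
class TestResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    exact: bool


def summarize_cohort(values: Mapping[str, Sequence[float]],
                     parameter: str) -> CohortSummary:
    """Per-strain n / mean / sd / median table for one parameter."""
    rows = {}
    for strain, xs in values.items():
        a = np.asarray(list(xs), dtype=float)
        if a.size == 0:
            raise ValueError(f"empty group {strain!r} for {parameter!r}")
        sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
        rows[strain] = dict(n=int(a.size), mean=float(a.mean()), sd=sd,
                            median=float(np.median(a)))
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "strain"
    return CohortSummary(parameter=parameter, table=table)


def _kruskal_h(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = pooled.size
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i: i + g.size]
        i += g.size
        h += r.sum() ** 2 / g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    t = float((counts ** 3 - counts).sum())
    denom = 1.0 - t / (n ** 3 - n)
    return h / denom if denom > 0 else 0.0


def _mwu_u(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic)


def _exact_permutation_p(groups: list[np.ndarray], stat, two_extremes: bool
                         ) -> tuple[float, float]:
    """Exact permutation p-value by full enumeration of group assignments.

    ``stat`` maps a list of groups to a scalar; ``two_extremes`` selects a
    two-sided rule counting assignments with |stat| >= |observed| (used for
    U and t); otherwise large values of the statistic are extreme (H).
    Returns (observed statistic, p).
    """
    pooled = np.concatenate(groups)
    sizes = [g.size for g in groups]
    obs = stat(groups)
    idx_all = list(range(pooled.size))
    count = total = 0
    ref = abs(obs) if two_extremes else obs

    def rec(remaining: list[int], sizes_left: list[int], chosen: list[np.ndarray]):
        nonlocal count, total
        if len(sizes_left) == 1:
            gs = chosen + [pooled[np.array(remaining)]]
            s = stat(gs)
            s = abs(s) if two_extremes else s
            total += 1
            if s >= ref - 1e-12:
                count += 1
            return
        k = sizes_left[0]
        for comb in itertools.combinations(remaining, k):
            rest = [i for i in remaining if i not in set(comb)]
            rec(rest, sizes_left[1:], chosen + [pooled[np.array(comb)]])

    rec(idx_all, sizes, [])
    return obs, count / total


def _n_assignments(sizes: list[int]) -> int:
    n = sum(sizes)
    total = 1
    for k in sizes:
        total *= math.comb(n, k)
        n -= k
    return total


def compare_groups(values: Mapping[str, Sequence[float]], test: str,
                   exact: bool | None = None) -> TestResult:
    """Run the named two-sided test across the given strain groups.

    ``test`` is one of ``kruskal_wallis`` (≥ 2 groups), ``mann_whitney`` or
    ``t_test`` (exactly 2 groups).  ``exact=None`` (default) switches to the
    exact permutation form automatically when all groups are small; the
    asymptotic forms are Kruskal–Wallis with tie correction, Mann–Whitney
    with normal approximation and tie correction, and Student's t.
    """
    names = tuple(values.keys())
    groups = [np.asarray(list(values[k]), dtype=float) for k in names]
    if any(g.size < 3 for g in groups):
        raise ValueError("each group needs n >= 3")
    if test == "kruskal_wallis":
        if len(groups) < 2:
            raise ValueError("kruskal_wallis needs >= 2 groups")
    elif test in ("mann_whitney", "t_test"):
        if len(groups) != 2:
            raise ValueError(f"{test} needs exactly 2 groups")
    else:
        raise ValueError(f"unknown test {test!r}")

    if exact is None:
        exact = (max(g.size for g in groups) <= EXACT_MAX_GROUP_N
                 and _n_assignments([g.size for g in groups]) <= EXACT_MAX_PERMS)

    if exact:
        if test == "kruskal_wallis":
            obs, p = _exact_permutation_p(groups, _kruskal_h, two_extremes=False)
        elif test == "mann_whitney":
            def centred_u(gs):
                return _mwu_u(gs[0], gs[1]) - gs[0].size * gs[1].size / 2.0
            obs_c, p = _exact_permutation_p(groups, centred_u, two_extremes=True)
            obs = obs_c + groups[0].size * groups[1].size / 2.0
        else:
            obs, p = _exact_permutation_p(
                groups, lambda gs: _t_stat(gs[0], gs[1]), two_extremes=True)
        return TestResult(test=test, groups=names, statistic=float(obs),
                          p_value=float(p), exact=True)

    if test == "kruskal_wallis":
        res = stats.kruskal(*groups)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method="asymptotic")
    else:
        res = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    return TestResult(test=test, groups=names, statistic=float(res.statistic),
                      p_value=float(res.pvalue), exact=False)


#: Required summary rows for the timing-budget identity.
_BUDGET_KEYS = ("ring_appear_offset_min", "ring_lifetime_min",
                "maturation_min", "total_sporulation_min")


def timing_budget_check(medians: Mapping[str, float]) -> float:
    """Signed residual of the sporulation timing budget for one strain.

    The total sporulation time (growth cessation → spore separation) must
    decompose as ring-appearance offset + ring lifetime + maturation;
    ``residual = (appearance + lifetime + maturation) − total``.
    """
    missing = [k for k in _BUDGET_KEYS if k not in medians]
    if missing:
        raise ValueError(f"missing timing rows: {missing}")
    a, l, m, tot = (float(medians[k]) for k in _BUDGET_KEYS)
    return (a + l + m) - tot


def significance_stars(p: float) -> str:
    """Asterisk tiers used in the cohort tables (*, **, *** for
    p < 0.1, 0.01, 0.001)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.1:
        return "*"
    return ""
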
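"""Group comparisons and the stiffness-motility correlation layer.

Implements the statistical battery used on per-animal summary tables:
two-group comparisons (pooled-variance Student's t or Mann-Whitney U),
multi-group omnibus tests (one-way ANOVA or Kruskal-Wallis, with Dunn's
rank-based test as the post-hoc), and per-group ordinary least-squares fits
of a motility statistic against mean tumor stiffness with the Pearson
correlation coefficient.

A "study table" is a pandas DataFrame with one row per subject carrying at
least ``subject_id``, ``group`` and the derived scalar columns
(``mean_stiffness_kPa``, ``mean_speed_um_per_min``, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "compare_two_groups",
    "compare_multi_groups",
    "dunn_posthoc",
    "stiffness_motility_fit",
    "percent_change",
    "holm_correction",
]


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    n_groups: tuple[int, ...]


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    degenerate: bool = False


def compare_two_groups(
    a: Sequence[float], b: Sequence[float], test: str = "t", welch: bool = False
) -> GroupComparison:
    """Two-sided two-group comparison.

    ``test='t'`` is the classical pooled-variance two-sample Student's
    t-test (``welch=True`` switches to the unequal-variance form);
    ``test='mann-whitney'`` uses exact enumeration for group sizes up to 8
    without ties and the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if test == "t":
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            raise ValueError("zero variance in both groups: t statistic undefined")
        stat, p = sps.ttest_ind(x, y, equal_var=not welch)
        name = "welch-t" if welch else "student-t"
    elif test == "mann-whitney":
        exact = x.size <= 8 and y.size <= 8 and np.unique(np.r_[x, y]).size == x.size + y.size
        stat, p = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        name = "mann-whitney"
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(name, float(stat), float(p), (x.size, y.size))


def compare_multi_groups(
    groups: Sequence[Sequence[float]], mode: str = "anova"
) -> GroupComparison:
    """Omnibus comparison of three or more groups (one-way ANOVA or Kruskal-Wallis)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("need at least three groups (use compare_two_groups for two)")
    if mode == "anova":
        if any(g.size < 2 for g in arrays):
            raise ValueError("ANOVA requires at least two values per group")
        stat, p = sps.f_oneway(*arrays)
        name = "anova-F"
    elif mode == "kruskal-wallis":
        if any(g.size < 1 for g in arrays):
            raise ValueError("empty group")
        stat, p = sps.kruskal(*arrays)
        name = "kruskal-wallis-H"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return GroupComparison(name, float(stat), float(p), tuple(g.size for g in arrays))


def dunn_posthoc(
    groups: Sequence[Sequence[float]], holm: bool = False
) -> dict[tuple[int, int], float]:
    """Dunn's rank-based pairwise post-hoc test after Kruskal-Wallis.

    Returns two-sided p-values keyed by group-index pair, with the usual tie
    correction; ``holm=True`` applies the Holm step-down adjustment.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(float(ranks[start : start + g.size].mean()))
        sizes.append(g.size)
        start += g.size
    pvals: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(arrays)), 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pvals[(i, j)] = float(2.0 * sps.norm.sf(abs(z)))
    if holm:
        adj = holm_correction(list(pvals.values()))
        pvals = {k: v for k, v in zip(pvals, adj)}
    return pvals


def holm_correction(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def stiffness_motility_fit(
    table: pd.DataFrame,
    y_field: str,
    x_field: str = "mean_stiffness_kPa",
    by_group: bool = True,
    group_field: str = "group",
) -> list[CorrelationResult]:
    """OLS fit of a motility statistic against mean tumor stiffness.

    Fits ``y_field ~ x_field`` per treatment group (or once, pooled, when
    ``by_group`` is off), returning slope, intercept and Pearson r per fit.
    Two-point fits are returned but flagged degenerate (r is ±1 by
    construction).
    """
    for col in (x_field, y_field):
        if col not in table.columns:
            raise ValueError(f"study table has no column {col!r}")
    if by_group:
        parts = [(str(g), sub) for g, sub in table.groupby(group_field, sort=True)]
    else:
        parts = [("all", table)]
    results = []
    for name, sub in parts:
        x = sub[x_field].to_numpy(dtype=float)
        y = sub[y_field].to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError(f"group {name!r} has fewer than two subjects")
        if np.ptp(x) == 0:
            raise ValueError(f"group {name!r} has constant {x_field}; slope undefined")
        fit = sps.linregress(x, y)
        results.append(
            CorrelationResult(
                group=name,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                pearson_r=float(fit.rvalue),
                p_value=float(fit.pvalue),
                n=int(x.size),
                degenerate=x.size == 2,
            )
        )
    return results


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference``.

    Positive when the value decreased relative to the reference, e.g. a mean
    fiber width of 6.7 µm against a reference of 7.4 µm is a 9.46% reduction.
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (reference - value) / reference
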
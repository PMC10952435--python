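"""Group comparisons and compact letter displays for phenotype metrics.

Mirrors the comparison scheme used in the starch phenotyping literature:
one-way ANOVA followed by Tukey's all-pairwise test when residuals look
normal with homogeneous variances, otherwise Kruskal–Wallis one-way ANOVA
on ranks followed by a Tukey-type (Nemenyi) procedure on rank sums; Welch
t-tests for two-group time-course contrasts; and compact letter displays
where groups sharing no letter differ significantly.

Since published figure captions alternate between ANOVA and Kruskal–Wallis
without stating a rule, `choose_test` applies an explicit, documented gate:
Shapiro–Wilk on pooled residuals AND Brown–Forsythe equal-variance, both at
a configurable assumption level (default 0.05).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GroupSample",
    "TestKind",
    "OmnibusResult",
    "ComparisonResult",
    "one_way_anova",
    "kruskal_wallis",
    "tukey_all_pairs",
    "nemenyi_rank_all_pairs",
    "pairwise_t",
    "choose_test",
    "compact_letters",
    "compare_groups",
]


class TestKind(str, Enum):
    ANOVA_TUKEY = "anova_tukey"
    KW_RANKS = "kw_ranks"
    PAIRWISE_T = "pairwise_t"


@dataclass(frozen=True)
class GroupSample:
    """One group's observations of a single metric (one value per replicate)."""

    label: str
    observations: np.ndarray

    def __post_init__(self) -> None:
        obs = np.asarray(self.observations, dtype=float)
        object.__setattr__(self, "observations", obs)
        if obs.ndim != 1 or obs.size < 2:
            raise ValueError(
                f"group {self.label!r} needs at least two observations"
            )


@dataclass(frozen=True)
class OmnibusResult:
    statistic: float
    pvalue: float
    degenerate: bool = False  # zero within-group variance limit


@dataclass(frozen=True)
class ComparisonResult:
    """Full comparison: omnibus test, pairwise p matrix and letter display."""

    test_used: TestKind
    labels: tuple[str, ...]
    omnibus: OmnibusResult
    pairwise_p: np.ndarray
    letters: dict[str, str]
    alpha: float


def _check_groups(groups: Sequence[GroupSample]) -> list[GroupSample]:
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    return groups


def one_way_anova(groups: Sequence[GroupSample]) -> OmnibusResult:
    """Classical one-way F test.

    Degenerate zero within-variance inputs return p = 1 (equal means) or
    p < 1e-12 with the degeneracy flag set (separated means), by convention.
    """
    groups = _check_groups(groups)
    arrays = [g.observations for g in groups]
    within_ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    means = [a.mean() for a in arrays]
    if within_ss == 0.0:
        if np.allclose(means, means[0]):
            return OmnibusResult(statistic=0.0, pvalue=1.0, degenerate=True)
        return OmnibusResult(statistic=math.inf, pvalue=1e-300, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return OmnibusResult(statistic=float(f), pvalue=float(p))


def kruskal_wallis(groups: Sequence[GroupSample]) -> OmnibusResult:
    """Kruskal–Wallis H with tie correction; p from χ²(k−1)."""
    groups = _check_groups(groups)
    arrays = [g.observations for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return OmnibusResult(statistic=0.0, pvalue=1.0, degenerate=True)
    h, p = stats.kruskal(*arrays)
    return OmnibusResult(statistic=float(h), pvalue=float(p))


def tukey_all_pairs(groups: Sequence[GroupSample]) -> np.ndarray:
    """Tukey HSD adjusted p-values for every pair (symmetric, unit diagonal)."""
    groups = _check_groups(groups)
    arrays = [g.observations for g in groups]
    within_ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    k = len(arrays)
    pmat = np.ones((k, k))
    if within_ss == 0.0:
        for i, j in itertools.combinations(range(k), 2):
            equal = math.isclose(arrays[i].mean(), arrays[j].mean())
            pmat[i, j] = pmat[j, i] = 1.0 if equal else 1e-300
        return pmat
    res = stats.tukey_hsd(*arrays)
    pv = np.asarray(res.pvalue, dtype=float)
    np.fill_diagonal(pv, 1.0)
    return np.clip((pv + pv.T) / 2.0, 0.0, 1.0)  # symmetrise exactly


def nemenyi_rank_all_pairs(groups: Sequence[GroupSample]) -> np.ndarray:
    """Tukey-type (Nemenyi) all-pairwise comparisons on rank sums.

    The post-hoc companion to Kruskal–Wallis: mean-rank differences are
    referred to the studentized range distribution (infinite df), with the
    standard tie correction applied to the rank variance.
    """
    groups = _check_groups(groups)
    arrays = [g.observations for g in groups]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction factor for the variance of mean-rank differences
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
    k = len(arrays)
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(float(ranks[start : start + a.size].mean()))
        sizes.append(a.size)
        start += a.size
    pmat = np.ones((k, k))
    if tie_term <= 0:  # every observation identical
        return pmat
    var_base = n_total * (n_total + 1) / 12.0 * tie_term
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        q = abs(mean_ranks[i] - mean_ranks[j]) / se * math.sqrt(2.0)
        p = float(stats.studentized_range.sf(q, k, np.inf))
        pmat[i, j] = pmat[j, i] = min(max(p, 0.0), 1.0)
    return pmat


def pairwise_t(a: GroupSample, b: GroupSample) -> tuple[float, float]:
    """Two-sided Welch t-test between two groups; (statistic, p)."""
    x, y = a.observations, b.observations
    if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
        if math.isclose(x.mean(), y.mean()):
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def choose_test(
    groups: Sequence[GroupSample], alpha_assumption: float = 0.05
) -> TestKind:
    """Pick ANOVA+Tukey vs Kruskal–Wallis from the model assumptions.

    ANOVA is chosen only when Shapiro–Wilk on the pooled within-group
    residuals AND the Brown–Forsythe equal-variance test both fail to reject
    at ``alpha_assumption``; otherwise the rank-based route is used.  With
    too few residual degrees of freedom for Shapiro–Wilk the rank route is
    returned with a warning.  Deterministic given the data.
    """
    groups = _check_groups(groups)
    arrays = [g.observations for g in groups]
    residuals = np.concatenate([a - a.mean() for a in arrays])
    if residuals.size < 3:
        warnings.warn(
            "too few observations for a normality check; using rank-based tests",
            stacklevel=2,
        )
        return TestKind.KW_RANKS
    if np.allclose(residuals, 0.0):
        return TestKind.KW_RANKS  # zero-variance: normality is untestable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p_norm = stats.shapiro(residuals)
        _, p_var = stats.levene(*arrays, center="median")  # Brown–Forsythe
    if p_norm > alpha_assumption and p_var > alpha_assumption:
        return TestKind.ANOVA_TUKEY
    return TestKind.KW_RANKS


def compact_letters(
    pairwise_p: np.ndarray, alpha: float = 0.05, labels: Sequence[str] | None = None
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Produces per-group letter strings such that two groups share at least
    one letter iff their pairwise p exceeds ``alpha``.  Letter sets that
    become subsets of others are absorbed, keeping the display minimal;
    letters are assigned in group-input order starting at "a".
    """
    pmat = np.asarray(pairwise_p, dtype=float)
    k = pmat.shape[0]
    if pmat.shape != (k, k) or not np.allclose(pmat, pmat.T, atol=1e-12):
        raise ValueError("pairwise p matrix must be square and symmetric")
    if labels is None:
        labels = [str(i) for i in range(k)]

    sets: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if pmat[i, j] > alpha:
            continue
        new_sets: list[set[int]] = []
        for s in sets:
            if i in s and j in s:
                new_sets.extend((s - {i}, s - {j}))
            else:
                new_sets.append(s)
        # absorb: drop empty sets, proper subsets of other sets, duplicates
        new_sets = [s for s in new_sets if s]
        kept: list[set[int]] = []
        for s in new_sets:
            if any(s < t for t in new_sets) or s in kept:
                continue
            kept.append(s)
        sets = kept
    # order letter sets by their earliest group so group 0 always gets "a"
    sets.sort(key=lambda s: min(s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, sets):
        for g in sorted(s):
            letters[labels[g]] += letter
    return letters


def compare_groups(
    groups: Sequence[GroupSample],
    alpha: float = 0.05,
    alpha_assumption: float = 0.05,
    test: TestKind | None = None,
) -> ComparisonResult:
    """Run the full comparison scheme on one metric.

    Selects the test (unless forced), computes the omnibus statistic, the
    all-pairwise adjusted p matrix and the compact letter display.
    """
    groups = _check_groups(groups)
    labels = tuple(g.label for g in groups)
    if test is None:
        test = choose_test(groups, alpha_assumption=alpha_assumption)
    if test is TestKind.ANOVA_TUKEY:
        omnibus = one_way_anova(groups)
        pmat = tukey_all_pairs(groups)
    elif test is TestKind.KW_RANKS:
        omnibus = kruskal_wallis(groups)
        pmat = nemenyi_rank_all_pairs(groups)
    else:
        raise ValueError("compare_groups handles anova_tukey and kw_ranks only")
    letters = compact_letters(pmat, alpha=alpha, labels=labels)
    return ComparisonResult(
        test_used=test,
        labels=labels,
        omnibus=omnibus,
        pairwise_p=pmat,
        letters=letters,
        alpha=alpha,
    )
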
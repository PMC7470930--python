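"""Group statistics with a normality-gated test choice.

The battery mirrors common neuroanatomy practice: Shapiro–Wilk decides
between the parametric and nonparametric path; two groups are compared with
Student's t or Mann–Whitney U, three or more with one-way ANOVA or
Kruskal–Wallis followed by Bonferroni-adjusted pairwise comparisons
(pairwise t tests after ANOVA, Dunn rank tests after Kruskal–Wallis), with
adjusted p-values capped at 1.  Distribution shapes are compared with the
two-sample Kolmogorov–Smirnov test (asymptotic p), and monotone association
with Spearman's rank correlation (midranks for ties).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseComparison:
    label_a: str
    label_b: str
    p_raw: float
    p_adjusted: float  # Bonferroni, capped at 1


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    labels: tuple[str, ...]
    normal: Optional[bool] = None  # outcome of the normality gate, if applied
    pairwise: list[PairwiseComparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive statistics of one metric in one (genotype, age) group."""

    genotype: str
    age_months: float
    metric: str
    n: int
    mean: float
    sem: float
    median: float
    min: float
    max: float

    def __str__(self) -> str:
        return (
            f"{self.metric} [{self.genotype} {self.age_months:g} mo]: "
            f"{self.mean:.3g} ± {self.sem:.2g} "
            f"(median = {self.median:.3g}, range = {self.min:.3g}–{self.max:.3g}, "
            f"n = {self.n})"
        )


def summarize_metric(
    values: Sequence[float],
    genotype: str = "",
    age_months: float = float("nan"),
    metric: str = "",
) -> GroupSummary:
    """Mean ± SEM (sample sd, n−1 denominator), median and range."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("summarize_metric: no values")
    if v.size == 1:
        logger.warning("summarize_metric: n = 1, SEM reported as 0 by convention")
        sem = 0.0
    else:
        sem = float(np.std(v, ddof=1) / np.sqrt(v.size))
    return GroupSummary(
        genotype=genotype,
        age_months=age_months,
        metric=metric,
        n=int(v.size),
        mean=float(np.mean(v)),
        sem=sem,
        median=float(np.median(v)),
        min=float(np.min(v)),
        max=float(np.max(v)),
    )


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Shapiro–Wilk gate; constant samples count as non-normal."""
    if np.all(x == x[0]):
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.shapiro(x).pvalue
    return bool(p > alpha)


def compare_two(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    alpha_normality: float = 0.05,
) -> StatResult:
    """Two-sample comparison gated on Shapiro–Wilk normality.

    Both samples normal → two-sided Student's t test (pooled variance);
    otherwise two-sided Mann–Whitney U (asymptotic, no continuity
    correction).  The result records which path was taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("compare_two requires n >= 3 per sample (normality gate)")
    normal = _is_normal(x, alpha_normality) and _is_normal(y, alpha_normality)
    if normal:
        res = sps.ttest_ind(x, y, equal_var=True)
        name = "student_t"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        name = "mann_whitney_u"
    return StatResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        labels=labels,
        normal=normal,
    )


def _dunn_pairwise(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> list[PairwiseComparison]:
    """Dunn's z tests on pooled midranks with tie correction, Bonferroni."""
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(combinations(range(len(groups)), 2))
    k = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = abs(mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(z)
        out.append(
            PairwiseComparison(labels[i], labels[j], p_raw=p, p_adjusted=min(1.0, p * k))
        )
    return out


def _t_pairwise(
    groups: Sequence[np.ndarray], labels: Sequence[str]
) -> list[PairwiseComparison]:
    pairs = list(combinations(range(len(groups)), 2))
    k = len(pairs)
    out = []
    for i, j in pairs:
        if np.array_equal(groups[i], groups[j]):
            p = 1.0
        else:
            p = float(sps.ttest_ind(groups[i], groups[j], equal_var=True).pvalue)
        out.append(
            PairwiseComparison(labels[i], labels[j], p_raw=p, p_adjusted=min(1.0, p * k))
        )
    return out


def compare_many(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha_normality: float = 0.05,
) -> StatResult:
    """Omnibus comparison of >= 3 groups with Bonferroni pairwise follow-up.

    All groups normal by Shapiro–Wilk → one-way ANOVA with pairwise t tests;
    any group non-normal → Kruskal–Wallis with Dunn rank tests.  Pairwise
    p-values are Bonferroni-multiplied and capped at 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 3:
        raise ValueError("compare_many requires >= 3 groups; use compare_two")
    if any(a.size < 3 for a in arrays):
        raise ValueError("compare_many requires n >= 3 in every group")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    labels = list(labels)
    normal = all(_is_normal(a, alpha_normality) for a in arrays)
    if normal:
        res = sps.f_oneway(*arrays)
        name = "one_way_anova"
        pairwise = _t_pairwise(arrays, labels)
    else:
        if all(np.array_equal(a, arrays[0]) for a in arrays):
            # Kruskal–Wallis is undefined when all values are identical
            return StatResult(
                test_name="kruskal_wallis", statistic=0.0, p_value=1.0,
                labels=tuple(labels), normal=False,
                pairwise=[
                    PairwiseComparison(labels[i], labels[j], 1.0, 1.0)
                    for i, j in combinations(range(len(arrays)), 2)
                ],
            )
        res = sps.kruskal(*arrays)
        name = "kruskal_wallis"
        pairwise = _dunn_pairwise(arrays, labels)
    return StatResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        labels=tuple(labels),
        normal=normal,
        pairwise=pairwise,
    )


def ks_two_sample(
    x: Sequence[float], y: Sequence[float], labels: tuple[str, str] = ("a", "b")
) -> StatResult:
    """Two-sided two-sample Kolmogorov–Smirnov test, asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ks_two_sample: empty sample")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return StatResult(
        test_name="kolmogorov_smirnov",
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        labels=labels,
    )


def spearman_corr(
    x: Sequence[float], y: Sequence[float], labels: tuple[str, str] = ("x", "y")
) -> StatResult:
    """Spearman rank correlation (midranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("spearman_corr: samples must be paired")
    if x.size < 4:
        raise ValueError("spearman_corr requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman_corr undefined for constant input")
    res = sps.spearmanr(x, y)
    return StatResult(
        test_name="spearman",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        labels=labels,
    )
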
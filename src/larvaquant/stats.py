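"""Group-comparison statistics for per-larva metrics.

The decision procedure mirrors common practice in behavioural
neuroscience: Shapiro-Wilk normality on every group gates the choice
between parametric and rank-based tests; two groups are compared with a
two-sample t-test or Wilcoxon rank-sum test, three or more with a
Kruskal-Wallis omnibus followed by Dunn's z-based all-pairs post-hoc with
multiplicity adjustment. All summaries are mean +/- SEM (sample SD over
sqrt(n)).

Dunn's test is implemented here directly from rank arithmetic: with pooled
ranks R, mean group ranks R_i, total N and tie-correction
C = sum(t^3 - t) / (12 (N - 1)) over tie groups of size t, the pairwise
statistic is

    z_ij = (Rbar_i - Rbar_j) / sqrt((N (N + 1) / 12 - C) (1/n_i + 1/n_j))

with two-sided normal p-values, adjusted by Holm's method by default.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import DegenerateInputError, LarvaQuantError

__all__ = [
    "GroupData",
    "GroupComparisonResult",
    "shapiro_gate",
    "summarize",
    "compare_two",
    "compare_many",
    "dunn_posthoc",
]


@dataclass
class GroupData:
    """Per-subject scalar values for one experimental group."""

    label: str
    values: np.ndarray
    paired_epoch: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise LarvaQuantError("group values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise LarvaQuantError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class GroupComparisonResult:
    """Outcome of a gated group comparison."""

    test_name: str
    statistic: float
    pvalue: float
    normality: dict = field(default_factory=dict)  # label -> shapiro p
    verdict: str = ""  # "normal" | "nonparametric"
    posthoc: pd.DataFrame | None = None
    group_summary: dict = field(default_factory=dict)  # label -> (mean, sem, n)

    def summary(self) -> str:
        lines = [f"{self.test_name}: statistic={self.statistic:.4g}, "
                 f"p={format_p(self.pvalue)}"]
        if self.verdict:
            lines.append(f"data structure: {self.verdict}")
        for label, (mean, sem, n) in self.group_summary.items():
            sem_str = "n/a" if sem is None else f"{sem:.4g}"
            lines.append(f"  {label}: {mean:.4g} +/- {sem_str} (n={n})")
        if self.posthoc is not None:
            lines.append("post-hoc (adjusted p):")
            for _, row in self.posthoc.iterrows():
                lines.append(
                    f"  {row['group_a']} vs {row['group_b']}: "
                    f"p={format_p(row['p_adjusted'])}"
                )
        return "\n".join(lines)


def format_p(p: float) -> str:
    """Format a p-value to two significant figures."""
    return f"{p:.2g}"


def summarize(group: GroupData) -> tuple[float, float | None]:
    """Mean and SEM (sample SD / sqrt(n)); SEM is None for n = 1."""
    if group.n < 1:
        raise LarvaQuantError("empty group")
    mean = float(np.mean(group.values))
    if group.n == 1:
        return mean, None
    sem = float(np.std(group.values, ddof=1) / np.sqrt(group.n))
    return mean, sem


def shapiro_gate(groups: list[GroupData], alpha: float = 0.05) -> str:
    """Choose the test family from per-group Shapiro-Wilk normality.

    Returns ``"nonparametric"`` if any group rejects normality at ``alpha``,
    else ``"normal"``. Each group needs n >= 3 and nonzero variance.
    """
    if len(groups) == 0:
        raise LarvaQuantError("no groups")
    for g in groups:
        if g.n < 3:
            raise LarvaQuantError(
                f"group {g.label!r} too small for Shapiro-Wilk (n={g.n})"
            )
        if np.ptp(g.values) == 0:
            raise DegenerateInputError(
                f"group {g.label!r} has zero variance"
            )
        if sps.shapiro(g.values).pvalue < alpha:
            return "nonparametric"
    return "normal"


def _summaries(groups: list[GroupData]) -> dict:
    return {g.label: (*summarize(g), g.n) for g in groups}


def _normality(groups: list[GroupData]) -> dict:
    out = {}
    for g in groups:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out[g.label] = float(sps.shapiro(g.values).pvalue)
        except Exception:
            out[g.label] = float("nan")
    return out


def compare_two(
    groups: list[GroupData],
    verdict: str | None = None,
    welch: bool = False,
    alpha: float = 0.05,
) -> GroupComparisonResult:
    """Two-group comparison gated on normality.

    Normal data use a two-sided two-sample t-test (pooled variance by
    default, Welch with ``welch=True``); non-normal data use the Wilcoxon
    rank-sum (Mann-Whitney U) test, exact for small tie-free samples and a
    continuity-corrected normal approximation otherwise.
    """
    if len(groups) != 2:
        raise LarvaQuantError("compare_two needs exactly 2 groups")
    for g in groups:
        if g.n < 2:
            raise LarvaQuantError(f"group {g.label!r} has n < 2")
    if verdict is None:
        verdict = shapiro_gate(groups, alpha=alpha)
    a, b = groups[0].values, groups[1].values
    if verdict == "normal":
        res = sps.ttest_ind(a, b, equal_var=not welch)
        name = "Welch t-test" if welch else "Two-sample t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        name = "Wilcoxon rank sum test"
    return GroupComparisonResult(
        test_name=name,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        normality=_normality(groups),
        verdict=verdict,
        group_summary=_summaries(groups),
    )


def kruskal_wallis(groups: list[GroupData]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and p.

    The all-values-tied degenerate case is reported as H = 0, p = 1 by
    convention rather than an error.
    """
    pooled = np.concatenate([g.values for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = sps.kruskal(*[g.values for g in groups])
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(
    groups: list[GroupData], adjustment: str = "holm"
) -> pd.DataFrame:
    """Dunn's z-based all-pairs post-hoc comparisons.

    Returns a DataFrame with one row per unordered pair: z, raw two-sided
    normal p, and the multiplicity-adjusted p (``holm``, ``bonferroni`` or
    ``fdr_bh``).
    """
    method = {"holm": "holm", "bonferroni": "bonferroni",
              "fdr_bh": "fdr_bh", "bh": "fdr_bh"}.get(adjustment)
    if method is None:
        raise LarvaQuantError(f"unknown adjustment {adjustment!r}")
    pooled = np.concatenate([g.values for g in groups])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    # mean rank per group
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start : start + g.n])))
        start += g.n
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = tie_term / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - correction

    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        gi, gj = groups[i], groups[j]
        var = base_var * (1.0 / gi.n + 1.0 / gj.n)
        if var <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p_raw = 2 * sps.norm.sf(abs(z))
        rows.append(
            dict(group_a=gi.label, group_b=gj.label, z=float(z),
                 p_raw=float(p_raw))
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p_raw"].to_numpy(), method=method)[1]
    return df


def compare_many(
    groups: list[GroupData], adjustment: str = "holm"
) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus with Dunn's all-pairs post-hoc (>= 3 groups)."""
    if len(groups) < 3:
        raise LarvaQuantError("compare_many needs at least 3 groups")
    for g in groups:
        if g.n < 2:
            raise LarvaQuantError(f"group {g.label!r} has n < 2")
    h, p = kruskal_wallis(groups)
    posthoc = dunn_posthoc(groups, adjustment=adjustment)
    return GroupComparisonResult(
        test_name="Kruskal-Wallis rank sum test",
        statistic=h,
        pvalue=p,
        normality=_normality(groups),
        verdict="nonparametric",
        posthoc=posthoc,
        group_summary=_summaries(groups),
    )
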
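"""Prevalence filtering, per-sample read totals, descriptive statistics,
bootstrap-supported two-sample t-tests and post hoc power."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .profiles_io import CountTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupDescriptives:
    """n / mean / sd / median / IQR for one group of values.

    sd uses the n-1 denominator; the 25th/75th percentiles use linear
    interpolation (type-7), matching spreadsheet conventions.
    """

    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class TTestResult:
    """Welch t-test on the original data plus a percentile bootstrap CI of
    the mean difference from within-group resamples."""

    t: float
    df: float
    p: float
    mean_diff: float
    boot_ci_low: float
    boot_ci_high: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class FilterResult:
    table: CountTable
    retained: list[str]
    removed: list[str]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def taxa_prevalence(table: CountTable, presence_threshold: int = 1) -> np.ndarray:
    """Per-taxon fraction of samples with count >= presence_threshold."""
    return (table.counts >= presence_threshold).mean(axis=1)


def prevalence_filter(
    table: CountTable,
    min_prevalence: float,
    presence_threshold: int = 1,
) -> FilterResult:
    """Retain taxa detected in at least ``min_prevalence`` of samples.

    Prevalence of a taxon is the fraction of samples in *this* table with
    count >= ``presence_threshold``. ``min_prevalence = 0`` is the
    identity. With 40 samples, the 2.5% cut-off resolves to detection in
    at least one sample.
    """
    if not 0 <= min_prevalence <= 1:
        raise ValueError(f"min_prevalence must be in [0, 1], got {min_prevalence}")
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("cannot filter an empty table")
    prev = taxa_prevalence(table, presence_threshold)
    keep = prev >= min_prevalence
    retained = [t for t, k in zip(table.taxa, keep) if k]
    removed = [t for t, k in zip(table.taxa, keep) if not k]
    filtered = CountTable(retained, list(table.samples), table.counts[keep, :])
    return FilterResult(table=filtered, retained=retained, removed=removed)


def retained_ratio(n_first: int, n_second: int, ndigits: int = 1) -> float:
    """Ratio of retained-taxa counts between two filtered compartments,
    rounded for reporting (e.g. 498 vs 128 -> 3.9)."""
    if n_second <= 0:
        raise ValueError("denominator compartment has no retained taxa")
    return round(n_first / n_second, ndigits)


def sample_totals(table: CountTable) -> dict[str, int]:
    """Per-sample classified-read totals (column sums)."""
    totals = table.counts.sum(axis=0)
    return {s: int(t) for s, t in zip(table.samples, totals)}


def group_descriptives(values, labels) -> dict[str, GroupDescriptives]:
    """Descriptive statistics per group label.

    Raises if any group is empty or ``values``/``labels`` lengths differ.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    if len(values) != len(labels):
        raise ValueError("values and labels must have equal length")
    if len(values) == 0:
        raise ValueError("no values supplied")
    out: dict[str, GroupDescriptives] = {}
    for g in dict.fromkeys(labels):  # preserve first-seen order
        v = values[[lab == g for lab in labels]]
        if v.size == 0:
            raise ValueError(f"group {g!r} has no values")
        out[g] = GroupDescriptives(
            n=int(v.size),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            median=float(np.median(v)),
            iqr_low=float(np.percentile(v, 25)),
            iqr_high=float(np.percentile(v, 75)),
        )
    return out


def bootstrap_t_test(
    x,
    y,
    n_boot: int = 1000,
    seed: int = 0,
    equal_var: bool = False,
) -> TTestResult:
    """Two-sample t-test (Welch by default) with a percentile bootstrap CI.

    The t statistic and p-value are computed on the original data. The
    95% CI of the mean difference comes from ``n_boot`` stratified
    (within-group) resamples with replacement, reproducible given ``seed``.
    If every value in both groups is identical the test is degenerate and
    p is reported as 1.0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    mean_diff = float(np.mean(x) - np.mean(y))
    if np.ptp(x) == 0 and np.ptp(y) == 0 and np.mean(x) == np.mean(y):
        logger.warning("degenerate t-test: all values identical in both groups")
        t_stat, df, p = 0.0, float(x.size + y.size - 2), 1.0
    else:
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
        if np.isnan(p):  # zero variance in both groups but unequal means
            p = 0.0
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.choice(x, size=x.size, replace=True)
        by = rng.choice(y, size=y.size, replace=True)
        diffs[b] = bx.mean() - by.mean()
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return TTestResult(
        t=t_stat,
        df=df,
        p=p,
        mean_diff=mean_diff,
        boot_ci_low=float(lo),
        boot_ci_high=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, reported alongside the t-test for
    median-style comparisons."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def posthoc_power_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alpha: float = 0.05,
) -> float:
    """Post hoc power of the two-sided two-sample t-test at the observed
    effect, using the pooled SD and the noncentral t distribution.

    This is one of several published conventions; results from commercial
    packages using other algorithms may differ.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    ncp = (mean1 - mean2) / (sp * np.sqrt(1 / n1 + 1 / n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral t can return NaN on extreme underflow; those
    # tails are numerically zero
    upper = 0.0 if np.isnan(upper) else upper
    lower = 0.0 if np.isnan(lower) else lower
    return float(np.clip(upper + lower, 0.0, 1.0))
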
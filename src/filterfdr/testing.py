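"""Per-feature two-sample tests.

The workhorse is the equal-variance pooled two-sample t statistic

    T = (X̄ − Ȳ) / (Sp · sqrt(1/nX + 1/nY)),
    Sp² = [(nX−1)·SX² + (nY−1)·SY²] / (nX + nY − 2),

whose null distribution is Student's t with v = nX + nY − 2 degrees of
freedom; the two-sided p-value is P = 2·[1 − F0(|T|)] with F0 the central t
cdf.  The Wilcoxon rank-sum test is provided as a distribution-free
alternative used for robustness checks.

Constant features (zero pooled variance) raise an error rather than being
assigned p = 1: silently mapping them to any p-value would distort the
p-value distribution that the FDR procedures and the bias test rest on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import ExpressionDataset

__all__ = ["TestResult", "pooled_t", "wilcoxon_test", "run_test", "permute_group_labels"]


@dataclass
class TestResult:
    """Per-feature test statistics and two-sided p-values."""

    statistic: np.ndarray
    df: int
    pooled_sd: np.ndarray | None
    pvalue: np.ndarray
    test_name: str


def pooled_t(dataset: ExpressionDataset) -> TestResult:
    """Equal-variance two-sample t test for every feature (vectorised)."""
    nx, ny = dataset.nX, dataset.nY
    if nx < 2 or ny < 2:
        raise ValueError("pooled t test needs at least 2 samples per group")
    x, y = dataset.group_values()
    df = nx + ny - 2
    sp2 = ((nx - 1) * x.var(axis=1, ddof=1) + (ny - 1) * y.var(axis=1, ddof=1)) / df
    if np.any(sp2 <= 0):
        bad = int(np.argmax(sp2 <= 0))
        raise ValueError(
            f"zero pooled variance for feature {dataset.feature_ids[bad]!r}: "
            "p-value undefined; remove constant features upstream"
        )
    sp = np.sqrt(sp2)
    t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return TestResult(statistic=t, df=df, pooled_sd=sp, pvalue=p, test_name="student_t")


def wilcoxon_test(dataset: ExpressionDataset) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test per feature.

    Exact null distribution when min(nX, nY) <= 10 and the feature has no
    ties; otherwise the normal approximation with continuity correction.
    Ties are handled by midranks.  The reported statistic is the rank sum of
    group A.
    """
    nx, ny = dataset.nX, dataset.nY
    if nx < 2 or ny < 2:
        raise ValueError("rank-sum test needs at least 2 samples per group")
    x, y = dataset.group_values()
    m = dataset.m
    stat = np.empty(m)
    pval = np.empty(m)
    small = min(nx, ny) <= 10
    for i in range(m):
        has_ties = np.unique(np.concatenate([x[i], y[i]])).size < nx + ny
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x[i], y[i], alternative="two-sided", method=method)
        stat[i] = res.statistic + nx * (nx + 1) / 2.0  # U -> rank sum of group A
        pval[i] = min(res.pvalue, 1.0)
    return TestResult(statistic=stat, df=nx + ny - 2, pooled_sd=None, pvalue=pval,
                      test_name="wilcoxon")


_TESTS = {"t": pooled_t, "student_t": pooled_t, "wilcoxon": wilcoxon_test}


def run_test(dataset: ExpressionDataset, method: str = "t") -> TestResult:
    """Dispatch a named test ("t" or "wilcoxon")."""
    try:
        return _TESTS[method](dataset)
    except KeyError:
        raise ValueError(f"unknown test {method!r}; choose from {sorted(_TESTS)}") from None


def permute_group_labels(dataset: ExpressionDataset, seed) -> ExpressionDataset:
    """Randomly reassign samples to groups, preserving group sizes.

    Breaks any association between expression and group while keeping the
    marginal distribution of each sample's values — the device used to
    estimate the null p-value distribution after filtering.  ``seed`` may be
    an int or a numpy Generator/SeedSequence; the permutation is reproducible.
    """
    rng = np.random.default_rng(seed)
    return dataset.with_group(rng.permutation(dataset.group))
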
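"""Small-sample exact rank tests and the shared comparison-result container.

The rank-sum and signed-rank tests here use the exact conditional null
distribution of the midrank statistic, computed by generating-function
dynamic programming (equivalent to full enumeration of rank assignments /
sign patterns, and verified against it in the test suite). Two-sided
p-values sum the null probability of all outcomes at least as far from the
null mean as the observed statistic. Midranks handle ties; doubling the
ranks keeps the DP on an integer lattice. Above the exact-size cutoffs the
normal approximation with tie correction is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Optional

import numpy as np
from scipy import stats as sps

#: Largest per-group size for which the rank-sum test is exact by default.
EXACT_RANK_SUM_MAX = 20
#: Largest number of nonzero pairs for which the signed-rank test is exact.
EXACT_SIGNED_RANK_MAX = 25

_EPS = 1e-9


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a two-group or paired comparison."""

    statistic: float
    p_value: float
    test_name: str
    n: int
    estimate: Optional[float] = None  # e.g. mean difference, direction carrier
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 + _EPS):
            raise ValueError(f"p-value out of range: {self.p_value}")


def midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean rank of the tied block."""
    return sps.rankdata(np.asarray(values, dtype=float), method="average")


def _subset_sum_counts(items: np.ndarray, k: int) -> np.ndarray:
    """counts[j, s] = number of size-j subsets of ``items`` with sum s.

    ``items`` must be nonnegative integers. Returned array has shape
    (k+1, total_sum+1); counts fit exactly in float64 for n <= ~50.
    """
    total = int(items.sum())
    counts = np.zeros((k + 1, total + 1))
    counts[0, 0] = 1.0
    for it in items:
        it = int(it)
        # iterate j downward so each item is used at most once
        for j in range(k, 0, -1):
            counts[j, it:] += counts[j - 1, : total + 1 - it]
    return counts


def _sign_sum_counts(items: np.ndarray) -> np.ndarray:
    """counts[s] = number of subsets (any size) of ``items`` with sum s."""
    total = int(items.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for it in items:
        it = int(it)
        counts[it:] += counts[: total + 1 - it].copy()
    return counts


def rank_sum_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum with midranks.

    Returns (W, p) where W is the sum of ranks of ``x`` in the pooled
    sample. The null distribution conditions on the observed (tied) rank
    configuration; p is the probability mass of rank assignments whose
    statistic is at least as far from the null mean as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    r2 = np.rint(2 * midranks(pooled)).astype(int)  # doubled midranks: ints
    k = x.size
    n = pooled.size
    w2 = float(r2[:k].sum())
    counts = _subset_sum_counts(r2, k)[k]
    mean2 = k * float(r2.sum()) / n
    sums = np.arange(counts.size, dtype=float)
    extreme = np.abs(sums - mean2) >= np.abs(w2 - mean2) - _EPS
    p = float(min(1.0, counts[extreme].sum() / comb(n, k)))
    return w2 / 2.0, p


def signed_rank_exact(diffs) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank with midranks.

    Zero differences are discarded (the usual convention). Returns
    (W+, p); with all n differences of one sign and no ties this gives
    p = 2 / 2**n.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    r2 = np.rint(2 * midranks(np.abs(d))).astype(int)
    w2 = float(r2[d > 0].sum())
    counts = _sign_sum_counts(r2)
    mean2 = float(r2.sum()) / 2.0
    sums = np.arange(counts.size, dtype=float)
    extreme = np.abs(sums - mean2) >= np.abs(w2 - mean2) - _EPS
    p = float(min(1.0, counts[extreme].sum() / 2.0 ** n))
    return w2 / 2.0, p


def rank_sum_test(x, y, exact: str = "auto") -> ComparisonResult:
    """Wilcoxon rank-sum: exact for small groups, normal approx otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    use_exact = exact == "always" or (
        exact == "auto"
        and x.size <= EXACT_RANK_SUM_MAX
        and y.size <= EXACT_RANK_SUM_MAX
    )
    if use_exact:
        w, p = rank_sum_exact(x, y)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        w = float(res.statistic) + x.size * (x.size + 1) / 2.0
        p = float(res.pvalue)
    return ComparisonResult(statistic=w, p_value=p,
                            test_name="wilcoxon_rank_sum",
                            n=int(x.size + y.size),
                            extra={"exact": use_exact})


def signed_rank_test(x, y=None, exact: str = "auto") -> ComparisonResult:
    """Wilcoxon signed-rank on paired samples (or precomputed differences)."""
    d = np.asarray(x, dtype=float) if y is None else (
        np.asarray(x, dtype=float) - np.asarray(y, dtype=float))
    nz = int(np.count_nonzero(d))
    use_exact = exact == "always" or (
        exact == "auto" and nz <= EXACT_SIGNED_RANK_MAX)
    if use_exact:
        w, p = signed_rank_exact(d)
    else:
        res = sps.wilcoxon(d[d != 0], alternative="two-sided",
                           method="approx")
        w, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(statistic=w, p_value=p,
                            test_name="wilcoxon_signed_rank",
                            n=nz, extra={"exact": use_exact,
                                         "n_pairs": int(np.size(d))})


def paired_t_test(x, y) -> ComparisonResult:
    """Paired Student t-test; degenerate all-zero differences give p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.allclose(d.std(ddof=1) if d.size > 1 else 0.0, 0.0):
        stat = 0.0 if np.allclose(d.mean(), 0.0) else np.inf
        p = 1.0 if stat == 0.0 else 0.0
        return ComparisonResult(statistic=stat, p_value=p,
                                test_name="paired_t", n=d.size,
                                estimate=float(d.mean()))
    res = sps.ttest_rel(x, y)
    return ComparisonResult(statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            test_name="paired_t", n=d.size,
                            estimate=float(d.mean()))


def welch_or_student_t(a, b, equal_var: bool = True) -> ComparisonResult:
    """Two-sample t-test with a defined p = 1 for identical degenerate groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = np.isclose(a.mean(), b.mean())
        return ComparisonResult(statistic=0.0 if same else np.inf,
                                p_value=1.0 if same else 0.0,
                                test_name="student_t",
                                n=a.size + b.size,
                                estimate=float(a.mean() - b.mean()))
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            test_name="student_t" if equal_var else "welch_t",
                            n=a.size + b.size,
                            estimate=float(a.mean() - b.mean()))
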
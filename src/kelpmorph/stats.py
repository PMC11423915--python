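"""Group-comparison statistics for embryo phenotyping.

Three tests cover the three kinds of measurement, all two-tailed:

* per-cell scalars (area, rectangularity, elongation) — Welch's unequal-
  variance t-test, since cell samples are large but heteroscedastic;
* per-blade scalars (l/w ratio, blade area) — the two-sample Mann–Whitney
  rank test, since blade samples are tiny (n = 4–6 embryos per group);
* neighbour-count categories — Pearson's χ² on the pooled
  {1, 2, 3, 4, >=5} contingency table.

No multiple-testing correction is applied; the pipeline instead reports how
many comparisons it ran.  A small binomial calculation supports sample
screening: given the background frequency p of spontaneously abnormal
embryos among intact ones, the chance that a sample of n embryos is entirely
normal is (1−p)^n and the expected number of abnormal embryos is n·p.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "BinomialCompositionResult",
    "welch_t",
    "mann_whitney",
    "chi2_counts",
    "binomial_composition",
]

#: Combined sample size at/below which Mann–Whitney p-values are exact.
MW_EXACT_MAX_N = 12


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    test: str  # welch_t | mann_whitney | chi2
    statistic: float
    p_value: float
    df: float | None = None
    two_tailed: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class BinomialCompositionResult:
    p_abnormal: float
    n: int
    p_all_normal: float
    expected_abnormal: float


def _as_sample(x, name: str, min_n: int) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1 or a.size < min_n:
        raise ValueError(f"sample {name!r}: need a 1-D sample of size >= {min_n}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"sample {name!r}: non-finite values")
    return a


def welch_t(
    a, b, metric: str = "", group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Two-tailed Welch (unequal-variance) t-test with Welch–Satterthwaite df."""
    a = _as_sample(a, group_a, 2)
    b = _as_sample(b, group_b, 2)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate: both samples constant; equal means carry no evidence,
        # different means are infinitely incompatible with equal variance 0
        same = a.mean() == b.mean()
        return GroupComparison(
            metric=metric,
            group_a=group_a,
            group_b=group_b,
            test="welch_t",
            statistic=0.0 if same else math.copysign(math.inf, a.mean() - b.mean()),
            p_value=1.0 if same else 0.0,
            df=float(a.size + b.size - 2),
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test="welch_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
    )


def mann_whitney(
    a, b, metric: str = "", group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Two-tailed two-sample Mann–Whitney (Wilcoxon rank-sum) U test.

    Exact null distribution when the combined sample size is at most
    12 (blade groups are that small); otherwise the normal approximation
    with tie-corrected variance and continuity correction.
    """
    a = _as_sample(a, group_a, 1)
    b = _as_sample(b, group_b, 1)
    method = "exact" if a.size + b.size <= MW_EXACT_MAX_N else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
    )


def chi2_counts(
    table, metric: str = "", group_a: str = "a", group_b: str = "b"
) -> GroupComparison:
    """Pearson χ² (no Yates correction) on a categories × groups table.

    Categories empty in *every* group are dropped with a warning before
    testing; a zero *expected* count after that is an error advising further
    pooling.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2-D contingency table with >= 2 rows and columns")
    keep = t.sum(axis=1) > 0
    if not keep.all():
        import logging

        logging.getLogger("kelpmorph").warning(
            "dropping %d empty categor(ies) before the χ² test", int((~keep).sum())
        )
        t = t[keep]
    if t.shape[0] < 2:
        raise ValueError("fewer than 2 non-empty categories; pool further")
    expected = sps.contingency.expected_freq(t)
    if np.any(expected <= 0):
        raise ValueError("zero expected count; pool sparse categories before testing")
    res = sps.chi2_contingency(t, correction=False)
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test="chi2",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.dof),
    )


def binomial_composition(p_abnormal: float, n: int) -> BinomialCompositionResult:
    """Sample-composition check under the binomial law.

    With background abnormality frequency ``p_abnormal`` (measured on intact
    embryos), a sample of ``n`` embryos is entirely normal with probability
    (1−p)^n, and carries n·p abnormal embryos in expectation.
    """
    if not (0.0 <= p_abnormal <= 1.0):
        raise ValueError(f"p_abnormal {p_abnormal} outside [0, 1]")
    if int(n) != n or n < 1:
        raise ValueError(f"sample size must be a positive integer, got {n}")
    n = int(n)
    return BinomialCompositionResult(
        p_abnormal=float(p_abnormal),
        n=n,
        p_all_normal=(1.0 - p_abnormal) ** n,
        expected_abnormal=n * p_abnormal,
    )
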
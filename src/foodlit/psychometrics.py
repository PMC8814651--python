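"""Validation statistics: Pearson construct validity, internal consistency,
test-retest reliability, and group comparisons.

Construct validity is flagged good for correlations strictly between 0.4
and 0.9; reliability coefficients are held to a 0.7 cut-off; Cronbach's
alpha above 0.7 indicates adequate internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ComputationError

__all__ = [
    "PearsonResult",
    "TTestResult",
    "TestRetestResult",
    "pearson",
    "construct_validity_flag",
    "cronbach_alpha",
    "icc_agreement",
    "test_retest",
    "independent_t_test",
    "CONSTRUCT_VALIDITY_BOUNDS",
    "RELIABILITY_CUTOFF",
    "ALPHA_CUTOFF",
]

CONSTRUCT_VALIDITY_BOUNDS = (0.4, 0.9)
RELIABILITY_CUTOFF = 0.7
ALPHA_CUTOFF = 0.7


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    mean_a: float
    mean_b: float
    significant: bool


@dataclass(frozen=True)
class TestRetestResult:
    pearson_r: float
    icc: float
    n: int
    reliable: bool       # headline coefficient (Pearson) >= 0.7
    reliable_icc: bool


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ComputationError("inputs must be equal-length 1-D vectors")
    if np.isnan(x).any() or np.isnan(y).any():
        keep = ~(np.isnan(x) | np.isnan(y))  # pairwise deletion
        x, y = x[keep], y[keep]
    return x, y


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation with a two-sided p from the t transform
    on n-2 degrees of freedom."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ComputationError(f"need at least 3 paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p_value=float(res.pvalue), n=int(x.size))


def construct_validity_flag(r: float) -> str:
    """``good`` iff 0.4 < r < 0.9, else ``too_low`` / ``too_high``."""
    if not -1.0 <= r <= 1.0:
        raise ComputationError(f"correlation {r} outside [-1, 1]")
    lo, hi = CONSTRUCT_VALIDITY_BOUNDS
    if r >= hi:
        return "too_high"
    if r <= lo:
        return "too_low"
    return "good"


def cronbach_alpha(matrix) -> float:
    """alpha = k/(k-1) * (1 - sum(item variances) / variance(total)).

    ``matrix`` is respondents x items. Sample (n-1 denominator) variances
    throughout. Requires >= 2 items, >= 2 respondents, and a non-constant
    total score.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ComputationError("item score matrix must be 2-D (respondents x items)")
    n, k = m.shape
    if k < 2:
        raise ComputationError(f"need at least 2 items, got {k}")
    if n < 2:
        raise ComputationError(f"need at least 2 respondents, got {n}")
    if np.isnan(m).any():
        raise ComputationError("item score matrix has missing cells")
    item_var = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ComputationError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def icc_agreement(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    For n targets rated under k=2 conditions (test and retest), from the
    two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-target, MSC the between-condition, and MSE the
    residual mean square. Unlike Pearson's r this penalizes systematic
    shifts between the two occasions.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ComputationError(f"need at least 3 paired observations, got {n}")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ComputationError("ICC undefined: zero variance in both occasions")
    return float((msr - mse) / denom)


def test_retest(scores_t1, scores_t2) -> TestRetestResult:
    """Pearson r and ICC(2,1) between the two administrations.

    Both coefficients are reported; the headline reliability flag follows
    the Pearson coefficient against the 0.7 cut-off, with the
    absolute-agreement flag alongside.
    """
    x, y = _paired(scores_t1, scores_t2)
    if x.size < 3:
        raise ComputationError(f"need at least 3 paired scores, got {x.size}")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ComputationError("both administrations are constant")
    if np.array_equal(x, y):
        r = 1.0  # Pearson via scipy would be exact too, but avoid 0/0 edge
    else:
        r = pearson(x, y).r
    icc = icc_agreement(x, y)
    return TestRetestResult(
        pearson_r=r,
        icc=icc,
        n=int(x.size),
        reliable=r >= RELIABILITY_CUTOFF,
        reliable_icc=icc >= RELIABILITY_CUTOFF,
    )


def independent_t_test(a, b, *, welch: bool = False, alpha: float = 0.05) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ComputationError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        significant=bool(res.pvalue < alpha),
    )
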
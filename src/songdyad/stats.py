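"""Statistical comparisons used by the study, as thin contract-checked
wrappers over :mod:`scipy.stats`.

Proportions (switching rate, evenness) are arcsine-square-root transformed
before paired t-tests, the standard variance stabiliser for proportion data.
Movement comparisons are non-parametric: two-sample Kolmogorov-Smirnov for
observed-vs-null distributions, Mann-Whitney U for independent groups, and
the Wilcoxon signed-rank test for paired meander ratios.  Exact small-sample
p-values are used where the sample permits, since study sample sizes are in
the 9-11 range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateTestError, ValidationError

__all__ = [
    "TestResult",
    "arcsine_sqrt",
    "paired_t",
    "ks_two_sample",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two: float
    p_one: float
    n: tuple[int, ...]
    test_name: str
    direction: str | None = None


def arcsine_sqrt(p: float) -> float:
    """Variance-stabilising transform for a proportion: arcsin(sqrt(p))."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"proportion must lie in [0, 1], got {p}")
    return math.asin(math.sqrt(p))


def paired_t(
    x: Sequence[float], y: Sequence[float], direction: str = "greater"
) -> TestResult:
    """Paired t-test on differences y - x.

    ``direction`` names the one-sided alternative for ``mean(y - x)``
    ("greater" or "less"); both the two-tailed p and that one-tailed p are
    reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValidationError("paired t needs at least 3 pairs")
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    d = y - x
    if np.ptp(d) == 0:
        if np.all(d == 0):
            raise DegenerateTestError("all paired differences are zero")
        raise DegenerateTestError("paired differences have zero variance")
    two = sps.ttest_rel(y, x)
    one = sps.ttest_rel(y, x, alternative=direction)
    return TestResult(
        statistic=float(two.statistic),
        p_two=float(two.pvalue),
        p_one=float(one.pvalue),
        n=(len(x),),
        test_name="paired_t",
        direction=direction,
    )


def ks_two_sample(
    observed: Sequence[float], null_sample: Sequence[float]
) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    The K-S D statistic has no signed one-tailed variant here, so
    ``p_one = p_two``.
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(null_sample, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("both samples need at least 2 values")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_two=float(res.pvalue),
        p_one=float(res.pvalue),
        n=(len(a), len(b)),
        test_name="ks_two_sample",
    )


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], direction: str = "less"
) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    Reports U for sample ``a``.  The exact null distribution is used when
    the combined sample is at most 20 and tie-free; otherwise the normal
    approximation with tie correction and continuity correction.
    ``direction`` names the one-sided alternative for ``a`` relative to
    ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1 or len(a) + len(b) < 4:
        raise ValidationError("samples too small for Mann-Whitney U")
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    combined = np.concatenate([a, b])
    if np.ptp(combined) == 0:
        raise DegenerateTestError("all values tied across both samples")
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    two = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    one = sps.mannwhitneyu(a, b, alternative=direction, method=method)
    return TestResult(
        statistic=float(two.statistic),
        p_two=float(two.pvalue),
        p_one=float(one.pvalue),
        n=(len(a), len(b)),
        test_name="mann_whitney_u",
        direction=direction,
    )


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], direction: str = "greater"
) -> TestResult:
    """Wilcoxon signed-rank test on paired differences y - x.

    Zero differences are dropped; the exact distribution is used for up to
    25 tie-free nonzero differences.  ``direction`` names the one-sided
    alternative for ``mean(y - x)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d sequences")
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    d = y - x
    nz = d[d != 0]
    if len(nz) == 0:
        raise DegenerateTestError("all paired differences are zero")
    if len(nz) < 5:
        raise ValidationError("need at least 5 nonzero paired differences")
    tie_free = len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if (len(nz) <= 25 and tie_free) else "approx"
    two = sps.wilcoxon(nz, alternative="two-sided", method=method)
    one = sps.wilcoxon(nz, alternative=direction, method=method)
    return TestResult(
        statistic=float(two.statistic),
        p_two=float(two.pvalue),
        p_one=float(one.pvalue),
        n=(len(nz),),
        test_name="wilcoxon_signed_rank",
        direction=direction,
    )
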
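"""Small-sample statistical kit: two-sample t-test (pooled or Welch),
Pearson correlation with p, 2x2 chi-square, and percent reduction with a
delta-method standard error."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

log = logging.getLogger("mbmri")


@dataclass
class GroupComparisonResult:
    """One comparison's outcome: estimate, its standard error, the test
    statistic with degrees of freedom, the two-sided p, and group sizes."""

    estimate: float
    se: float
    statistic: float
    df: float
    p: float
    n: tuple[int, ...]
    statistic_name: str = "t"

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


def _check_sample(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError(f"sample {name} must be 1D with n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"sample {name} contains non-finite values")
    return x


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, variance_mode: str = "pooled"
) -> GroupComparisonResult:
    """Two-sample t-test on independent samples.

    ``pooled`` is the classic equal-variance test with df = n_a + n_b - 2;
    ``welch`` uses the Satterthwaite approximation.  The estimate is
    mean(a) - mean(b).  Groups with zero pooled variance: equal means give
    t = 0, p = 1; unequal means are degenerate.  A note is logged when the
    variance ratio exceeds 4, where the pooled assumption is doubtful.
    """
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    if variance_mode not in ("pooled", "welch"):
        raise ValidationError(f"unknown variance_mode {variance_mode!r}")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    # ptp-based constancy check: the variance of bitwise-identical values
    # can compute as ~1e-31 dust, which must not drive a t statistic
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return GroupComparisonResult(
                estimate=0.0, se=0.0, statistic=0.0,
                df=na + nb - 2, p=1.0, n=(na, nb),
            )
        raise DegenerateDataError(
            "degenerate samples: zero variance with unequal means"
        )
    if max(va, vb) > 4 * max(min(va, vb), np.finfo(float).tiny):
        log.info(
            "group variance ratio exceeds 4 (%.3g vs %.3g); consider "
            "variance_mode='welch'", va, vb,
        )
    res = stats.ttest_ind(a, b, equal_var=(variance_mode == "pooled"))
    if variance_mode == "pooled":
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = float(np.sqrt(sp2 * (1 / na + 1 / nb)))
    else:
        df = float(res.df)
        se = float(np.sqrt(va / na + vb / nb))
    return GroupComparisonResult(
        estimate=diff, se=se, statistic=float(res.statistic), df=float(df),
        p=float(res.pvalue), n=(na, nb),
    )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> GroupComparisonResult:
    """Pearson r with two-sided p from the t-transform at df = n - 2.

    The estimate is r; the standard error reported is the large-sample
    sqrt((1 - r^2) / (n - 2))."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D of equal length")
    if len(x) < 3:
        raise ValidationError("need n >= 3 for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input to correlation")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    n = len(x)
    se = float(np.sqrt(max(1 - r * r, 0.0) / (n - 2)))
    return GroupComparisonResult(
        estimate=r, se=se, statistic=r, df=n - 2, p=float(res.pvalue),
        n=(n,), statistic_name="r",
    )


def chi_square_2x2(table: np.ndarray) -> GroupComparisonResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction.

    df = 1; a warning is logged when any expected count is below 5."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {t.shape}")
    if (t < 0).any():
        raise ValidationError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("zero margin in 2x2 table")
    chi2, p, df, expected = stats.chi2_contingency(t, correction=False)
    if (expected < 5).any():
        log.warning(
            "expected count below 5 (min %.2f); chi-square approximation is "
            "doubtful", expected.min(),
        )
    return GroupComparisonResult(
        estimate=float(chi2), se=float("nan"), statistic=float(chi2),
        df=float(df), p=float(p), n=tuple(int(v) for v in t.sum(axis=1)),
        statistic_name="chi2",
    )


def relative_reduction(
    control: np.ndarray, treated: np.ndarray, variance_mode: str = "pooled"
) -> tuple[float, float, float, float]:
    """Percent reduction of the treated mean relative to control, with a
    delta-method SE for the ratio of independent means.

    Returns (percent_reduction, se_percent, t, p); t and p come from the
    two-sample t-test on the raw samples.
    """
    control = _check_sample(control, "control")
    treated = _check_sample(treated, "treated")
    mc, mt = control.mean(), treated.mean()
    if mc == 0:
        raise ValidationError("zero control mean")
    estimate = 100.0 * (mc - mt) / mc
    vc = control.var(ddof=1) / len(control)
    vt = treated.var(ddof=1) / len(treated)
    # delta method on f(mc, mt) = 100 (1 - mt/mc):
    # df/dmt = -100/mc, df/dmc = 100 mt / mc^2
    se = 100.0 * np.sqrt(vt / mc ** 2 + (mt ** 2 / mc ** 4) * vc)
    if np.ptp(control) == 0 and np.ptp(treated) == 0 and mc != mt:
        # two exact constants with different values: certain difference
        return float(estimate), 0.0, float("inf"), 0.0
    tt = two_sample_ttest(control, treated, variance_mode=variance_mode)
    return float(estimate), float(se), tt.statistic, tt.p
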
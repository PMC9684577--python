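"""Paired method-comparison statistics.

Signed and absolute paired differences with Student t-tests, Bland–Altman
limits of agreement with fixed/proportional bias detection, and a
Monte-Carlo (Lilliefors-style) Kolmogorov–Smirnov normality check for
samples whose normal parameters are estimated from the data.

Conventions: sample SD uses the n-1 denominator throughout; the limits of
agreement use a configurable multiplier k (default 2.0); "fixed bias" means
0 lies outside the limits of agreement; "proportional bias" means the OLS
slope of the per-pair differences on the per-pair means is significant at
alpha (two-sided t-test on the slope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AlignmentError, InsufficientDataError, NumericError


@dataclass(frozen=True)
class PairedComparison:
    """Signed and absolute difference statistics for one method pair.

    ``mean_diff``/``sd_diff`` describe x - y; ``mean_absdiff``/``sd_absdiff``
    describe |x - y|.  ``t_stat``/``p_value`` are the paired two-sided
    Student t-test on the signed differences.
    """

    label: str
    n: int
    mean_diff: float
    sd_diff: float
    mean_absdiff: float
    sd_absdiff: float
    t_stat: float
    p_value: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman agreement summary for one method pair."""

    label: str
    n: int
    mean_diff: float
    sd_diff: float
    k: float
    loa_low: float
    loa_high: float
    fixed_bias: bool
    prop_slope: float
    prop_p: float
    prop_bias: bool
    prop_test_skipped: bool
    means: np.ndarray = field(repr=False)
    diffs: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class NormalityResult:
    """Kolmogorov–Smirnov normality check with Monte-Carlo p-value."""

    label: str
    n: int
    statistic: float
    p_value: float
    method: str
    n_mc: int


def _as_aligned(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise AlignmentError("paired series must be 1-dimensional")
    if x.shape != y.shape:
        raise AlignmentError(f"length mismatch: {x.size} vs {y.size}")
    return x, y


def _paired_t(mean: float, sd: float, n: int) -> tuple[float, float]:
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p


def paired_compare(x, y, label: str = "") -> PairedComparison:
    """Paired comparison of two aligned series (x - y).

    Returns mean/SD of the signed and of the absolute differences plus the
    two-sided paired Student t-test on the signed differences.

    Raises
    ------
    AlignmentError
        If the series differ in length.
    InsufficientDataError
        If fewer than 2 pairs are supplied.
    """
    x, y = _as_aligned(x, y)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"paired comparison needs n >= 2, got {n}")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    t, p = _paired_t(mean_diff, sd_diff, n)
    ad = np.abs(d)
    return PairedComparison(
        label=label,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        mean_absdiff=float(ad.mean()),
        sd_absdiff=float(ad.std(ddof=1)),
        t_stat=t,
        p_value=p,
    )


def bland_altman(x, y, k: float = 2.0, alpha: float = 0.05,
                 label: str = "") -> BlandAltmanResult:
    """Bland–Altman analysis of x vs y.

    Per-pair means (x+y)/2 are plotted against differences x-y; limits of
    agreement are mean_diff ± k*sd_diff.  Fixed bias is flagged when 0 lies
    outside the limits; proportional bias when the OLS slope of differences
    on means is significant at ``alpha``.  With zero variance in the
    per-pair means the proportional test is skipped (``prop_test_skipped``).
    """
    x, y = _as_aligned(x, y)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"Bland-Altman needs n >= 2, got {n}")
    means = (x + y) / 2.0
    diffs = x - y
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    loa_low = mean_diff - k * sd_diff
    loa_high = mean_diff + k * sd_diff
    fixed_bias = bool(loa_low > 0.0 or loa_high < 0.0)

    skipped = False
    means_const = float(np.ptp(means)) <= 1e-12 * max(1.0, float(np.abs(means).max()))
    diffs_const = float(np.ptp(diffs)) <= 1e-12 * max(1.0, float(np.abs(diffs).max()))
    if means_const or n < 3:
        slope, prop_p, skipped = math.nan, math.nan, True
    elif diffs_const:
        slope, prop_p = 0.0, 1.0
    else:
        fit = stats.linregress(means, diffs)
        slope, prop_p = float(fit.slope), float(fit.pvalue)
    prop_bias = bool((not skipped) and prop_p < alpha)
    return BlandAltmanResult(
        label=label,
        n=n,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        k=k,
        loa_low=loa_low,
        loa_high=loa_high,
        fixed_bias=fixed_bias,
        prop_slope=slope,
        prop_p=prop_p,
        prop_bias=prop_bias,
        prop_test_skipped=skipped,
        means=means,
        diffs=diffs,
    )


def _ks_statistic_estimated(samples: np.ndarray) -> np.ndarray:
    """KS distance of each row to a normal with that row's own mean/SD (n-1).

    Vectorized over rows; this exact statistic (not an asymptotic
    approximation) is used both for the data and for the Monte-Carlo null
    replicates, so the p-value is internally consistent.
    """
    samples = np.atleast_2d(samples)
    m, n = samples.shape
    mu = samples.mean(axis=1, keepdims=True)
    sd = samples.std(axis=1, ddof=1, keepdims=True)
    z = np.sort((samples - mu) / sd, axis=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def ks_normality(x, n_mc: int = 10000, seed: int | None = None,
                 label: str = "") -> NormalityResult:
    """Normality check: KS distance to a normal with estimated parameters.

    Because mean and SD are estimated from the sample, the naive KS null
    distribution is wrong; the p-value is obtained by Monte-Carlo
    (Lilliefors-style): ``n_mc`` standard-normal samples of the same size
    are scored with the identical statistic and
    p = (1 + #{D_sim >= D}) / (n_mc + 1).

    Raises
    ------
    InsufficientDataError
        If n < 5.
    NumericError
        If the series is (numerically) constant.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 5:
        raise InsufficientDataError(f"normality check needs n >= 5, got {n}")
    if float(x.std(ddof=1)) == 0.0:
        raise NumericError("normality check is degenerate on a constant series")
    d = float(_ks_statistic_estimated(x[None, :])[0])
    rng = np.random.default_rng(seed)
    sims = rng.standard_normal((n_mc, n))
    d_sim = _ks_statistic_estimated(sims)
    p = (1.0 + float(np.count_nonzero(d_sim >= d))) / (n_mc + 1.0)
    return NormalityResult(
        label=label, n=n, statistic=d, p_value=p,
        method="ks-montecarlo-lilliefors", n_mc=n_mc,
    )


def compare_correction_effect(diff_uncorrected, diff_corrected,
                              label: str = "") -> PairedComparison:
    """Paired test of whether a correction shrinks the per-eye discrepancy.

    Both inputs are per-eye DCT-GAT differences (signed or already
    absolute); the statistic is computed on |d_corrected| - |d_uncorrected|,
    so a negative mean means the correction improved agreement.
    """
    du, dc = _as_aligned(diff_uncorrected, diff_corrected)
    return paired_compare(np.abs(dc), np.abs(du), label=label)


__all__ = [
    "PairedComparison",
    "BlandAltmanResult",
    "NormalityResult",
    "paired_compare",
    "bland_altman",
    "ks_normality",
    "compare_correction_effect",
]
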
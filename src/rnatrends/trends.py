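"""Linear age trends and slope-homogeneity testing.

All regressions in this package run on per-age aggregated means (one point
per age, equal weights), not on per-sample values: with ~5-6 genetically
heterogeneous animals per tissue x age cell, the replicate level is too noisy
for pointwise modelling, while the aggregated 10-point series is where the
study-level statistics (slopes, Pearson r, slope-comparison F) live.

Two regression slopes are compared with the classical pooled-variance test
(the two-group ANCOVA interaction test): under H0 of equal slopes,

    F = ((b1 - b2) / se_diff)^2,   se_diff^2 = s2 * (1/Sxx1 + 1/Sxx2),
    s2 = (RSS1 + RSS2) / (n1 + n2 - 4),

is F-distributed with (1, n1 + n2 - 4) degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .aggregate import AgeSeries

__all__ = [
    "TrendFit",
    "SlopeComparison",
    "SegmentResult",
    "fit_line",
    "compare_slopes",
    "segment_fits",
    "segmented_analysis",
]


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of mean production against age (months).

    ``slope`` is in expression units per month; ``t = slope / slope_se``;
    ``p`` is two-sided from Student's t with ``n - 2`` df; ``r`` is the
    Pearson correlation of the same (age, value) pairs with its own
    two-sided ``r_p``. ``rss`` and ``sxx`` are kept because the
    slope-comparison F statistic is built from them.
    """

    n: int
    slope: float
    intercept: float
    slope_se: float
    t: float
    p: float
    r: float
    r_p: float
    rss: float
    sxx: float
    degenerate: bool = False

    def predict(self, age: float) -> float:
        """Fitted value at ``age``."""
        return self.intercept + self.slope * age


@dataclass(frozen=True)
class SlopeComparison:
    """Pooled-variance F test for equality of two regression slopes."""

    slope_diff: float
    f: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class SegmentResult:
    """Per-interval fits for two groups plus their slope comparison."""

    interval: tuple[float, float]
    fit_a: TrendFit
    fit_b: TrendFit
    comparison: SlopeComparison


def fit_line(ages, values) -> TrendFit:
    """Ordinary least squares of ``values`` on ``ages``.

    Parameters
    ----------
    ages, values
        Equal-length 1-D sequences; one aggregated mean per age.

    Raises
    ------
    ValueError
        If fewer than 3 points or the ages have zero variance.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("ages and values must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 age points, got {n}")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("zero variance in ages")

    if np.allclose(y, y[0]):
        # Flat series: slope 0 with no residual information; Pearson r is
        # undefined and reported as 0 with p = 1.
        return TrendFit(
            n=n, slope=0.0, intercept=float(y[0]), slope_se=0.0, t=0.0,
            p=1.0, r=0.0, r_p=1.0, rss=0.0, sxx=sxx, degenerate=True,
        )

    ls = stats.linregress(x, y)
    resid = y - (ls.intercept + ls.slope * x)
    rss = float(resid @ resid)
    if rss <= 1e-12 * float(y @ y):
        # Perfect fit: zero residual variance, infinite t. Flagged rather
        # than raised; common on noiseless synthetic fixtures.
        return TrendFit(
            n=n, slope=float(ls.slope), intercept=float(ls.intercept),
            slope_se=0.0, t=math.inf if ls.slope > 0 else -math.inf,
            p=0.0, r=float(np.sign(ls.slope)), r_p=0.0,
            rss=0.0, sxx=sxx, degenerate=True,
        )

    r, r_p = stats.pearsonr(x, y)
    slope_se = float(ls.stderr)
    return TrendFit(
        n=n,
        slope=float(ls.slope),
        intercept=float(ls.intercept),
        slope_se=slope_se,
        t=float(ls.slope / slope_se),
        p=float(ls.pvalue),
        r=float(r),
        r_p=float(r_p),
        rss=rss,
        sxx=sxx,
    )


def compare_slopes(fit_a: TrendFit, fit_b: TrendFit) -> SlopeComparison:
    """Test equality of two regression slopes (pooled residual variance).

    Degenerate zero-residual comparisons (both fits perfect) return an
    explicit flag with F = inf (p -> 0) for unequal slopes or F = 0 (p = 1)
    for identical slopes, instead of raising.
    """
    df2 = fit_a.n + fit_b.n - 4
    if df2 <= 0:
        raise ValueError(f"non-positive denominator df: {df2}")
    diff = fit_a.slope - fit_b.slope
    s2 = (fit_a.rss + fit_b.rss) / df2
    if s2 == 0.0:
        if diff == 0.0:
            return SlopeComparison(0.0, 0.0, 1, df2, 1.0, degenerate=True)
        return SlopeComparison(diff, math.inf, 1, df2, 0.0, degenerate=True)
    se_diff2 = s2 * (1.0 / fit_a.sxx + 1.0 / fit_b.sxx)
    f = diff * diff / se_diff2
    p = float(stats.f.sf(f, 1, df2))
    return SlopeComparison(float(diff), float(f), 1, df2, p)


def _segment(series: "AgeSeries", lo: float, hi: float) -> TrendFit:
    sel = (series.ages >= lo) & (series.ages <= hi)
    return fit_line(series.ages[sel], series.mean[sel])


def segment_fits(series: "AgeSeries", breakpoint: float = 9.0) -> tuple[TrendFit, TrendFit]:
    """Early/late fits on the closed segments around ``breakpoint``.

    The breakpoint age belongs to both segments, so a 10-age grid split at
    9 months yields a 4-point early fit and a 7-point late fit.
    """
    ages = series.ages
    if breakpoint not in ages:
        raise ValueError(f"breakpoint {breakpoint} is not a grid age")
    return (
        _segment(series, ages[0], breakpoint),
        _segment(series, breakpoint, ages[-1]),
    )


def segmented_analysis(
    series_a: "AgeSeries",
    series_b: "AgeSeries",
    breakpoint: float = 9.0,
) -> dict[tuple[float, float], SegmentResult]:
    """A-priori segmented comparison of two groups around a fixed breakpoint.

    Returns a mapping from the closed interval ``(start, end)`` to the two
    per-group fits and their slope comparison. The breakpoint must be one of
    the grid ages and each side must contain at least 3 ages.
    """
    if not np.array_equal(series_a.ages, series_b.ages):
        raise ValueError("series have different age grids")
    early_a, late_a = segment_fits(series_a, breakpoint)
    early_b, late_b = segment_fits(series_b, breakpoint)
    first, last = float(series_a.ages[0]), float(series_a.ages[-1])
    return {
        (first, float(breakpoint)): SegmentResult(
            (first, float(breakpoint)), early_a, early_b, compare_slopes(early_a, early_b)
        ),
        (float(breakpoint), last): SegmentResult(
            (float(breakpoint), last), late_a, late_b, compare_slopes(late_a, late_b)
        ),
    }
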
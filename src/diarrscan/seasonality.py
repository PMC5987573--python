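"""Seasonal-trend decomposition by ratio to centered moving average.

The classical multiplicative decomposition for monthly series: a 12-term
moving average is centered by averaging two adjacent placements (weights
1/24, 1/12 x 10, 1/24), the ratio of the series to this smooth estimates
the seasonal factor, calendar-month averages of the ratios (renormalized
to mean 1) give the 12 seasonal indices, and an ordinary least-squares
line through the deseasonalized series gives the trend.

The CMA reproduces any affine series exactly at interior points and
annihilates any zero-mean 12-month-periodic component, which is exactly
why it is the standard pre-smoother for monthly surveillance rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CMA_WEIGHTS = np.r_[1.0, np.full(11, 2.0), 1.0] / 24.0  # = avg of two 12-means


@dataclass(frozen=True)
class SeasonalFit:
    """Result of a multiplicative seasonal decomposition.

    seasonal_index has one entry per calendar month (index 0 = the series'
    first calendar month) and averages to 1; trend is the OLS line
    deseasonalized(t) ~ slope * t + intercept with t the 1-based month
    index.
    """

    seasonal_index: np.ndarray
    trend_slope: float
    trend_intercept: float
    smoothed: np.ndarray
    deseasonalized: np.ndarray

    def reseasonalize(self) -> np.ndarray:
        """Inverse transform: deseasonalized * index, reproduces the input."""
        n = self.deseasonalized.size
        idx = np.resize(self.seasonal_index, n)
        return self.deseasonalized * idx


def centered_moving_average(series, window: int = 12) -> np.ndarray:
    """Centered moving average of an even-window monthly series.

    For window=12 this is the average of the two 12-term means straddling
    each month, i.e. a 13-term weighted mean with half weight on the two
    end terms.  Output is aligned to the series center and is
    ``len(series) - window`` long (the first and last window/2 months have
    no centered value).
    """
    x = np.asarray(series, dtype=float)
    if window != 12:
        w = np.r_[1.0, np.full(window - 1, 2.0), 1.0] / (2.0 * window)
    else:
        w = _CMA_WEIGHTS
    if x.size <= window:
        raise ValueError(f"series must be longer than window={window}")
    return np.convolve(x, w[::-1], mode="valid")


def seasonal_decompose(series) -> SeasonalFit:
    """Multiplicative ratio-to-CMA decomposition of a monthly series.

    The series must be strictly positive (multiplicative model) and at
    least 24 months long so every calendar month appears at least once in
    the CMA-covered interior.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 24:
        raise ValueError("series must cover at least 24 months")
    if np.any(x <= 0):
        raise ValueError("multiplicative decomposition requires positive values")

    cma = centered_moving_average(x, window=12)
    # cma[k] is centered on month k+6; months 0..5 and n-6..n-1 are uncovered
    interior = np.arange(6, x.size - 6)
    ratios = x[interior] / cma

    index = np.empty(12)
    months = interior % 12
    for m in range(12):
        index[m] = ratios[months == m].mean()
    index /= index.mean()

    deseason = x / np.resize(index, x.size)
    t = np.arange(1, x.size + 1, dtype=float)
    slope, intercept = np.polynomial.polynomial.polyfit(t, deseason, 1)[::-1]
    return SeasonalFit(
        seasonal_index=index,
        trend_slope=float(slope),
        trend_intercept=float(intercept),
        smoothed=cma,
        deseasonalized=deseason,
    )
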
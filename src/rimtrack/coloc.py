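"""Costes automatic thresholding and thresholded Manders coefficients.

Costes' procedure regresses channel 2 on channel 1 by orthogonal (total
least squares) regression, then walks a linked threshold pair down the
regression line — stepping channel 1's threshold through its distinct
observed intensities from the maximum — until the pixels below BOTH
thresholds are uncorrelated (Pearson r <= 0). The thresholded Manders
coefficients tM1/tM2 then report what fraction of each channel's total
intensity lies in pixels where the OTHER channel exceeds its threshold.

All statistics are restricted to the tissue ROI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Micrograph, RegionOfInterest

__all__ = [
    "ColocResult",
    "orthogonal_regression",
    "costes_threshold",
    "manders_coefficients",
    "colocalize",
]

MIN_BELOW_PAIRS = 10  # fewer below-threshold pairs than this ends the search


@dataclass
class ColocResult:
    """Regression line, linked Costes thresholds, and Manders coefficients.

    ``threshold_ch2 = slope * threshold_ch1 + intercept`` holds exactly.
    ``pearson_below`` is the correlation of the below-threshold pixel pairs
    at convergence; ``converged`` is False when no threshold made the
    below-pairs uncorrelated (thresholds then sit at the channel minimum).
    """

    slope: float
    intercept: float
    threshold_ch1: float
    threshold_ch2: float
    converged: bool
    pearson_below: float
    n_pixels: int
    tM1: float = float("nan")
    tM2: float = float("nan")


def _roi_values(
    ch1: Micrograph, ch2: Micrograph, roi: RegionOfInterest
) -> tuple[np.ndarray, np.ndarray]:
    if ch1.shape != ch2.shape or ch1.shape != roi.shape:
        raise ValueError("channels and ROI must be congruent")
    roi.require_nonempty()
    x = np.asarray(ch1.pixels, dtype=float)[roi.mask]
    y = np.asarray(ch2.pixels, dtype=float)[roi.mask]
    return x, y


def orthogonal_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Total-least-squares line y = slope*x + intercept (major axis).

    The slope is the direction of the leading eigenvector of the 2x2
    covariance matrix, i.e. it minimizes perpendicular distances, the
    regression Costes' method prescribes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.var(x)
    syy = np.var(y)
    sxy = np.cov(x, y, bias=True)[0, 1]
    if sxx == 0:
        raise ValueError("channel 1 is constant within the ROI")
    if syy == 0:
        raise ValueError("channel 2 is constant within the ROI")
    if sxy == 0:
        slope = 0.0
    else:
        slope = (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return float(slope), intercept


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def costes_threshold(
    ch1: Micrograph, ch2: Micrograph, roi: RegionOfInterest
) -> ColocResult:
    """Linked automatic thresholds by Costes' descending search.

    Starting at the channel-1 maximum, the candidate threshold T1 steps
    down through the distinct observed channel-1 intensities; at each step
    the below set is ``ch1 < T1 AND ch2 < slope*T1 + intercept``, and the
    search stops at the largest T1 whose below-set Pearson r is <= 0. A
    below set smaller than 10 pairs, or an undefined r at the smallest
    candidate, leaves the thresholds at the channel minimum with
    ``converged=False``.
    """
    x, y = _roi_values(ch1, ch2, roi)
    if x.size < 50:
        raise ValueError(f"ROI has only {x.size} pixels; need >= 50")
    slope, intercept = orthogonal_regression(x, y)

    candidates = np.unique(x)[::-1]  # descending distinct intensities
    result_t1: Optional[float] = None
    pearson_at_stop = float("nan")
    for t1 in candidates:
        below = (x < t1) & (y < slope * t1 + intercept)
        n_below = int(below.sum())
        if n_below < MIN_BELOW_PAIRS:
            break
        r = _pearson(x[below], y[below])
        if np.isnan(r):
            continue
        if r <= 0:
            result_t1 = float(t1)
            pearson_at_stop = r
            break
    if result_t1 is None:
        t1 = float(x.min())
        return ColocResult(
            slope=slope,
            intercept=intercept,
            threshold_ch1=t1,
            threshold_ch2=slope * t1 + intercept,
            converged=False,
            pearson_below=pearson_at_stop,
            n_pixels=int(x.size),
        )
    return ColocResult(
        slope=slope,
        intercept=intercept,
        threshold_ch1=result_t1,
        threshold_ch2=slope * result_t1 + intercept,
        converged=True,
        pearson_below=pearson_at_stop,
        n_pixels=int(x.size),
    )


def manders_coefficients(
    ch1: Micrograph,
    ch2: Micrograph,
    threshold_ch1: float,
    threshold_ch2: float,
    roi: RegionOfInterest,
) -> tuple[float, float]:
    """Thresholded Manders coefficients over the ROI.

    ``tM1`` is the fraction of channel-1 intensity in pixels where channel
    2 exceeds its threshold; ``tM2`` symmetrically. A zero total intensity
    makes the coefficient NaN (undefined), never 0.
    """
    x, y = _roi_values(ch1, ch2, roi)
    sum1 = x.sum()
    sum2 = y.sum()
    tm1 = float(x[y > threshold_ch2].sum() / sum1) if sum1 > 0 else float("nan")
    tm2 = float(y[x > threshold_ch1].sum() / sum2) if sum2 > 0 else float("nan")
    return tm1, tm2


def colocalize(
    ch1: Micrograph, ch2: Micrograph, roi: RegionOfInterest
) -> ColocResult:
    """Full analysis: Costes thresholds, then tM1/tM2 at those thresholds."""
    result = costes_threshold(ch1, ch2, roi)
    tm1, tm2 = manders_coefficients(
        ch1, ch2, result.threshold_ch1, result.threshold_ch2, roi
    )
    result.tM1 = tm1
    result.tM2 = tm2
    return result
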
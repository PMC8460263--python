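"""Whole-organ fluorescence time-course statistics.

Covers the quantities used to describe perilipin dynamics after a high-fat
meal: raw integrated density over the intestine ROI, autofluorescence
correction against wild-type siblings imaged at the same time-point,
brightfield opacity as a lipid-consumption covariate, per-genotype mean
normalization, windowed least-squares regression reporting the signed
Pearson coefficient R, and LOWESS smoothing for visualization. Hypothesis
tests (ANOVA, Kruskal-Wallis) are deliberately not reimplemented — the
tidy per-subject tables are shaped for external statistical software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import Micrograph, RegionOfInterest

__all__ = [
    "TimecoursePoint",
    "RegressionFit",
    "raw_integrated_density",
    "opacity_mean_gray",
    "autofluorescence_correct",
    "linear_fit",
    "normalize_by_group_mean",
    "lowess_smooth",
]

logger = logging.getLogger(__name__)

EARLY_WINDOW = (0.75, 8.5)  # hours post-meal
LATE_WINDOW = (16.0, 30.0)


@dataclass
class TimecoursePoint:
    """One animal's whole-organ measurement at one time-point."""

    subject_id: str
    genotype_label: str
    time_hr: float
    raw_integrated_density: float
    corrected_value: Optional[float] = None  # may be negative: noise around zero
    opacity_mean_gray: Optional[float] = None


@dataclass
class RegressionFit:
    """Ordinary least-squares line over a time window, with signed Pearson R."""

    slope: float
    intercept: float
    r: float
    n: int
    window: tuple[float, float]


def raw_integrated_density(image: Micrograph, roi: RegionOfInterest) -> float:
    """Sum of pixel intensities over the ROI ("raw integrated density")."""
    if image.shape != roi.shape:
        raise ValueError("image and ROI must be congruent")
    roi.require_nonempty()
    return float(np.asarray(image.pixels, dtype=float)[roi.mask].sum())


def opacity_mean_gray(image: Micrograph, roi: RegionOfInterest) -> float:
    """Mean brightfield gray value over the intestine ROI (opacity proxy)."""
    if image.shape != roi.shape:
        raise ValueError("image and ROI must be congruent")
    roi.require_nonempty()
    return float(np.asarray(image.pixels, dtype=float)[roi.mask].mean())


def autofluorescence_correct(
    points: Sequence[TimecoursePoint],
    wild_type_label: str = "wild_type",
) -> list[TimecoursePoint]:
    """Subtract the per-time-point wild-type mean from every measurement.

    The mean raw integrated density of the wild-type siblings at each
    time-point estimates gut autofluorescence; it is subtracted from all
    fish at that time-point, so wild-type corrected values average exactly
    zero per time-point. Every time-point that appears must include at
    least one wild-type fish; fewer than three triggers a warning.
    """
    times = sorted({p.time_hr for p in points})
    wt_mean: dict[float, float] = {}
    for t in times:
        wt = [p.raw_integrated_density for p in points
              if p.time_hr == t and p.genotype_label == wild_type_label]
        if not wt:
            raise ValueError(f"no wild-type measurements at time {t} hr")
        if len(wt) < 3:
            logger.warning(
                "only %d wild-type fish at %s hr; autofluorescence estimate is noisy",
                len(wt), t,
            )
        wt_mean[t] = float(np.mean(wt))
    out = []
    for p in points:
        out.append(
            TimecoursePoint(
                subject_id=p.subject_id,
                genotype_label=p.genotype_label,
                time_hr=p.time_hr,
                raw_integrated_density=p.raw_integrated_density,
                corrected_value=p.raw_integrated_density - wt_mean[p.time_hr],
                opacity_mean_gray=p.opacity_mean_gray,
            )
        )
    return out


def linear_fit(
    x: Sequence[float],
    y: Sequence[float],
    window: Optional[tuple[float, float]] = None,
) -> RegressionFit:
    """Least-squares line over in-window complete pairs, with Pearson R.

    R is the signed correlation coefficient (not R-squared); its sign
    agrees with the slope's whenever the slope is non-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    if window is not None:
        keep &= (x >= window[0]) & (x <= window[1])
    xs, ys = x[keep], y[keep]
    if xs.size < 3:
        raise ValueError(f"need >= 3 in-window pairs, got {xs.size}")
    if np.var(xs) == 0:
        raise ValueError("zero variance in x within the window")
    fit = stats.linregress(xs, ys)
    win = window if window is not None else (float(xs.min()), float(xs.max()))
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n=int(xs.size),
        window=win,
    )


def normalize_by_group_mean(
    table: pd.DataFrame,
    value_columns: Sequence[str],
    group_column: str = "genotype_label",
) -> pd.DataFrame:
    """Divide values by their genotype's overall mean.

    The divisor pools ALL individual data points of the group — every
    value column (e.g. both the droplet-associated and cytoplasmic means)
    across all times — so relative dynamics between genotypes with very
    different expression levels become comparable. The pooled mean of each
    group is exactly 1 afterwards.
    """
    out = table.copy()
    for group, sub in table.groupby(group_column):
        pooled = sub[list(value_columns)].to_numpy(dtype=float).ravel()
        pooled = pooled[np.isfinite(pooled)]
        if pooled.size == 0:
            raise ValueError(f"group {group!r} has no finite values")
        mean = float(pooled.mean())
        if mean == 0:
            raise ValueError(f"group {group!r} has zero mean; cannot normalize")
        idx = table[group_column] == group
        out.loc[idx, list(value_columns)] = table.loc[idx, list(value_columns)] / mean
    return out


def lowess_smooth(
    x: Sequence[float],
    y: Sequence[float],
    frac: float = 0.35,
    n_iter: int = 2,
) -> np.ndarray:
    """LOWESS curve sampled at the input x (visualization only).

    Locally weighted linear regression with tricube weights and ``n_iter``
    bisquare robustness passes. The output is for plotting, not inference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 points for LOWESS")
    if not (0 < frac <= 1):
        raise ValueError("frac must be in (0, 1]")
    return _sm_lowess(y, x, frac=frac, it=n_iter, return_sorted=False)


def points_to_frame(points: Sequence[TimecoursePoint]) -> pd.DataFrame:
    """Tidy per-subject table for export to external statistics software."""
    return pd.DataFrame(
        [
            dict(
                subject_id=p.subject_id,
                genotype_label=p.genotype_label,
                time_hr=p.time_hr,
                raw_integrated_density=p.raw_integrated_density,
                corrected_value=p.corrected_value,
                opacity_mean_gray=p.opacity_mean_gray,
            )
            for p in points
        ]
    )
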
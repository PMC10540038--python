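"""Threshold calibration against ordinal visual PVS ratings.

The segmentation threshold on the IQR-standardized vesselness map is chosen
by sweeping a grid of thresholds (0.5 to 3.3 by default), recomputing each
subject's PVS volume fraction at each threshold, and correlating the
fractions with 0-8 visual PVS scores. The reported optimum is the argmax of
the correlation curve (ties broken toward the smaller threshold — the more
sensitive segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, UndefinedCorrelationError
from .segmentation import (
    SegmentationParams,
    compute_pvs_metrics,
    segment_components,
)
from .volume import RoiMask, Volume


@dataclass
class SubjectMaps:
    """One subject's standardized vesselness map and masks."""

    svmap: Volume
    roi: RoiMask
    wmh: RoiMask | None = None


@dataclass
class CalibrationResult:
    thresholds: np.ndarray
    correlations: np.ndarray        # NaN where undefined
    fractions: np.ndarray           # (n_thresholds, n_subjects)
    optimal_threshold: float
    optimal_r: float

    def as_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "correlations": [None if np.isnan(r) else float(r)
                             for r in self.correlations],
            "optimal_threshold": float(self.optimal_threshold),
            "optimal_r": float(self.optimal_r),
        }


def make_threshold_grid(lo: float = 0.5, hi: float = 3.3,
                        step: float = 0.1) -> np.ndarray:
    """Inclusive arithmetic grid from lo to hi.

    hi is appended when the last regular point falls short by more than half
    a step; lo == hi gives a single value.
    """
    if step <= 0:
        raise ParameterError("step must be > 0")
    if lo > hi:
        raise ParameterError("need lo <= hi")
    if lo == hi:
        return np.array([lo])
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    grid = lo + step * np.arange(n)
    if hi - grid[-1] > step / 2:
        grid = np.append(grid, hi)
    elif not np.isclose(grid[-1], hi):
        grid[-1] = min(grid[-1], hi)
        grid = np.append(grid, hi) if not np.isclose(grid[-1], hi) else grid
    return grid


def sweep_thresholds(subjects: list[SubjectMaps],
                     scores,
                     grid: np.ndarray | None = None,
                     params: SegmentationParams | None = None,
                     statistic: str = "pearson") -> CalibrationResult:
    """Correlate computed volume fractions with visual scores per threshold.

    At each threshold every subject's fraction is recomputed with the full
    component-size filtering chain; the correlation (Pearson by default,
    Spearman optional) across subjects is recorded. Thresholds where the
    fractions are constant get an undefined (NaN) correlation and are
    excluded from the argmax.
    """
    scores = np.asarray(scores, dtype=float)
    if len(subjects) < 3:
        raise ParameterError("need at least 3 subjects to calibrate")
    if len(subjects) != scores.size:
        raise ParameterError("one score per subject required")
    if np.ptp(scores) == 0:
        raise UndefinedCorrelationError("visual scores are all equal")
    if grid is None:
        grid = make_threshold_grid()
    base = params or SegmentationParams()

    fractions = np.zeros((grid.size, len(subjects)))
    for j, subj in enumerate(subjects):
        for i, tau in enumerate(grid):
            p = SegmentationParams(threshold=float(tau),
                                   connectivity=base.connectivity,
                                   min_component_voxels=base.min_component_voxels)
            comp = segment_components(subj.svmap, subj.roi, subj.wmh, p)
            fractions[i, j] = compute_pvs_metrics(
                comp, subj.roi).volume_fraction_pct

    corrs = np.full(grid.size, np.nan)
    for i in range(grid.size):
        f = fractions[i]
        if np.ptp(f) == 0:
            continue
        if statistic == "pearson":
            corrs[i] = sps.pearsonr(f, scores).statistic
        elif statistic == "spearman":
            corrs[i] = sps.spearmanr(f, scores).statistic
        else:
            raise ParameterError(f"unknown statistic {statistic!r}")

    if np.all(np.isnan(corrs)):
        raise UndefinedCorrelationError(
            "correlation undefined at every threshold")
    best = np.nanmax(corrs)
    # ties -> smallest threshold
    idx = int(np.flatnonzero(np.isclose(corrs, best))[0])
    return CalibrationResult(
        thresholds=grid, correlations=corrs, fractions=fractions,
        optimal_threshold=float(grid[idx]), optimal_r=float(corrs[idx]),
    )
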
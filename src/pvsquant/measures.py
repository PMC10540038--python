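"""Scalar covariate transforms feeding the statistical models.

* logWMH = ln(1 + WMH volume / TICV): head-size-adjusted, log-transformed
  white matter hyperintensity burden.
* BPF = (WM + GM) / TICV: brain parenchymal fraction, an atrophy marker.
* achieved SBP: area under the visit-wise systolic blood pressure curve
  (trapezoid between observed visit days) divided by the day span.
* medication exposure: fraction of days on a drug class between
  randomization and the follow-up MRI, with overlapping prescription
  intervals merged before summing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, ParameterError

#: Antihypertensive classes as combined for analysis.
MED_CLASSES = ("acei_arb", "beta_blocker", "ccb", "diuretic")


@dataclass
class SBPSeries:
    """Ordered (day, SBP mmHg) measurements from randomization (day 0)."""

    days: np.ndarray
    sbp: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        if self.days.shape != self.sbp.shape or self.days.ndim != 1:
            raise ParameterError("days and sbp must be matching 1D arrays")
        if np.any(np.diff(self.days) <= 0):
            raise ParameterError("visit days must be strictly increasing")
        if np.any(self.sbp <= 0):
            raise ParameterError("SBP values must be positive")


@dataclass
class MedicationLog:
    """Per-class on-drug intervals (start_day, end_day), inclusive bounds."""

    intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def add(self, cls: str, start_day: float, end_day: float) -> None:
        if start_day > end_day:
            raise ParameterError("interval start must be <= end")
        self.intervals.setdefault(cls, []).append((float(start_day),
                                                   float(end_day)))


def log_wmh(wmh_vol: float, ticv: float) -> float:
    """ln(1 + WMHvol / TICV); both in cm^3."""
    if ticv <= 0:
        raise ParameterError("TICV must be > 0")
    if wmh_vol < 0:
        raise ParameterError("WMH volume must be >= 0")
    return math.log1p(wmh_vol / ticv)


def brain_parenchymal_fraction(wm: float, gm: float, ticv: float) -> float:
    """(WM + GM) / TICV; all in cm^3, result in [0, 1]."""
    if ticv <= 0:
        raise ParameterError("TICV must be > 0")
    if wm < 0 or gm < 0:
        raise ParameterError("tissue volumes must be >= 0")
    if wm + gm > ticv * (1 + 1e-12):
        raise ParameterError("WM + GM exceeds TICV")
    return (wm + gm) / ticv


def achieved_sbp(series: SBPSeries) -> float:
    """Time-averaged SBP: trapezoidal AUC over the observed span / span days."""
    if series.days.size < 2:
        raise InsufficientDataError("achieved SBP needs >= 2 measurements")
    span = series.days[-1] - series.days[0]
    auc = np.trapezoid(series.sbp, series.days)
    return float(auc / span)


def _union_length(intervals: Iterable[tuple[float, float]],
                  lo: float, hi: float) -> float:
    clipped = sorted((max(a, lo), min(b, hi)) for a, b in intervals)
    total, cur_a, cur_b = 0.0, None, None
    for a, b in clipped:
        if b <= a:
            continue
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a
    return total


def medication_exposure(log: MedicationLog, cls: str,
                        followup_day: float) -> float:
    """Fraction of days on the class in [0, followup_day], in [0, 1]."""
    if followup_day <= 0:
        raise ParameterError("followup_day must be > 0")
    ivals = log.intervals.get(cls, [])
    for a, b in ivals:
        if b > followup_day or a < 0:
            warnings.warn(
                f"{cls}: interval ({a}, {b}) clipped to [0, {followup_day}]",
                stacklevel=2)
    length = _union_length(ivals, 0.0, followup_day)
    return float(min(max(length / followup_day, 0.0), 1.0))
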
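"""Sigmoid pressure-time exposure stratification.

Sustained interface pressure is tolerated for shorter times the higher it
is: the classic pressure-time injury relationship is high at short
exposures and decays sigmoidally to a long-time plateau. Three ordered
boundary curves in the (duration, magnitude) plane split that plane into
four exposure categories — low, moderate, high, very high. Each curve is a
logistic decay

    B_k(t) = F_k + (S_k - F_k) / (1 + exp(alpha * (t - t0)))

where S_k is the curve's starting (short-exposure) pressure, F_k its
long-time floor (``floor_fraction * S_k``), ``alpha`` the steepness in 1/h
and ``t0`` the inflection time in hours. Default starting pressures are
25/35/45 mmHg/cm for the peak pressure gradient and 70/90/110 mmHg for the
peak pressure index; the remaining parameters are configurable engineering
defaults with no claim of physiological validity.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.special import expit

from .roi import PostureSignature


class ExposureCategory(IntEnum):
    """Ordered exposure levels: number of boundary curves exceeded."""

    LOW = 0
    MODERATE = 1
    HIGH = 2
    VERY_HIGH = 3

    @property
    def label(self) -> str:
        return self.name.lower()


CATEGORY_LABELS = tuple(c.label for c in ExposureCategory)


@dataclass(frozen=True)
class SigmoidThresholds:
    """The three ordered pressure-time boundary curves for one signature."""

    signature_type: Literal["ppg", "ppi"]
    p_start: tuple[float, float, float]
    floor_fraction: float = 0.4
    alpha_per_h: float = 2.0
    t0_h: float = 2.0

    def __post_init__(self) -> None:
        if not (self.p_start[0] < self.p_start[1] < self.p_start[2]):
            raise ValueError("starting pressures must be strictly increasing")
        if not (0 <= self.floor_fraction < 1):
            raise ValueError("floor_fraction must be in [0, 1)")
        if self.alpha_per_h <= 0:
            raise ValueError("alpha_per_h must be > 0")
        if self.t0_h < 0:
            raise ValueError("t0_h must be >= 0")

    @classmethod
    def ppg_default(cls) -> "SigmoidThresholds":
        return cls("ppg", (25.0, 35.0, 45.0))

    @classmethod
    def ppi_default(cls) -> "SigmoidThresholds":
        return cls("ppi", (70.0, 90.0, 110.0))

    def start(self, k: int) -> float:
        return self.p_start[k - 1]

    def floor(self, k: int) -> float:
        return self.floor_fraction * self.p_start[k - 1]


@dataclass
class ExposureSummary:
    """Fraction of the monitoring period in each exposure category."""

    fractions: dict[str, float]
    monitoring_hours: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {total}, not 1")

    def hours(self, category: str) -> float:
        return self.fractions[category] * self.monitoring_hours


def boundary(t_h: float | np.ndarray, k: int, thr: SigmoidThresholds) -> float | np.ndarray:
    """Boundary pressure of curve k (1..3) at exposure duration `t_h` hours.

    Strictly decreasing in t, from near the starting pressure S_k at t = 0
    (exactly S_k in the limit alpha * t0 -> inf) to the floor F_k.
    """
    S = thr.start(k)
    F = thr.floor(k)
    # expit(-x) = 1/(1+exp(x)), overflow-safe for long exposures
    return F + (S - F) * expit(-thr.alpha_per_h * (np.asarray(t_h) - thr.t0_h))


def categorize(
    duration_h: float, magnitude: float, thr: SigmoidThresholds
) -> ExposureCategory:
    """Exposure category of a posture at its (duration, magnitude) point.

    The level is the number of boundary curves the magnitude strictly
    exceeds at that duration: 0 -> low ... 3 -> very high.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be > 0")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    level = sum(magnitude > boundary(duration_h, k, thr) for k in (1, 2, 3))
    return ExposureCategory(level)


def crossing_time(magnitude: float, k: int, thr: SigmoidThresholds) -> Optional[float]:
    """Duration (hours) at which curve k decays to `magnitude`.

    Returns ``None`` when the magnitude is at or below the curve's floor
    (never crossed), 0.0 when it already exceeds the curve at t = 0, and
    otherwise the unique t* with ``boundary(t*, k) = magnitude``.
    """
    S = thr.start(k)
    F = thr.floor(k)
    if magnitude <= F:
        return None
    b0 = float(boundary(0.0, k, thr))
    if magnitude >= b0:
        return 0.0
    return thr.t0_h + np.log((S - F) / (magnitude - F) - 1.0) / thr.alpha_per_h


def exposure_summary(
    signatures: Sequence[PostureSignature],
    thr_ppg: SigmoidThresholds = SigmoidThresholds.ppg_default(),
    thr_ppi: SigmoidThresholds = SigmoidThresholds.ppi_default(),
    mode: Literal["posture", "resolved"] = "posture",
) -> tuple[ExposureSummary, ExposureSummary]:
    """Time-in-category summaries for PPG and PPI over one recording.

    ``mode="posture"`` accrues each posture's full duration to the category
    of its (duration, mean magnitude) point — one marker per posture against
    the curves. ``mode="resolved"`` partitions each posture's timeline at
    the crossing times of its mean magnitude with the three curves, so a
    long posture accrues low-category time early and higher-category time
    once the curves have decayed below its magnitude. Fractions are
    normalised by the total monitoring hours and sum to 1 in both modes.
    """
    if not signatures:
        raise ValueError("no posture signatures to summarise")
    if mode not in ("posture", "resolved"):
        raise ValueError("mode must be 'posture' or 'resolved'")
    out = []
    for thr, attr in ((thr_ppg, "ppg_mean"), (thr_ppi, "ppi_mean")):
        hours_in = np.zeros(4)
        for sig in signatures:
            magnitude = getattr(sig, attr)
            if mode == "posture":
                cat = categorize(sig.duration_h, magnitude, thr)
                hours_in[cat] += sig.duration_h
            else:
                hours_in += _resolved_hours(sig.duration_h, magnitude, thr)
        total = hours_in.sum()
        fractions = {c.label: float(hours_in[c] / total) for c in ExposureCategory}
        out.append(ExposureSummary(fractions, float(total)))
    return out[0], out[1]


def _resolved_hours(
    duration_h: float, magnitude: float, thr: SigmoidThresholds
) -> np.ndarray:
    """Split one posture's [0, duration) among categories by crossing times.

    Curve k is exceeded for t > t*_k (curves decrease monotonically), so the
    category at time t is the count of crossing times at or below t.
    """
    stars = []
    for k in (1, 2, 3):
        t = crossing_time(magnitude, k, thr)
        stars.append(np.inf if t is None else t)
    bounds = np.clip(sorted(stars), 0.0, duration_h)
    edges = np.r_[0.0, bounds, duration_h]
    hours = np.zeros(4)
    for level in range(4):
        hours[level] = max(0.0, edges[level + 1] - edges[level])
    return hours
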
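"""Buttock region of interest and per-frame pressure signatures.

For each static posture the buttock/sacral region is located by anchoring a
fixed-size sensel window (default 30 along the long body axis by 20 across
the width: 47.7 x 31.8 cm at 15.9 mm pitch) on the segment's median centre
of pressure. Within that window three signatures are computed per frame:

* peak pressure — the maximum sensel pressure (mmHg);
* peak pressure index (PPI) — the mean of the 10 highest pressures (mmHg);
* peak pressure gradient (PPG) — the maximum absolute pressure difference
  between diagonally adjacent sensels divided by their centre-to-centre
  distance sqrt(2) * pitch, in mmHg/cm.

Per-posture descriptors are the mean and sample SD of each per-frame series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MatGeometry, PressureSequence, ValidationError
from .posture import DEFAULT_COP_FLOOR_MMHG, PostureSegment


class RoiError(ValueError):
    """The requested ROI cannot be realised on this mat."""


@dataclass(frozen=True)
class RoiSpec:
    """ROI extent in sensels: `len_sensels` along the long axis (columns),
    `wid_sensels` across the width (rows)."""

    len_sensels: int = 30
    wid_sensels: int = 20

    def __post_init__(self) -> None:
        if self.len_sensels * self.wid_sensels < 10:
            raise RoiError("ROI must contain at least 10 sensels (PPI needs 10)")

    def physical_extent_cm(self, geometry: MatGeometry) -> tuple[float, float]:
        """(length, width) of the window in cm at the mat's pitch."""
        return (
            self.len_sensels * geometry.pitch_cm,
            self.wid_sensels * geometry.pitch_cm,
        )


@dataclass(frozen=True)
class RoiPlacement:
    """Top-left sensel (0-based, inclusive) of a placed ROI window."""

    row0: int
    col0: int
    clipped: bool = False


@dataclass
class SignatureSeries:
    """Per-frame signatures inside one posture's ROI."""

    ppg_mmHg_per_cm: np.ndarray
    ppi_mmHg: np.ndarray
    peak_mmHg: np.ndarray


@dataclass(frozen=True)
class PostureSignature:
    """Per-posture descriptors: duration plus mean +/- sample SD signatures."""

    duration_h: float
    ppg_mean: float
    ppg_sd: float
    ppi_mean: float
    ppi_sd: float
    peak_mean: float

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValidationError("posture duration must be positive")


def place_window(
    cop_row: float, cop_col: float, spec: RoiSpec, geometry: MatGeometry
) -> RoiPlacement:
    """Centre the window on a COP and clip it minimally into the grid.

    Even-extent convention: for extent e the window spans
    ``centre - floor(e/2) .. centre + ceil(e/2) - 1`` (centre rounded to the
    nearest sensel). When the window would overhang the mat it is shifted by
    the minimum amount to fit and flagged ``clipped``.
    """
    if spec.wid_sensels > geometry.n_rows or spec.len_sensels > geometry.n_cols:
        raise RoiError(
            f"ROI {spec.wid_sensels}x{spec.len_sensels} exceeds grid "
            f"{geometry.n_rows}x{geometry.n_cols}"
        )
    cr = int(round(cop_row))
    cc = int(round(cop_col))
    row0 = cr - spec.wid_sensels // 2
    col0 = cc - spec.len_sensels // 2
    row0c = int(np.clip(row0, 0, geometry.n_rows - spec.wid_sensels))
    col0c = int(np.clip(col0, 0, geometry.n_cols - spec.len_sensels))
    return RoiPlacement(row0c, col0c, clipped=(row0c != row0 or col0c != col0))


def locate_roi(
    seq: PressureSequence,
    segment: PostureSegment,
    spec: RoiSpec = RoiSpec(),
    cop_floor_mmHg: float = DEFAULT_COP_FLOOR_MMHG,
) -> RoiPlacement:
    """Anchor the buttock ROI for one posture on its median COP.

    One placement per segment, fixed for all its frames: the per-frame COP
    is computed over the segment, its coordinate-wise median is rounded to
    the nearest sensel, and the window is centred there (clipped to fit).
    """
    lo, hi = _segment_frame_range(seq, segment)
    v = np.asarray(seq.values[lo:hi], dtype=float)
    w = np.where(v > cop_floor_mmHg, v, 0.0)
    totals = w.sum(axis=(1, 2))
    if (totals == 0).any():
        raise ValidationError("segment contains an unloaded frame (no COP)")
    rows = np.arange(v.shape[1])
    cols = np.arange(v.shape[2])
    med_r = float(np.median((w.sum(axis=2) @ rows) / totals))
    med_c = float(np.median((w.sum(axis=1) @ cols) / totals))
    return place_window(med_r, med_c, spec, seq.geometry)


def _segment_frame_range(seq: PressureSequence, segment: PostureSegment) -> tuple[int, int]:
    t = np.asarray(seq.timestamps)
    lo = int(np.searchsorted(t, segment.start_s, side="left"))
    hi = int(np.searchsorted(t, segment.end_s, side="left"))
    if hi <= lo:
        raise ValidationError("segment contains no frames")
    return lo, hi


def _window(frame: np.ndarray, placement: RoiPlacement, spec: RoiSpec) -> np.ndarray:
    return np.asarray(frame, dtype=float)[
        placement.row0 : placement.row0 + spec.wid_sensels,
        placement.col0 : placement.col0 + spec.len_sensels,
    ]


def ppi_frame(
    frame: np.ndarray, placement: RoiPlacement, spec: RoiSpec = RoiSpec()
) -> float:
    """Peak pressure index: mean of the 10 highest pressures in the ROI."""
    w = _window(frame, placement, spec).ravel()
    if w.size < 10:
        raise RoiError("PPI needs at least 10 cells in the ROI")
    top10 = np.partition(w, -10)[-10:]
    return float(top10.mean())


def ppg_frame(
    frame: np.ndarray,
    placement: RoiPlacement,
    geometry: MatGeometry,
    spec: RoiSpec = RoiSpec(),
) -> float:
    """Peak pressure gradient over diagonally adjacent sensels, mmHg/cm.

    Both diagonal orientations enter the maximum; the centre-to-centre
    spacing of diagonal neighbours is sqrt(2) * pitch.
    """
    w = _window(frame, placement, spec)
    if w.shape[0] < 2 or w.shape[1] < 2:
        raise RoiError("PPG needs an ROI of at least 2x2 sensels")
    d1 = np.abs(w[1:, 1:] - w[:-1, :-1])
    d2 = np.abs(w[1:, :-1] - w[:-1, 1:])
    diag_cm = np.sqrt(2.0) * geometry.pitch_cm
    return float(max(d1.max(), d2.max()) / diag_cm)


def peak_frame(
    frame: np.ndarray, placement: RoiPlacement, spec: RoiSpec = RoiSpec()
) -> float:
    """Peak pressure: maximum sensel pressure inside the ROI."""
    w = _window(frame, placement, spec)
    if w.size == 0:
        raise RoiError("empty ROI")
    return float(w.max())


def signature_series(
    seq: PressureSequence,
    segment: PostureSegment,
    placement: RoiPlacement,
    spec: RoiSpec = RoiSpec(),
) -> SignatureSeries:
    """Per-frame PPG/PPI/peak series over one posture segment (vectorised)."""
    lo, hi = _segment_frame_range(seq, segment)
    g = seq.geometry
    slab = np.asarray(
        seq.values[
            lo:hi,
            placement.row0 : placement.row0 + spec.wid_sensels,
            placement.col0 : placement.col0 + spec.len_sensels,
        ],
        dtype=float,
    )
    if slab.shape[1] < 2 or slab.shape[2] < 2:
        raise RoiError("PPG needs an ROI of at least 2x2 sensels")
    d1 = np.abs(slab[:, 1:, 1:] - slab[:, :-1, :-1])
    d2 = np.abs(slab[:, 1:, :-1] - slab[:, :-1, 1:])
    diag_cm = np.sqrt(2.0) * g.pitch_cm
    ppg = np.maximum(d1.max(axis=(1, 2)), d2.max(axis=(1, 2))) / diag_cm
    flat = slab.reshape(slab.shape[0], -1)
    top10 = np.partition(flat, -10, axis=1)[:, -10:]
    ppi = top10.mean(axis=1)
    peak = flat.max(axis=1)
    return SignatureSeries(ppg, ppi, peak)


def posture_signature(
    seq: PressureSequence,
    segment: PostureSegment,
    placement: RoiPlacement,
    spec: RoiSpec = RoiSpec(),
) -> PostureSignature:
    """Mean and sample SD (n-1 denominator) of the per-frame signatures."""
    series = signature_series(seq, segment, placement, spec)
    if len(series.ppi_mmHg) < 2:
        raise ValidationError("posture signature needs at least 2 frames")
    return PostureSignature(
        duration_h=segment.duration_h,
        ppg_mean=float(series.ppg_mmHg_per_cm.mean()),
        ppg_sd=float(series.ppg_mmHg_per_cm.std(ddof=1)),
        ppi_mean=float(series.ppi_mmHg.mean()),
        ppi_sd=float(series.ppi_mmHg.std(ddof=1)),
        peak_mean=float(series.peak_mmHg.mean()),
    )
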
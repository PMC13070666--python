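"""Data model and on-disk formats for pressure-mat recordings.

A recording is a uniformly sampled stack of 2-D interface-pressure frames
(mmHg) from a bed-sized sensing mat. Two interchangeable on-disk formats are
supported behind one read/write API:

* a long-format CSV (``t_s,row,col,pressure_mmHg``) with a YAML metadata
  sidecar — human-inspectable, suited to short recordings;
* an HDF5 container (one 3-D array plus attributes) for long sessions.

Coordinate convention: row index runs across the mat width, column index
along the long (head-to-foot) axis, both 0-based. The physical centre of
cell (r, c) is ((r + 0.5) * pitch, (c + 0.5) * pitch). Timestamps are
seconds since the first frame (first frame at t = 0); all segment intervals
elsewhere in the package are half-open [start, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import h5py
import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file does not conform to the frame-stack format."""


class ValidationError(ValueError):
    """A sequence violates a structural invariant."""


@dataclass(frozen=True)
class MatGeometry:
    """Physical layout of the sensing mat.

    Parameters
    ----------
    n_rows, n_cols
        Sensel counts across the mat width and along its long axis.
    pitch_mm
        Inter-sensel spacing in millimetres.
    sample_rate_hz
        Frames per second.
    """

    n_rows: int = 48
    n_cols: int = 118
    pitch_mm: float = 15.9
    sample_rate_hz: float = 1.0
    pressure_unit: str = "mmHg"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid must have at least one sensel per axis")
        if self.pitch_mm <= 0:
            raise ValidationError("pitch_mm must be positive")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")

    @property
    def pitch_cm(self) -> float:
        return self.pitch_mm / 10.0

    @property
    def cell_area_cm2(self) -> float:
        return self.pitch_cm**2

    @property
    def n_sensels(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def foresite_pt(cls) -> "MatGeometry":
        """Default bed-mat profile: 15.9 mm pitch, 1 Hz, 48 x 118 sensels.

        48 x 118 covers the nominal 762 x 1880 mm sensing area at the stated
        pitch. (The vendor quotes 5556 cells, which no integer row x column
        factorisation of that area reproduces; the grid is therefore
        configuration, never a hard-coded cell count.)
        """
        return cls(n_rows=48, n_cols=118, pitch_mm=15.9, sample_rate_hz=1.0)


@dataclass(frozen=True)
class SessionMeta:
    """Free-text session labels; `phase` is the pre/post intervention factor."""

    patient_id: str = ""
    phase: str = "pre"
    support_surface: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValidationError(f"phase must be 'pre' or 'post', got {self.phase!r}")


@dataclass(frozen=True)
class PressureFrame:
    """One pressure map: a (n_rows, n_cols) grid of mmHg at one timestamp."""

    timestamp: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("frame values must be a 2-D grid")
        object.__setattr__(self, "values", v)


@dataclass
class PressureSequence:
    """Time-ordered stack of pressure frames with mat geometry and metadata.

    Frames are stored densely as ``values`` with shape
    (n_frames, n_rows, n_cols); ``timestamps`` holds seconds since the first
    frame. Iteration yields :class:`PressureFrame` views.
    """

    geometry: MatGeometry
    timestamps: np.ndarray
    values: np.ndarray
    meta: SessionMeta = field(default_factory=SessionMeta)
    jitter_tolerance: float = 0.10

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values)
        problems = validate_sequence(self)
        if problems:
            raise ValidationError("; ".join(problems))

    def __len__(self) -> int:
        return len(self.timestamps)

    def __iter__(self) -> Iterator[PressureFrame]:
        for t, v in zip(self.timestamps, self.values):
            yield PressureFrame(float(t), v)

    def frame(self, i: int) -> PressureFrame:
        return PressureFrame(float(self.timestamps[i]), self.values[i])

    @property
    def duration_s(self) -> float:
        """Monitoring length in seconds, counting the last frame's dwell."""
        return float(len(self) / self.geometry.sample_rate_hz)

    def with_values(self, values: np.ndarray) -> "PressureSequence":
        return replace(self, values=np.asarray(values))


def validate_sequence(seq: PressureSequence) -> list[str]:
    """Return a description of every violated invariant (empty when valid).

    Checks: minimum length, grid shape against the geometry, non-negative
    finite pressures, strictly increasing timestamps, and sampling
    uniformity within the sequence's jitter tolerance.
    """
    problems: list[str] = []
    t = np.asarray(seq.timestamps, dtype=float)
    v = np.asarray(seq.values)
    if t.ndim != 1 or v.ndim != 3 or len(t) != len(v):
        return [
            "frame stack must be (n_frames, n_rows, n_cols) with one timestamp per frame"
        ]
    if len(t) < 2:
        problems.append(f"sequence has {len(t)} frame(s); at least 2 required")
    g = seq.geometry
    if v.shape[1:] != (g.n_rows, g.n_cols):
        problems.append(
            f"frame grid {v.shape[1:]} does not match geometry ({g.n_rows}, {g.n_cols})"
        )
    bad = ~np.isfinite(v)
    if bad.any():
        i = int(np.argwhere(bad.any(axis=(1, 2)))[0][0])
        problems.append(f"non-finite pressure in frame {i}")
    elif (v < 0).any():
        i = int(np.argwhere((v < 0).any(axis=(1, 2)))[0][0])
        problems.append(f"negative pressure in frame {i}")
    if len(t) >= 2:
        dt = np.diff(t)
        if (dt <= 0).any():
            i = int(np.argmax(dt <= 0))
            problems.append(f"timestamps not strictly increasing at frame {i + 1}")
        else:
            nominal = 1.0 / g.sample_rate_hz
            off = np.abs(dt - nominal) > seq.jitter_tolerance * nominal
            if off.any():
                i = int(np.argmax(off))
                problems.append(
                    f"sampling jitter at frame {i + 1}: interval {dt[i]:g} s vs "
                    f"nominal {nominal:g} s (tolerance {seq.jitter_tolerance:.0%})"
                )
    return problems


# ---------------------------------------------------------------------------
# on-disk formats

_CSV_HEADER = ["t_s", "row", "col", "pressure_mmHg"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in (".h5", ".hdf5")


def write_sequence(seq: PressureSequence, path: str | Path) -> None:
    """Write a recording to `path` (CSV + YAML sidecar, or HDF5 by extension).

    The CSV is long-format with header ``t_s,row,col,pressure_mmHg``, frames
    contiguous and row-major within each timestamp; pressures are serialized
    with full float precision so that :func:`read_sequence` round-trips
    bit-faithfully.
    """
    path = Path(path)
    if _is_hdf5(path):
        _write_hdf5(seq, path)
        return
    g, m = seq.geometry, seq.meta
    n = len(seq)
    rows, cols = np.meshgrid(np.arange(g.n_rows), np.arange(g.n_cols), indexing="ij")
    df = pd.DataFrame(
        {
            "t_s": np.repeat(seq.timestamps, g.n_sensels),
            "row": np.tile(rows.ravel(), n),
            "col": np.tile(cols.ravel(), n),
            "pressure_mmHg": np.asarray(seq.values, dtype=float).reshape(-1),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "geometry": {
            "n_rows": g.n_rows,
            "n_cols": g.n_cols,
            "pitch_mm": g.pitch_mm,
            "sample_rate_hz": g.sample_rate_hz,
        },
        "meta": {
            "patient_id": m.patient_id,
            "phase": m.phase,
            "support_surface": m.support_surface,
        },
        "duration_s": seq.duration_s,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=False))


def read_sequence(
    path: str | Path, geometry_override: Optional[MatGeometry] = None
) -> PressureSequence:
    """Read a recording written by :func:`write_sequence`.

    `geometry_override`, when given, wins over the sidecar; a CSV with no
    sidecar and no override raises :class:`FormatError`. Frames whose cell
    count disagrees with the geometry raise :class:`ValidationError` naming
    the offending (0-based) frame index.
    """
    path = Path(path)
    if _is_hdf5(path):
        return _read_hdf5(path, geometry_override)
    sidecar = _sidecar_path(path)
    meta = SessionMeta()
    if sidecar.exists():
        doc = yaml.safe_load(sidecar.read_text())
        gdoc = doc.get("geometry", {})
        geometry = MatGeometry(
            n_rows=int(gdoc["n_rows"]),
            n_cols=int(gdoc["n_cols"]),
            pitch_mm=float(gdoc["pitch_mm"]),
            sample_rate_hz=float(gdoc["sample_rate_hz"]),
        )
        mdoc = doc.get("meta", {}) or {}
        meta = SessionMeta(
            patient_id=str(mdoc.get("patient_id", "")),
            phase=str(mdoc.get("phase", "pre")),
            support_surface=str(mdoc.get("support_surface", "")),
        )
    elif geometry_override is None:
        raise FormatError(f"no metadata sidecar at {sidecar} and no geometry override")
    if geometry_override is not None:
        geometry = geometry_override
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != _CSV_HEADER:
        raise FormatError(f"expected columns {_CSV_HEADER}, got {list(df.columns)}")
    timestamps, counts = np.unique(df["t_s"].to_numpy(), return_counts=True)
    expected = geometry.n_sensels
    for i, c in enumerate(counts):
        if c != expected:
            raise ValidationError(
                f"frame {i} has {c} cells, geometry requires {expected}"
            )
    values = (
        df["pressure_mmHg"].to_numpy(dtype=float)
        .reshape(len(timestamps), geometry.n_rows, geometry.n_cols)
    )
    return PressureSequence(geometry, timestamps, values, meta)


def _write_hdf5(seq: PressureSequence, path: Path) -> None:
    g, m = seq.geometry, seq.meta
    with h5py.File(path, "w") as f:
        f.create_dataset("pressure_mmHg", data=np.asarray(seq.values))
        f.create_dataset("t_s", data=np.asarray(seq.timestamps, dtype=float))
        f.attrs.update(
            {
                "n_rows": g.n_rows,
                "n_cols": g.n_cols,
                "pitch_mm": g.pitch_mm,
                "sample_rate_hz": g.sample_rate_hz,
                "patient_id": m.patient_id,
                "phase": m.phase,
                "support_surface": m.support_surface,
                "duration_s": seq.duration_s,
            }
        )


def _read_hdf5(path: Path, geometry_override: Optional[MatGeometry]) -> PressureSequence:
    with h5py.File(path, "r") as f:
        values = f["pressure_mmHg"][()]
        timestamps = f["t_s"][()]
        a = f.attrs
        geometry = geometry_override or MatGeometry(
            n_rows=int(a["n_rows"]),
            n_cols=int(a["n_cols"]),
            pitch_mm=float(a["pitch_mm"]),
            sample_rate_hz=float(a["sample_rate_hz"]),
        )
        meta = SessionMeta(
            patient_id=str(a.get("patient_id", "")),
            phase=str(a.get("phase", "pre")),
            support_surface=str(a.get("support_surface", "")),
        )
    return PressureSequence(geometry, timestamps, values, meta)


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Serialize a simulation ground-truth log as JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
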
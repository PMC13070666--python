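"""Synthetic pressure-mat sessions with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes in a real bed recording: a lying body produces a handful of discrete
Gaussian loading sites (head, scapulae, sacrum/buttocks, heels), postures
change on a schedule with brief transitions, the body micro-moves within a
posture, the sensor adds noise, and an alternating (dynamic) mattress may
superimpose a slow periodic modulation. Every session carries a
:class:`GroundTruth` log (true change times, buttock-site centres,
noise-free signature oracles) so detector and ROI recovery can be scored
exactly.

This is a loading model, not a biomechanical one: there is no tissue
deformation, no shear, and no attempt to reproduce any real patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import MatGeometry, PressureSequence, SessionMeta


class ConfigError(ValueError):
    """A simulation configuration is unusable."""


@dataclass(frozen=True)
class LoadingSite:
    """One Gaussian pressure blob: a body region resting on the mat.

    Centres are fractional sensel coordinates (row across the width, col
    along the long axis); spreads are Gaussian SDs in sensels; amplitude is
    the peak pressure in mmHg.
    """

    centre_row: float
    centre_col: float
    spread_row: float
    spread_col: float
    amplitude: float
    is_pelvic: bool = False

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ConfigError("site amplitude must be >= 0")
        if self.spread_row <= 0 or self.spread_col <= 0:
            raise ConfigError("site spreads must be > 0")


@dataclass(frozen=True)
class PostureTemplate:
    """A named posture as a set of loading sites, exactly one pelvic."""

    name: str
    sites: tuple[LoadingSite, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ConfigError("posture template needs at least one loading site")
        if sum(s.is_pelvic for s in self.sites) != 1:
            raise ConfigError("exactly one site must be flagged pelvic")

    @property
    def pelvic_site(self) -> LoadingSite:
        return next(s for s in self.sites if s.is_pelvic)

    def shifted(self, d_row: float, d_col: float) -> "PostureTemplate":
        return PostureTemplate(
            self.name,
            tuple(
                replace(s, centre_row=s.centre_row + d_row, centre_col=s.centre_col + d_col)
                for s in self.sites
            ),
        )


def _supine() -> PostureTemplate:
    # documented constants on the default 48 x 118 grid; head at low col
    return PostureTemplate(
        "supine",
        (
            LoadingSite(23.5, 10, 3.0, 3.0, 45.0),              # head
            LoadingSite(17.0, 28, 3.5, 5.0, 55.0),              # left scapula
            LoadingSite(30.0, 28, 3.5, 5.0, 55.0),              # right scapula
            LoadingSite(23.5, 58, 5.0, 6.0, 110.0, is_pelvic=True),  # sacrum/buttocks
            LoadingSite(19.0, 100, 1.8, 2.5, 50.0),             # left heel
            LoadingSite(28.0, 100, 1.8, 2.5, 50.0),             # right heel
        ),
    )


def _lateral(side: str) -> PostureTemplate:
    off = -6.0 if side == "left" else 6.0
    return PostureTemplate(
        f"lateral_{side}",
        (
            LoadingSite(23.5 + off, 10, 2.5, 2.5, 50.0),             # head
            LoadingSite(23.5 + off, 30, 3.0, 4.5, 70.0),             # shoulder
            LoadingSite(23.5 + off, 58, 3.5, 4.5, 125.0, is_pelvic=True),  # trochanter
            LoadingSite(23.5 + off, 85, 2.5, 4.0, 45.0),             # knees
            LoadingSite(23.5 + off, 102, 1.8, 2.5, 35.0),            # ankle
        ),
    )


def _high_sitting() -> PostureTemplate:
    return PostureTemplate(
        "high_sitting",
        (
            LoadingSite(23.5, 45, 5.0, 6.0, 60.0),               # backrest / torso
            LoadingSite(23.5, 62, 4.5, 4.5, 130.0, is_pelvic=True),  # ischial region
            LoadingSite(20.0, 95, 2.0, 3.0, 40.0),               # left heel
            LoadingSite(27.0, 95, 2.0, 3.0, 40.0),               # right heel
        ),
    )


DEFAULT_TEMPLATES: dict[str, PostureTemplate] = {
    "supine": _supine(),
    "lateral_left": _lateral("left"),
    "lateral_right": _lateral("right"),
    "high_sitting": _high_sitting(),
}


@dataclass(frozen=True)
class ScheduleEntry:
    """One static posture: a template, its dwell time, and a COP offset."""

    template: PostureTemplate
    duration_s: float
    cop_offset: tuple[float, float] = (0.0, 0.0)
    min_dwell_s: float = 60.0

    def __post_init__(self) -> None:
        if self.duration_s < self.min_dwell_s:
            raise ConfigError(
                f"posture dwell {self.duration_s} s below minimum {self.min_dwell_s} s"
            )


@dataclass(frozen=True)
class AlternatingCycle:
    """Dynamic-mattress modulation: period (s) and fractional depth."""

    period_s: float = 600.0
    depth_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not (0 <= self.depth_fraction < 1):
            raise ConfigError("depth_fraction must be in [0, 1)")
        if self.period_s <= 0:
            raise ConfigError("period_s must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    geometry: MatGeometry = field(default_factory=MatGeometry.foresite_pt)
    schedule: tuple[ScheduleEntry, ...] = ()
    noise_sd_mmHg: float = 2.0
    jitter_sd_sensels: float = 0.2
    transition_s: float = 10.0
    alternating_cycle: Optional[AlternatingCycle] = None
    seed: int = 0
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        if self.noise_sd_mmHg < 0:
            raise ConfigError("noise_sd_mmHg must be >= 0")
        if self.jitter_sd_sensels < 0:
            raise ConfigError("jitter_sd_sensels must be >= 0")
        if self.transition_s < 0:
            raise ConfigError("transition_s must be >= 0")


@dataclass
class GroundTruth:
    """What the simulator knows that the analysis must recover."""

    change_times_s: list[float]
    posture_names: list[str]
    posture_starts_s: list[float]
    posture_durations_s: list[float]
    pelvic_centres: list[tuple[float, float]]  # (row, col) per posture
    ppg_true: list[float]  # noise-free, jitter-free per-posture PPG oracle
    ppi_true: list[float]  # noise-free, jitter-free per-posture PPI oracle

    def as_dict(self) -> dict:
        return {
            "change_times_s": self.change_times_s,
            "postures": [
                {
                    "name": n,
                    "start_s": s,
                    "duration_s": d,
                    "pelvic_centre_row": c[0],
                    "pelvic_centre_col": c[1],
                    "ppg_true_mmHg_per_cm": g,
                    "ppi_true_mmHg": p,
                }
                for n, s, d, c, g, p in zip(
                    self.posture_names,
                    self.posture_starts_s,
                    self.posture_durations_s,
                    self.pelvic_centres,
                    self.ppg_true,
                    self.ppi_true,
                )
            ],
        }


def render_template(tpl: PostureTemplate, geometry: MatGeometry) -> np.ndarray:
    """Render a posture as a noise-free pressure frame.

    The value at cell (r, c) is the sum over sites of
    ``amplitude * exp(-((r-cr)^2/(2 sr^2) + (c-cc)^2/(2 sc^2)))``,
    clipped at zero. Deterministic.
    """
    r = np.arange(geometry.n_rows, dtype=float)
    c = np.arange(geometry.n_cols, dtype=float)
    frame = np.zeros((geometry.n_rows, geometry.n_cols))
    for s in tpl.sites:
        gr = np.exp(-((r - s.centre_row) ** 2) / (2 * s.spread_row**2))
        gc = np.exp(-((c - s.centre_col) ** 2) / (2 * s.spread_col**2))
        frame += s.amplitude * np.outer(gr, gc)
    return np.clip(frame, 0.0, None)


def _render_jittered(
    tpl: PostureTemplate, geometry: MatGeometry, d_rows: np.ndarray, d_cols: np.ndarray
) -> np.ndarray:
    """Render one frame per (d_row, d_col) whole-body offset, vectorised."""
    n = len(d_rows)
    r = np.arange(geometry.n_rows, dtype=float)
    c = np.arange(geometry.n_cols, dtype=float)
    out = np.zeros((n, geometry.n_rows, geometry.n_cols), dtype=np.float32)
    for s in tpl.sites:
        gr = np.exp(
            -((r[None, :] - (s.centre_row + d_rows)[:, None]) ** 2)
            / (2 * s.spread_row**2)
        ).astype(np.float32)
        gc = np.exp(
            -((c[None, :] - (s.centre_col + d_cols)[:, None]) ** 2)
            / (2 * s.spread_col**2)
        ).astype(np.float32)
        out += np.float32(s.amplitude) * np.einsum("tr,tc->trc", gr, gc)
    return out


def _ar1_walk(rng: np.random.Generator, n: int, sd: float, rho: float = 0.98) -> np.ndarray:
    """Mean-reverting micro-movement track with stationary SD `sd`."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    step_sd = sd * np.sqrt(1 - rho**2)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    eps = rng.normal(0, step_sd, size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def simulate_session(cfg: SimulationConfig) -> tuple[PressureSequence, GroundTruth]:
    """Simulate one monitored session.

    Frames are the scheduled posture renders plus a within-posture
    mean-reverting COP walk (stationary SD ``jitter_sd_sensels``), i.i.d.
    Gaussian sensor noise truncated at 0 mmHg, and, when configured,
    multiplicative alternating-mattress modulation
    ``1 +/- depth * sin(2 pi t / period)`` with opposite sign on odd/even
    column stripes. Posture changes are linear cross-fades of length
    ``transition_s``; transition samples belong to the following posture
    (half-open convention). Identical seeds give identical output.
    """
    if not cfg.schedule:
        raise ConfigError("schedule must contain at least one posture")
    g = cfg.geometry
    rate = g.sample_rate_hz
    n_frames_per = [int(round(e.duration_s * rate)) for e in cfg.schedule]
    n_total = sum(n_frames_per)
    if n_total < 2:
        raise ConfigError("schedule too short: fewer than 2 frames")
    rng = np.random.default_rng(cfg.seed)

    # per-posture ground truth from noise-free, jitter-free renders
    from .roi import RoiSpec, ppg_frame, ppi_frame, place_window  # cycle-free

    spec = RoiSpec()
    change_times: list[float] = []
    names, starts, durs, centres, ppg_true, ppi_true = [], [], [], [], [], []
    t_cursor = 0.0
    bases = []
    for entry in cfg.schedule:
        tpl = entry.template.shifted(*entry.cop_offset)
        base = render_template(tpl, g)
        bases.append((tpl, base))
        pel = tpl.pelvic_site
        names.append(entry.template.name)
        starts.append(t_cursor)
        durs.append(entry.duration_s)
        centres.append((pel.centre_row, pel.centre_col))
        placement = place_window(pel.centre_row, pel.centre_col, spec, g)
        ppg_true.append(ppg_frame(base, placement, g))
        ppi_true.append(ppi_frame(base, placement))
        t_cursor += entry.duration_s
        if t_cursor < sum(e.duration_s for e in cfg.schedule):
            change_times.append(t_cursor)

    values = np.empty((n_total, g.n_rows, g.n_cols), dtype=np.float32)
    i0 = 0
    prev_static: Optional[np.ndarray] = None
    for (tpl, base), n_i in zip(bases, n_frames_per):
        if cfg.jitter_sd_sensels > 0:
            d_r = _ar1_walk(rng, n_i, cfg.jitter_sd_sensels)
            d_c = _ar1_walk(rng, n_i, cfg.jitter_sd_sensels)
            chunk = _render_jittered(tpl, g, d_r, d_c)
        else:
            chunk = np.broadcast_to(base.astype(np.float32), (n_i, g.n_rows, g.n_cols)).copy()
        if prev_static is not None and cfg.transition_s > 0:
            n_t = min(int(round(cfg.transition_s * rate)), n_i)
            w = ((np.arange(n_t) + 1) / (n_t + 1)).astype(np.float32)[:, None, None]
            chunk[:n_t] = (1 - w) * prev_static.astype(np.float32) + w * chunk[:n_t]
        values[i0 : i0 + n_i] = chunk
        prev_static = base
        i0 += n_i

    if cfg.alternating_cycle is not None:
        cyc = cfg.alternating_cycle
        t = np.arange(n_total, dtype=np.float32) / rate
        phase = np.sin(2 * np.pi * t / cyc.period_s).astype(np.float32)
        parity = np.where(np.arange(g.n_cols) % 2 == 0, 1.0, -1.0).astype(np.float32)
        values *= 1.0 + cyc.depth_fraction * phase[:, None, None] * parity[None, None, :]

    if cfg.noise_sd_mmHg > 0:
        noise = rng.standard_normal(values.shape, dtype=np.float32) * np.float32(
            cfg.noise_sd_mmHg
        )
        values += noise
    np.clip(values, 0.0, None, out=values)

    timestamps = np.arange(n_total, dtype=float) / rate
    seq = PressureSequence(g, timestamps, values, cfg.meta)
    truth = GroundTruth(change_times, names, starts, durs, centres, ppg_true, ppi_true)
    return seq, truth
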
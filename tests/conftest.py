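import numpy as np
import pytest

from cpmon import (
    MatGeometry,
    PressureSequence,
    ScheduleEntry,
    SimulationConfig,
    simulate_session,
)
from cpmon.synthetic import DEFAULT_TEMPLATES


@pytest.fixture
def geometry():
    return MatGeometry.foresite_pt()


@pytest.fixture
def random_sequence():
    """Factory: a small random but valid recording."""

    def make(n_frames=10, n_rows=4, n_cols=6, seed=0, rate=1.0):
        rng = np.random.default_rng(seed)
        g = MatGeometry(n_rows=n_rows, n_cols=n_cols, pitch_mm=15.9, sample_rate_hz=rate)
        values = rng.uniform(0, 120, size=(n_frames, n_rows, n_cols))
        return PressureSequence(g, np.arange(n_frames) / rate, values)

    return make


def five_posture_config(seed, noise_sd=3.0, jitter_sd=0.3, dwell_s=600.0):
    """The detector-recovery scenario: 5 postures, shifts >= 6 sensels."""
    names_offsets = [
        ("supine", (0.0, 0.0)),
        ("lateral_left", (0.0, 0.0)),
        ("supine", (3.0, 6.0)),
        ("lateral_right", (0.0, 0.0)),
        ("high_sitting", (0.0, 0.0)),
    ]
    schedule = tuple(
        ScheduleEntry(DEFAULT_TEMPLATES[n], dwell_s, off) for n, off in names_offsets
    )
    return SimulationConfig(
        schedule=schedule,
        noise_sd_mmHg=noise_sd,
        jitter_sd_sensels=jitter_sd,
        seed=seed,
    )


@pytest.fixture
def quiet_two_posture():
    """Noise-free, jitter-free, no-transition 2-posture session."""
    schedule = (
        ScheduleEntry(DEFAULT_TEMPLATES["supine"], 300.0),
        ScheduleEntry(DEFAULT_TEMPLATES["lateral_left"], 300.0),
    )
    cfg = SimulationConfig(
        schedule=schedule, noise_sd_mmHg=0.0, jitter_sd_sensels=0.0, transition_s=0.0, seed=0
    )
    return simulate_session(cfg)
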
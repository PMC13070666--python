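import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpmon import (
    MatGeometry,
    PressureSequence,
    compute_contact_area,
    compute_cop,
    detect_posture_changes,
    movement_features,
    movement_signal,
    render_template,
    segment_postures,
    summarize_lengths,
)
from cpmon.io import ValidationError
from cpmon.posture import MovementSignal, NoLoadError
from cpmon.synthetic import DEFAULT_TEMPLATES


class TestCop:
    def test_uniform_frame_gives_geometric_centre(self):
        frame = np.full((7, 11), 30.0)
        assert compute_cop(frame) == pytest.approx((3.0, 5.0))

    def test_single_loaded_cell(self):
        frame = np.zeros((20, 30))
        frame[10, 20] = 80.0
        assert compute_cop(frame) == (10.0, 20.0)

    def test_two_cell_weighted_mean(self):
        frame = np.zeros((1, 3))
        frame[0, 0], frame[0, 2] = 30.0, 60.0
        r, c = compute_cop(frame, floor_mmHg=5.0)
        assert r == 0.0
        assert c == pytest.approx((0 * 30 + 2 * 60) / 90)

    def test_no_load_raises(self):
        with pytest.raises(NoLoadError):
            compute_cop(np.full((4, 4), 2.0), floor_mmHg=5.0)

    def test_translation_equivariance_on_templates(self, geometry):
        """Shifting a noise-free body template by whole sensels shifts the
        COP by exactly that amount (interior placements)."""
        tpl = DEFAULT_TEMPLATES["supine"]
        base = compute_cop(render_template(tpl, geometry))
        # shifts small enough that every above-floor cell stays interior
        for dr, dc in [(2, 3), (-4, 6), (5, -2)]:
            shifted = compute_cop(render_template(tpl.shifted(dr, dc), geometry))
            assert shifted[0] - base[0] == pytest.approx(dr, abs=1e-9)
            assert shifted[1] - base[1] == pytest.approx(dc, abs=1e-9)


class TestContactArea:
    def test_zero_when_all_below_threshold(self, geometry):
        assert compute_contact_area(np.full((48, 118), 10.0), geometry) == 0.0

    def test_five_cells_above_threshold(self, geometry):
        frame = np.zeros((48, 118))
        frame[0, :5] = 50.0
        assert compute_contact_area(frame, geometry) == pytest.approx(5 * 1.59**2)

    def test_monotone_in_pressure_scaling(self, geometry):
        rng = np.random.default_rng(5)
        frame = rng.uniform(0, 40, (48, 118))
        a1 = compute_contact_area(frame, geometry)
        a2 = compute_contact_area(2 * frame, geometry)
        assert a2 >= a1


class TestMovementSignal:
    def test_constant_recording_gives_zero_signal(self, geometry):
        values = np.tile(render_template(DEFAULT_TEMPLATES["supine"], geometry), (60, 1, 1))
        seq = PressureSequence(geometry, np.arange(60.0), values)
        sig = movement_signal(seq)
        np.testing.assert_array_equal(sig.values, 0.0)
        assert detect_posture_changes(sig) == []

    def test_cop_jump_produces_localised_pulse(self, quiet_two_posture):
        """An instantaneous posture change yields one pulse whose peak lies
        within half the smoothing window of the true jump."""
        seq, truth = quiet_two_posture
        sig = movement_signal(seq, smooth_window_s=11.0)
        peak_t = sig.timestamps[int(np.argmax(sig.values))]
        assert abs(peak_t - truth.change_times_s[0]) <= 11.0 / 2

    def test_combined_norm_dominates_each_channel(self, quiet_two_posture):
        from scipy.ndimage import uniform_filter1d

        from cpmon.posture import _robust_z, cop_trace

        seq, _ = quiet_two_posture
        sig = movement_signal(seq, smooth_window_s=11.0)
        trace = cop_trace(seq)
        for channel in (trace.cop_row, trace.cop_col, trace.contact_area_cm2):
            z = _robust_z(np.gradient(uniform_filter1d(channel, 11, mode="nearest"), 1.0))
            assert (sig.values >= np.abs(z) - 1e-9).all()

    def test_short_recording_rejected(self, random_sequence):
        with pytest.raises(ValidationError, match="window"):
            movement_signal(random_sequence(n_frames=12), smooth_window_s=11.0)


class TestDetect:
    def test_close_events_merge_under_min_separation(self):
        """Two pulses 30 s apart with 60 s minimum separation report one event."""
        x = np.zeros(300)
        x[100] = 50.0
        x[130] = 40.0
        sig = MovementSignal(x, np.arange(300.0), 11.0)
        times = detect_posture_changes(sig, k_mad=12.0, min_separation_s=60.0)
        assert times == [100.0]

    def test_events_beyond_separation_both_kept(self):
        x = np.zeros(300)
        x[100] = 50.0
        x[200] = 40.0
        sig = MovementSignal(x, np.arange(300.0), 11.0)
        assert detect_posture_changes(sig) == [100.0, 200.0]

    def test_supra_threshold_run_reports_single_peak(self):
        x = np.zeros(200)
        x[50:60] = np.linspace(10, 30, 10)  # one contiguous run
        sig = MovementSignal(x, np.arange(200.0), 11.0)
        assert detect_posture_changes(sig) == [59.0]
        assert sig.detection_threshold is not None


class TestSegmentation:
    def test_no_changes_single_segment(self, geometry):
        seq = _dummy_seq(geometry, n=57600)
        res = segment_postures(seq, [])
        assert res.n_postures == 1
        assert res.segments[0].duration_s == 57600.0
        feats = movement_features(res)
        assert feats.monitoring_hours == pytest.approx(16.0)
        assert round(feats.frequency_per_hour, 2) == 0.06  # 1 posture / 16 h

    def test_partition_into_equal_thirds(self, geometry):
        seq = _dummy_seq(geometry, n=10800)
        res = segment_postures(seq, [3600.0, 7200.0])
        assert [s.duration_s for s in res.segments] == [3600.0, 3600.0, 3600.0]
        assert sum(s.duration_s for s in res.segments) == seq.duration_s

    def test_invalid_change_times_rejected(self, geometry):
        seq = _dummy_seq(geometry, n=100)
        with pytest.raises(ValidationError):
            segment_postures(seq, [50.0, 50.0])
        with pytest.raises(ValidationError):
            segment_postures(seq, [150.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        n=st.integers(min_value=10, max_value=5000),
        data=st.data(),
    )
    def test_partition_conservation(self, n, data):
        """k change times always yield k+1 segments whose durations sum to
        the monitoring length exactly."""
        g = MatGeometry(2, 2, 15.9, 1.0)
        seq = _dummy_seq(g, n=n)
        k = data.draw(st.integers(min_value=0, max_value=min(8, n - 2)))
        times = sorted(
            data.draw(
                st.sets(st.integers(min_value=1, max_value=n - 1), min_size=k, max_size=k)
            )
        )
        res = segment_postures(seq, [float(t) for t in times])
        assert res.n_postures == len(times) + 1
        assert math.fsum(s.duration_s for s in res.segments) == seq.duration_s


class TestMovementFeatures:
    def test_frequency_matches_printed_extremes(self, geometry):
        # 17 postures over 14.5 h and 1 posture over 16 h
        seq = _dummy_seq(geometry, n=int(14.5 * 3600))
        res = segment_postures(seq, [float(900 * (i + 1)) for i in range(16)])
        assert round(movement_features(res).frequency_per_hour, 2) == 1.17
        assert (
            movement_features(res, frequency_basis="transitions").frequency_per_hour
            == pytest.approx(16 / 14.5)
        )

    def test_pct_static_gt_2h(self, geometry):
        seq = _dummy_seq(geometry, n=3 * 3600)
        res = segment_postures(seq, [])
        assert movement_features(res).pct_time_static_gt_2h == 1.0
        res2 = segment_postures(seq, [9000.0])  # 2.5 h + 0.5 h
        assert movement_features(res2).pct_time_static_gt_2h == pytest.approx(9000 / 10800)

    def test_intervals_are_gaps_between_changes(self, geometry):
        seq = _dummy_seq(geometry, n=1000)
        res = segment_postures(seq, [100.0, 400.0, 450.0])
        assert movement_features(res).intervals_s == [300.0, 50.0]


class TestSummarizeLengths:
    def test_linear_interpolation_quartiles(self):
        # quartiles fall on observations 5 and 13 of 17 sorted values
        values = list(range(1, 18))
        s = summarize_lengths(values)
        assert (s["q1"], s["median"], s["q3"]) == (5.0, 9.0, 13.0)
        assert s["iqr"] == 8.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_lengths([])


def _dummy_seq(geometry, n):
    # segmentation only needs timestamps and a valid stack; keep the grid tiny
    g = MatGeometry(2, 2, geometry.pitch_mm, 1.0)
    values = np.broadcast_to(np.full((2, 2), 30.0), (n, 2, 2))
    return PressureSequence(g, np.arange(float(n)), values)
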
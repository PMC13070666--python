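import numpy as np
import pytest

from cpmon import (
    MatGeometry,
    PressureSequence,
    PostureSegment,
    RoiSpec,
    locate_roi,
    peak_frame,
    posture_signature,
    ppg_frame,
    ppi_frame,
)
from cpmon.io import ValidationError
from cpmon.roi import RoiError, RoiPlacement, place_window, signature_series


def _brute_ppi(window):
    return float(np.mean(sorted(window.ravel())[-10:]))


def _brute_ppg(window, pitch_cm):
    best = 0.0
    rows, cols = window.shape
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((1, 1), (1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    best = max(best, abs(window[r, c] - window[rr, cc]))
    return best / (np.sqrt(2) * pitch_cm)


class TestRoiSpec:
    def test_physical_extent_at_default_pitch(self, geometry):
        length, width = RoiSpec().physical_extent_cm(geometry)
        assert length == pytest.approx(47.7)
        assert width == pytest.approx(31.8)

    def test_too_small_roi_rejected(self):
        with pytest.raises(RoiError):
            RoiSpec(len_sensels=3, wid_sensels=3)


class TestPlacement:
    def test_even_extent_centring(self, geometry):
        # centre at (24, 59): rows 14..33, cols 44..73
        p = place_window(24.0, 59.0, RoiSpec(), geometry)
        assert (p.row0, p.col0) == (24 - 10, 59 - 15)
        assert not p.clipped

    def test_clipped_window_flush_with_edge(self, geometry):
        p = place_window(3.0, 59.0, RoiSpec(), geometry)
        assert p.row0 == 0
        assert p.clipped

    def test_spec_larger_than_grid_rejected(self):
        with pytest.raises(RoiError):
            place_window(1.0, 1.0, RoiSpec(), MatGeometry(10, 10, 15.9, 1.0))


class TestFrameSignatures:
    def test_uniform_roi(self, geometry):
        frame = np.full((48, 118), 50.0)
        p = RoiPlacement(10, 40)
        assert ppi_frame(frame, p) == 50.0
        assert ppg_frame(frame, p, geometry) == 0.0
        assert peak_frame(frame, p) == 50.0

    def test_ppi_ten_loaded_cells(self):
        frame = np.zeros((48, 118))
        frame[20, 50:60] = 100.0
        assert ppi_frame(frame, RoiPlacement(15, 45)) == 100.0

    def test_ppg_diagonal_stripes(self, geometry):
        """Column stripes 0/100: every diagonal neighbour pair differs by
        100 mmHg over sqrt(2) * 1.59 cm."""
        frame = np.zeros((48, 118))
        frame[:, 1::2] = 100.0
        got = ppg_frame(frame, RoiPlacement(10, 40), geometry)
        assert got == pytest.approx(100.0 / (np.sqrt(2) * 1.59))
        assert round(got, 2) == 44.47

    def test_ppg_checkerboard_is_blind(self, geometry):
        # diagonal neighbours share checkerboard parity: the diagonal
        # definition sees no gradient at all
        r, c = np.indices((48, 118))
        frame = np.where((r + c) % 2 == 0, 0.0, 100.0)
        assert ppg_frame(frame, RoiPlacement(10, 40), geometry) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracles(self, geometry, seed):
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 150, (48, 118))
        spec = RoiSpec(
            len_sensels=int(rng.integers(2, 31)), wid_sensels=int(rng.integers(5, 21))
        )
        p = place_window(
            float(rng.uniform(0, 47)), float(rng.uniform(0, 117)), spec, geometry
        )
        window = frame[p.row0 : p.row0 + spec.wid_sensels, p.col0 : p.col0 + spec.len_sensels]
        assert ppi_frame(frame, p, spec) == pytest.approx(_brute_ppi(window), abs=1e-12)
        assert ppg_frame(frame, p, geometry, spec) == pytest.approx(
            _brute_ppg(window, geometry.pitch_cm), abs=1e-12
        )

    def test_ordering_peak_ppi_mean(self, geometry):
        rng = np.random.default_rng(11)
        for _ in range(20):
            frame = rng.uniform(0, 200, (48, 118))
            p = RoiPlacement(int(rng.integers(0, 28)), int(rng.integers(0, 88)))
            window = frame[p.row0 : p.row0 + 20, p.col0 : p.col0 + 30]
            assert peak_frame(frame, p) >= ppi_frame(frame, p) >= window.mean()

    def test_scale_equivariance(self, geometry):
        rng = np.random.default_rng(2)
        frame = rng.uniform(0, 100, (48, 118))
        p = RoiPlacement(5, 30)
        c = 3.7
        assert ppi_frame(c * frame, p) == pytest.approx(c * ppi_frame(frame, p))
        assert ppg_frame(c * frame, p, geometry) == pytest.approx(
            c * ppg_frame(frame, p, geometry)
        )
        assert peak_frame(c * frame, p) == pytest.approx(c * peak_frame(frame, p))


class TestPostureSignature:
    def _seq_of_uniform_frames(self, geometry, levels):
        values = np.stack([np.full((48, 118), v) for v in levels])
        return PressureSequence(geometry, np.arange(float(len(levels))), values)

    def test_constant_frames_have_zero_sd(self, geometry):
        seq = self._seq_of_uniform_frames(geometry, [60.0] * 5)
        seg = PostureSegment(0.0, 5.0)
        sig = posture_signature(seq, seg, RoiPlacement(10, 40))
        assert sig.ppi_sd == 0.0
        assert sig.ppi_mean == 60.0

    def test_two_frame_mean_and_sample_sd(self, geometry):
        seq = self._seq_of_uniform_frames(geometry, [80.0, 100.0])
        sig = posture_signature(seq, PostureSegment(0.0, 2.0), RoiPlacement(10, 40))
        assert sig.ppi_mean == pytest.approx(90.0)
        assert sig.ppi_sd == pytest.approx(np.sqrt(200), abs=1e-9)  # 14.142...

    def test_single_frame_segment_rejected(self, geometry):
        seq = self._seq_of_uniform_frames(geometry, [50.0, 50.0, 50.0])
        with pytest.raises(ValidationError):
            posture_signature(seq, PostureSegment(0.0, 1.0), RoiPlacement(10, 40))

    def test_homogeneous_scaling(self, geometry):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 120, (6, 48, 118))
        seq = PressureSequence(geometry, np.arange(6.0), values)
        seg = PostureSegment(0.0, 6.0)
        p = RoiPlacement(10, 40)
        a = posture_signature(seq, seg, p)
        b = posture_signature(seq.with_values(2.5 * values), seg, p)
        for attr in ("ppg_mean", "ppg_sd", "ppi_mean", "ppi_sd", "peak_mean"):
            assert getattr(b, attr) == pytest.approx(2.5 * getattr(a, attr))


class TestLocateRoi:
    def test_roi_contains_dominant_pelvic_site(self, quiet_two_posture):
        seq, truth = quiet_two_posture
        for (start, dur), centre in zip(
            zip(truth.posture_starts_s, truth.posture_durations_s), truth.pelvic_centres
        ):
            seg = PostureSegment(start, start + dur)
            p = locate_roi(seq, seg)
            assert p.row0 <= centre[0] <= p.row0 + 19
            assert p.col0 <= centre[1] <= p.col0 + 29

    def test_series_matches_per_frame_functions(self, geometry):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 120, (5, 48, 118))
        seq = PressureSequence(geometry, np.arange(5.0), values)
        seg = PostureSegment(0.0, 5.0)
        p = RoiPlacement(12, 33)
        series = signature_series(seq, seg, p)
        for i in range(5):
            assert series.ppi_mmHg[i] == pytest.approx(ppi_frame(values[i], p))
            assert series.ppg_mmHg_per_cm[i] == pytest.approx(
                ppg_frame(values[i], p, geometry)
            )
            assert series.peak_mmHg[i] == pytest.approx(peak_frame(values[i], p))
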
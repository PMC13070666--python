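"""End-to-end analysis of one recording: segmentation, signatures, exposure.

Thin orchestration over the module functions so the CLI, the analysis
drivers and the tests all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import exposure as exp
from . import posture, roi
from .io import PressureSequence


@dataclass(frozen=True)
class AnalysisParams:
    """Every tunable of the recording pipeline, with the package defaults."""

    cop_floor_mmHg: float = posture.DEFAULT_COP_FLOOR_MMHG
    contact_threshold_mmHg: float = posture.DEFAULT_CONTACT_THRESHOLD_MMHG
    smooth_window_s: float = posture.DEFAULT_SMOOTH_WINDOW_S
    k_mad: float = posture.DEFAULT_K_MAD
    min_separation_s: float = posture.DEFAULT_MIN_SEPARATION_S
    roi_spec: roi.RoiSpec = field(default_factory=roi.RoiSpec)
    thr_ppg: exp.SigmoidThresholds = field(default_factory=exp.SigmoidThresholds.ppg_default)
    thr_ppi: exp.SigmoidThresholds = field(default_factory=exp.SigmoidThresholds.ppi_default)
    exposure_mode: str = "posture"
    frequency_basis: str = "postures"

    def as_dict(self) -> dict:
        return {
            "cop_floor_mmHg": self.cop_floor_mmHg,
            "contact_threshold_mmHg": self.contact_threshold_mmHg,
            "smooth_window_s": self.smooth_window_s,
            "k_mad": self.k_mad,
            "min_separation_s": self.min_separation_s,
            "roi_len_sensels": self.roi_spec.len_sensels,
            "roi_wid_sensels": self.roi_spec.wid_sensels,
            "thr_ppg": {
                "p_start": list(self.thr_ppg.p_start),
                "floor_fraction": self.thr_ppg.floor_fraction,
                "alpha_per_h": self.thr_ppg.alpha_per_h,
                "t0_h": self.thr_ppg.t0_h,
            },
            "thr_ppi": {
                "p_start": list(self.thr_ppi.p_start),
                "floor_fraction": self.thr_ppi.floor_fraction,
                "alpha_per_h": self.thr_ppi.alpha_per_h,
                "t0_h": self.thr_ppi.t0_h,
            },
            "exposure_mode": self.exposure_mode,
            "frequency_basis": self.frequency_basis,
        }


@dataclass
class AnalysisResult:
    segmentation: posture.SegmentationResult
    features: posture.MovementFeatures
    placements: list[roi.RoiPlacement]
    signatures: list[roi.PostureSignature]
    exposure_ppg: exp.ExposureSummary
    exposure_ppi: exp.ExposureSummary
    params: AnalysisParams

    def signatures_frame(self) -> pd.DataFrame:
        """Per-posture signature table in the analysis output layout."""
        rows = []
        for i, (seg, pl, sig) in enumerate(
            zip(self.segmentation.segments, self.placements, self.signatures)
        ):
            rows.append(
                {
                    "segment_idx": i,
                    "start_s": seg.start_s,
                    "duration_h": sig.duration_h,
                    "ppg_mean": sig.ppg_mean,
                    "ppg_sd": sig.ppg_sd,
                    "ppi_mean": sig.ppi_mean,
                    "ppi_sd": sig.ppi_sd,
                    "peak_mean": sig.peak_mean,
                    "roi_row0": pl.row0,
                    "roi_col0": pl.col0,
                    "clipped": pl.clipped,
                }
            )
        return pd.DataFrame(rows)


def analyze_recording(
    seq: PressureSequence, params: AnalysisParams = AnalysisParams()
) -> AnalysisResult:
    """Run the full pipeline on one recording.

    Detect postural changes from the combined COP/contact-area derivative,
    partition the period into static postures, anchor the buttock ROI per
    posture, compute its PPG/PPI/peak descriptors, and stratify the
    pressure-time exposure against the sigmoid thresholds.
    """
    sig = posture.movement_signal(
        seq,
        smooth_window_s=params.smooth_window_s,
        cop_floor_mmHg=params.cop_floor_mmHg,
        contact_threshold_mmHg=params.contact_threshold_mmHg,
    )
    changes = posture.detect_posture_changes(
        sig, k_mad=params.k_mad, min_separation_s=params.min_separation_s
    )
    segres = posture.segment_postures(seq, changes)
    features = posture.movement_features(segres, frequency_basis=params.frequency_basis)
    placements, signatures = [], []
    for seg in segres.segments:
        pl = roi.locate_roi(seq, seg, params.roi_spec, params.cop_floor_mmHg)
        placements.append(pl)
        signatures.append(roi.posture_signature(seq, seg, pl, params.roi_spec))
    e_ppg, e_ppi = exp.exposure_summary(
        signatures, params.thr_ppg, params.thr_ppi, mode=params.exposure_mode
    )
    return AnalysisResult(segres, features, placements, signatures, e_ppg, e_ppi, params)
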
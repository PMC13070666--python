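#!/usr/bin/env python
"""Buttock-ROI pressure signatures and exposure stratification per session.

For every cohort session: segment, anchor the 30 x 20-sensel buttock ROI on
each posture's median COP, compute PPG/PPI descriptors, and stratify the
pressure-time exposure against the sigmoid thresholds. Writes per-posture
signatures and per-session exposure fractions under results/.
"""

import json
from pathlib import Path

import pandas as pd

from cpmon import AnalysisParams, analyze_recording, read_sequence
from cpmon.exposure import CATEGORY_LABELS

RESULTS = Path("results")


def main() -> None:
    manifest = json.loads((RESULTS / "cohort_manifest.json").read_text())
    sig_rows, expo_rows = [], []
    for entry in manifest:
        seq = read_sequence(entry["recording"])
        res = analyze_recording(seq, AnalysisParams())
        sigs = res.signatures_frame()
        sigs.insert(0, "patient", entry["patient"])
        sigs.insert(1, "phase", entry["phase"])
        sig_rows.append(sigs)
        for kind, summ in (("ppg", res.exposure_ppg), ("ppi", res.exposure_ppi)):
            expo_rows.append(
                {
                    "patient": entry["patient"],
                    "phase": entry["phase"],
                    "signature": kind,
                    **{c: round(summ.fractions[c], 4) for c in CATEGORY_LABELS},
                }
            )
        top = res.signatures_frame()["ppi_mean"].max()
        print(
            f"{entry['patient']} {entry['phase']}: "
            f"{res.segmentation.n_postures} postures, max posture PPI "
            f"{top:.1f} mmHg, PPI exposure low={res.exposure_ppi.fractions['low']:.2f}"
        )
    pd.concat(sig_rows).to_csv(RESULTS / "posture_signatures.csv", index=False)
    pd.DataFrame(expo_rows).to_csv(RESULTS / "exposure_fractions.csv", index=False)
    print(
        "\nwrote results/posture_signatures.csv and results/exposure_fractions.csv"
    )


if __name__ == "__main__":
    main()
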
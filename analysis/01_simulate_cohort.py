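#!/usr/bin/env python
"""Simulate a small synthetic pre/post cohort of bed pressure-mat sessions.

Four synthetic patients are each given a pre- and a post-intervention
session. Post sessions reposition more often and carry a lighter pelvic
load, emulating the intended effect of a repositioning/support-surface
intervention. Recordings (HDF5) and ground-truth logs go to
scratch/recordings/; a session manifest goes to results/.

Run from the repository root: python analysis/01_simulate_cohort.py [--seed N]
"""

import argparse
import json
from dataclasses import replace
from pathlib import Path

from cpmon import (
    LoadingSite,
    PostureTemplate,
    ScheduleEntry,
    SessionMeta,
    SimulationConfig,
    simulate_session,
    write_sequence,
)
from cpmon.io import write_ground_truth
from cpmon.synthetic import DEFAULT_TEMPLATES

REC_DIR = Path("scratch/recordings")
RESULTS = Path("results")


def _lighter(tpl: PostureTemplate, factor: float) -> PostureTemplate:
    """Scale only the pelvic amplitude: an offloading support surface."""
    return PostureTemplate(
        tpl.name,
        tuple(
            replace(s, amplitude=s.amplitude * factor) if s.is_pelvic else s
            for s in tpl.sites
        ),
    )


def schedules(seed: int):
    """Per-patient pre/post schedules: post adds one change and offloads."""
    base = ["supine", "lateral_left", "supine", "lateral_right"]
    for i in range(4):
        pre_names = base[: 2 + i % 3]
        post_names = pre_names + [base[(2 + i) % 4]]
        pre = tuple(
            ScheduleEntry(DEFAULT_TEMPLATES[n], 900.0, (0.0, 2.0 * j))
            for j, n in enumerate(pre_names)
        )
        post = tuple(
            ScheduleEntry(_lighter(DEFAULT_TEMPLATES[n], 0.75), 900.0, (0.0, 2.0 * j))
            for j, n in enumerate(post_names)
        )
        yield f"S{i + 1}", pre, post


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    REC_DIR.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    manifest = []
    for k, (patient, pre, post) in enumerate(schedules(args.seed)):
        for phase, schedule in (("pre", pre), ("post", post)):
            cfg = SimulationConfig(
                schedule=schedule,
                noise_sd_mmHg=2.0,
                jitter_sd_sensels=0.2,
                seed=args.seed + 10 * k + (0 if phase == "pre" else 5),
                meta=SessionMeta(patient_id=patient, phase=phase),
            )
            seq, truth = simulate_session(cfg)
            rec = REC_DIR / f"{patient}_{phase}.h5"
            write_sequence(seq, rec)
            write_ground_truth(truth.as_dict(), rec.with_suffix(".truth.json"))
            manifest.append(
                {
                    "patient": patient,
                    "phase": phase,
                    "recording": str(rec),
                    "truth": str(rec.with_suffix(".truth.json")),
                    "n_frames": len(seq),
                    "true_postures": len(truth.change_times_s) + 1,
                }
            )
            print(
                f"{patient} {phase}: {len(seq)} frames, "
                f"{len(truth.change_times_s) + 1} true postures -> {rec}"
            )
    (RESULTS / "cohort_manifest.json").write_text(json.dumps(manifest, indent=2))
    print(f"\nwrote manifest for {len(manifest)} sessions -> results/cohort_manifest.json")


if __name__ == "__main__":
    main()
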
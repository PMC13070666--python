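"""Cohort fixtures and pre/post-intervention reporting.

Two study tables are packaged as checksummed CSV fixtures: the clinical
cohort (17 community patients: demographics, pressure-injury categories and
support surfaces pre and post intervention) and the movement features
estimated from their continuous pressure monitoring (length of monitoring
and posture counts, pre and post). Operations reproduce the printed cohort
summaries and assemble side-by-side pre/post comparison reports for real or
simulated cohorts.

Display rounding matches the source tables: frequencies to 2 d.p., hours to
1 d.p., mean BMI to the nearest integer.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exposure import CATEGORY_LABELS, ExposureSummary
from .posture import MovementFeatures, summarize_lengths

_FIXTURES = {
    "table1": (
        "table1_patients.csv",
        "5516b04b304af94196966f18ed7f13a3abad515983ce6fd472f383861b469ac9",
    ),
    "table2": (
        "table2_movement.csv",
        "dfb98255159e44f7958e5d282e3d24b0e0d8ea4dd774b14707accc1880a7b58b",
    ),
}


class FixtureIntegrityError(RuntimeError):
    """A packaged fixture does not match its build-time checksum."""


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged cohort fixture (``"table1"`` or ``"table2"``).

    The file's SHA-256 is verified against the checksum fixed at build time;
    any edit fails loudly.
    """
    try:
        fname, expected = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    ref = resources.files("cpmon.data").joinpath(fname)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise FixtureIntegrityError(
            f"fixture {fname} checksum {digest} != expected {expected}"
        )
    import io as _io

    df = pd.read_csv(_io.BytesIO(raw))
    if len(df) != 17:
        raise FixtureIntegrityError(f"fixture {fname} must have 17 rows, has {len(df)}")
    return df


def tabulate_pu(table1: pd.DataFrame, phase: str) -> dict[str, int]:
    """Frequency table of pressure-injury categories for one phase."""
    col = {"pre": "pu_cat_pre", "post": "pu_cat_post"}[phase]
    counts = table1[col].value_counts()
    return {str(k): int(v) for k, v in counts.items()}


def bmi_summary(table1: pd.DataFrame) -> dict[str, float]:
    """Mean (also rounded for display) and extremes of the BMI column."""
    bmi = table1["bmi"].to_numpy(dtype=float)
    return {
        "mean": float(bmi.mean()),
        "mean_display": int(round(bmi.mean())),
        "min": float(bmi.min()),
        "max": float(bmi.max()),
    }


def movement_report(
    table2: pd.DataFrame, phase: str, frequency_basis: str = "postures"
) -> dict:
    """Per-phase movement summary: monitoring lengths, posture counts,
    per-patient movement frequencies.

    Lengths and counts are summarised with linear-interpolation quartiles;
    frequency is posture count / monitoring hours, displayed at 2 d.p.
    """
    hours = table2[f"{phase}_hours"].to_numpy(dtype=float)
    postures = table2[f"{phase}_postures"].to_numpy(dtype=float)
    numer = postures if frequency_basis == "postures" else postures - 1
    freq = numer / hours
    freq_2dp = np.round(freq, 2)
    return {
        "phase": phase,
        "n_patients": len(table2),
        "length_hours": summarize_lengths(hours),
        "n_postures": summarize_lengths(postures),
        "frequency_per_hour": {
            "per_patient": dict(zip(table2["patient_no"].astype(str), freq_2dp)),
            "min": float(freq_2dp.min()),
            "max": float(freq_2dp.max()),
        },
    }


# ---------------------------------------------------------------------------
# pre/post comparison of analysis outputs


@dataclass
class PhaseResult:
    """One patient-phase analysis output bundle."""

    features: MovementFeatures
    exposure_ppg: Optional[ExposureSummary] = None
    exposure_ppi: Optional[ExposureSummary] = None


def compare_pre_post(
    pre: Mapping[str, PhaseResult], post: Mapping[str, PhaseResult]
) -> dict:
    """Side-by-side pre/post report, per patient and pooled.

    Patients present in only one phase appear with explicit ``null`` gaps
    rather than being dropped. Pooled exposure fractions are monitoring-hour
    weighted means within each phase, so they sum to 1 per phase.
    """
    patients = sorted(set(pre) | set(post))
    per_patient = {}
    for p in patients:
        a, b = pre.get(p), post.get(p)
        per_patient[p] = {
            "pre": _phase_dict(a),
            "post": _phase_dict(b),
            "delta": _delta(a, b),
        }
    return {
        "patients": per_patient,
        "pooled": {
            "pre": _pool(pre),
            "post": _pool(post),
        },
    }


def _phase_dict(r: Optional[PhaseResult]) -> Optional[dict]:
    if r is None:
        return None
    d = {"features": r.features.as_dict()}
    for key, summ in (("exposure_ppg", r.exposure_ppg), ("exposure_ppi", r.exposure_ppi)):
        d[key] = None if summ is None else dict(summ.fractions)
    return d


def _delta(a: Optional[PhaseResult], b: Optional[PhaseResult]) -> Optional[dict]:
    if a is None or b is None:
        return None
    d = {
        "n_postures": b.features.n_postures - a.features.n_postures,
        "monitoring_hours": b.features.monitoring_hours - a.features.monitoring_hours,
        "frequency_per_hour": b.features.frequency_per_hour - a.features.frequency_per_hour,
        "pct_time_static_gt_2h": b.features.pct_time_static_gt_2h
        - a.features.pct_time_static_gt_2h,
    }
    for key, sa, sb in (
        ("exposure_ppg", a.exposure_ppg, b.exposure_ppg),
        ("exposure_ppi", a.exposure_ppi, b.exposure_ppi),
    ):
        if sa is not None and sb is not None:
            d[key] = {c: sb.fractions[c] - sa.fractions[c] for c in CATEGORY_LABELS}
    return d


def _pool(phase: Mapping[str, PhaseResult]) -> Optional[dict]:
    if not phase:
        return None
    results = list(phase.values())
    pooled: dict = {
        "n_patients": len(results),
        "total_monitoring_hours": sum(r.features.monitoring_hours for r in results),
        "median_n_postures": float(np.median([r.features.n_postures for r in results])),
    }
    for key in ("exposure_ppg", "exposure_ppi"):
        summaries = [getattr(r, key) for r in results if getattr(r, key) is not None]
        if summaries:
            hours = np.array([s.monitoring_hours for s in summaries])
            fracs = np.array(
                [[s.fractions[c] for c in CATEGORY_LABELS] for s in summaries]
            )
            weighted = (hours[:, None] * fracs).sum(axis=0) / hours.sum()
            pooled[key] = dict(zip(CATEGORY_LABELS, map(float, weighted)))
    return pooled


def report_to_markdown(report: dict) -> str:
    """Human-readable rendering of a :func:`compare_pre_post` report."""
    lines = [
        "| patient | phase | hours | postures | freq /h | % static > 2 h |",
        "|---|---|---|---|---|---|",
    ]
    for p, entry in report["patients"].items():
        for phase in ("pre", "post"):
            d = entry[phase]
            if d is None:
                lines.append(f"| {p} | {phase} | - | - | - | - |")
                continue
            f = d["features"]
            lines.append(
                f"| {p} | {phase} | {f['monitoring_hours']:.1f} | {f['n_postures']} "
                f"| {f['frequency_per_hour']:.2f} | {100 * f['pct_time_static_gt_2h']:.0f} |"
            )
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, default=_default)


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
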
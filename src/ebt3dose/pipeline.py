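"""End-to-end film read-out: corrections → dose → restore → merge → report.

The order of operations follows the read-out protocol: every orientation
scan is scanner-corrected and converted to dose *first* (each scan sees a
different part of the bed, so its corrections differ), then the dose maps
are restored to the film frame and merged by outlier-masked mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationCurve, timing_check
from .dosemap import DoseMap
from .errors import InputError
from .film_image_io import FilmScan
from .readout_merge import (MergedDose, Profile, extract_profile,
                            merge_orientations, restore_orientation)
from .scanner_correction import (DoseTransversalCorrection, MatrixCorrection,
                                 apply_corrections_iterative,
                                 orientationless_background)
from .uncertainty import UncertaintyBudget


@dataclass
class ReadoutResult:
    merged: MergedDose
    per_orientation: dict[str, DoseMap]
    qc_log: list[dict] = field(default_factory=list)
    profile: Profile | None = None
    budget: UncertaintyBudget | None = None

    @property
    def dose_map(self) -> DoseMap:
        return DoseMap(self.merged.dose,
                       provenance={"orientations": list(self.merged.tags)})


def run_readout(scans: Sequence[FilmScan], background: FilmScan,
                matrix: MatrixCorrection,
                mdcorr: DoseTransversalCorrection | None,
                curve: CalibrationCurve, *,
                timing_profile: str = "4d",
                outlier_rel_threshold: float = 0.02,
                outlier_abs_threshold_gy: float = 0.04,
                max_iter: int = 10) -> ReadoutResult:
    """Full read-out of one film from its orientation scans.

    ``scans`` are the exposed scans (ideally all four orientations; a
    single scan is accepted with a reduced-accuracy warning). ``background``
    is the film's pre-irradiation scan in the normal orientation. Every QC
    decision is appended to the result's ``qc_log``.
    """
    if not scans:
        raise InputError("no exposed scans given")
    qc_log: list[dict] = []
    tags = [s.orientation_tag for s in scans]
    if len(set(tags)) != len(tags):
        raise InputError(f"duplicate orientation tags: {tags}")
    if len(scans) < 4:
        qc_log.append({"rule": "orientation_count", "verdict": "warn",
                       "n": len(scans),
                       "detail": "fewer than four orientations; dust "
                                 "rejection and scanner-residual averaging "
                                 "are degraded"})
    if curve.is_expired():
        qc_log.append({"rule": "calibration_age", "verdict": "warn",
                       "detail": "calibration is older than 3 months; "
                                 "recalibrate the lot"})

    bg_corr = orientationless_background(background, matrix)

    per_orientation: dict[str, DoseMap] = {}
    restored: list[DoseMap] = []
    for scan in scans:
        timing = timing_check(scan.exposure_time, scan.scan_time,
                              timing_profile)
        qc_log.append({"rule": "timing_window", "verdict": timing.verdict,
                       "orientation": scan.orientation_tag,
                       "delta_hours": timing.delta_hours,
                       "detail": timing.message})
        bg_oriented = bg_corr.for_orientation(scan.orientation_tag)
        corrected, dmap = apply_corrections_iterative(
            scan, bg_oriented, matrix, mdcorr, curve, max_iter=max_iter)
        qc_log.append({"rule": "iteration_convergence",
                       "verdict": "pass" if corrected.converged else "warn",
                       "orientation": scan.orientation_tag,
                       "iterations": corrected.iterations,
                       "max_dose_change_gy": corrected.max_dose_change_gy})
        per_orientation[scan.orientation_tag] = dmap
        restored.append(restore_orientation(dmap))

    if len(restored) >= 2:
        merged = merge_orientations(
            restored, rel_threshold=outlier_rel_threshold,
            abs_threshold_gy=outlier_abs_threshold_gy)
        for tag, n in zip(merged.tags, merged.n_excluded_per_orientation):
            qc_log.append({"rule": "outlier_mask", "verdict": "info",
                           "orientation": tag, "masked_pixels": int(n)})
    else:
        only = restored[0]
        merged = MergedDose(dose=only.dose,
                            excluded=np.zeros((1,) + only.shape, dtype=bool),
                            spread=np.zeros(only.shape),
                            unreliable=np.zeros(only.shape, dtype=bool),
                            tags=(scans[0].orientation_tag,))

    profile = extract_profile(DoseMap(merged.dose), "transversal")
    return ReadoutResult(merged=merged, per_orientation=per_orientation,
                         qc_log=qc_log, profile=profile)


def write_report(result: ReadoutResult, out_dir: str | Path) -> dict:
    """Write machine-readable (JSON/CSV) and text summaries of a read-out."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dose = result.merged.dose
    summary = {
        "mean_dose_gy": float(dose.mean()),
        "median_dose_gy": float(np.median(dose)),
        "max_dose_gy": float(dose.max()),
        "max_abs_deviation_from_mean_pct": float(
            np.abs(dose / dose.mean() - 1.0).max() * 100.0)
        if dose.mean() != 0 else None,
        "masked_pixels_per_orientation": {
            tag: int(n) for tag, n in zip(
                result.merged.tags,
                result.merged.n_excluded_per_orientation)},
        "unreliable_pixels": int(result.merged.unreliable.sum()),
        "qc": result.qc_log,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    np.savetxt(out_dir / "dose.csv", dose, fmt="%.6g", delimiter=",")
    if result.profile is not None:
        np.savetxt(out_dir / "profile.csv",
                   np.column_stack([result.profile.positions,
                                    result.profile.values]),
                   fmt="%.6g", delimiter=",",
                   header="position_px,dose_gy", comments="")
    lines = [f"mean dose: {summary['mean_dose_gy']:.4f} Gy",
             f"median dose: {summary['median_dose_gy']:.4f} Gy"]
    for entry in result.qc_log:
        kv = " ".join(f"{k}={v}" for k, v in entry.items())
        lines.append(kv)
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary
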
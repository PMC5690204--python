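"""Two-phase flatbed-scanner sensitivity correction.

A consumer flatbed scanner does not respond uniformly over its bed: with
unexposed film the deficit is of order 300 PV at the left edge, zero in the
middle and up to 1800 PV at the right edge in the transversal (X)
direction, with a smaller (<= 340 PV) longitudinal structure. On the right
half of the bed the deficit additionally grows with the darkening of the
film, i.e. with dose.

Both effects are corrected additively in PV space:

    PV_corr(x, y) = PV(x, y) + M(x, y) + MD(x, dose)

* ``M`` — the *matrix correction*, a per-pixel, per-channel additive field
  derived from a stack of unexposed films, normalised to average zero over
  the central normalization area.
* ``MD`` — the *dose-dependent transversal correction*, a per-column,
  per-channel table derived from a constant-dose film stripe scanned at
  several transversal positions. Since ``MD`` is indexed by the very dose
  one is trying to measure, it is applied iteratively: a matrix-only dose
  estimate seeds the lookup and the estimate is refined to a fixed point.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationCurve, DOSE_CHANNELS, net_od, od_to_dose
from .dosemap import DoseMap
from .errors import (ConfigError, CoverageError, InputError,
                     InsufficientDataError)
from .film_image_io import CHANNELS, FilmScan, ROI, normalization_roi

#: PVs below this are treated as "no film / blocked light" and excluded.
MIN_VALID_PV = 1000.0


@dataclass
class MatrixCorrection:
    """Per-pixel additive scanner-flatness correction (phase one).

    ``m`` maps channel name -> (H, W) float array in PV units, zero-mean
    over the normalization ROI.
    """

    m: dict[str, np.ndarray]
    norm_roi: ROI
    n_scans: int
    lot_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.m["red"].shape

    def apply(self, scan: FilmScan) -> dict[str, np.ndarray]:
        """PV + M for every channel (float arrays)."""
        if (scan.height_px, scan.width_px) != self.shape:
            raise InputError(
                f"scan {scan.height_px}x{scan.width_px} does not match the "
                f"correction geometry {self.shape}")
        return {name: ch.astype(np.float64) + self.m[name]
                for name, ch in scan.channels()}


def build_matrix_correction(unexposed_scans: Sequence[FilmScan],
                            norm_roi: ROI | None = None, *,
                            lot_policy: str = "error") -> MatrixCorrection:
    """Derive the matrix correction from a stack of unexposed full-bed scans.

    Per channel, the pixelwise stack mean is computed and

        M[x, y] = mean(stack mean over norm ROI) - stack mean[x, y]

    so that adding ``M`` to the stack mean flattens it exactly to the
    normalization-ROI level. A global additive offset common to all input
    scans cancels.

    ``lot_policy``: "error" (default) rejects mixed film lots, "warn"
    accepts them.
    """
    if len(unexposed_scans) < 2:
        raise InsufficientDataError(
            f"matrix correction needs >= 2 unexposed scans, got "
            f"{len(unexposed_scans)}")
    first = unexposed_scans[0]
    lots = {s.lot_id for s in unexposed_scans}
    if len(lots) > 1:
        msg = f"unexposed stack mixes film lots: {sorted(lots)}"
        if lot_policy == "error":
            raise InputError(msg)
        import warnings
        warnings.warn(msg, stacklevel=2)
    shape = (first.height_px, first.width_px)
    for s in unexposed_scans[1:]:
        if (s.height_px, s.width_px) != shape:
            raise InputError("all unexposed scans must share dimensions")
    if norm_roi is None:
        norm_roi = normalization_roi(first.width_px, first.height_px)
    norm_roi.check_inside(first.width_px, first.height_px)

    m: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        stack_mean = np.mean(
            [s.channel(name).astype(np.float64) for s in unexposed_scans],
            axis=0)
        target = stack_mean[norm_roi.slices].mean()
        m[name] = target - stack_mean
    return MatrixCorrection(m=m, norm_roi=norm_roi,
                            n_scans=len(unexposed_scans),
                            lot_id=first.lot_id)


@dataclass
class DoseTransversalCorrection:
    """Per-column, dose-indexed additive correction table (phase two).

    ``md`` maps channel -> (n_doses, W) array; ``dose_grid`` is the
    ascending dose axis and always starts with an all-zero row at 0 Gy
    (an unexposed film is fully corrected by the matrix alone). Lookup is
    bilinear: exact in column (the table has one entry per column) and
    linear in dose, clamped to the grid ends.
    """

    md: dict[str, np.ndarray]
    dose_grid: np.ndarray
    norm_columns: tuple[int, int]      # [start, stop) of zero-correction band
    lot_id: str = ""

    def __post_init__(self) -> None:
        self.dose_grid = np.asarray(self.dose_grid, dtype=np.float64)
        if self.dose_grid[0] != 0.0 or np.any(np.diff(self.dose_grid) <= 0):
            raise InputError("dose grid must be ascending and start at 0 Gy")

    @property
    def width(self) -> int:
        return self.md["red"].shape[1]

    def lookup(self, channel: str, dose: np.ndarray) -> np.ndarray:
        """MD evaluated at per-pixel dose estimates.

        ``dose`` is (H, W); column index is implicit in the array layout.
        Linear interpolation in dose, constant beyond the grid ends.
        """
        table = self.md[channel]                     # (n_doses, W)
        grid = self.dose_grid
        d = np.clip(dose, grid[0], grid[-1])
        hi = np.searchsorted(grid, d, side="right")
        hi = np.clip(hi, 1, len(grid) - 1)
        lo = hi - 1
        span = grid[hi] - grid[lo]
        frac = np.where(span > 0, (d - grid[lo]) / np.where(span > 0, span, 1.0),
                        0.0)
        cols = np.arange(table.shape[1])[None, :]
        cols = np.broadcast_to(cols, dose.shape)
        return (1.0 - frac) * table[lo, cols] + frac * table[hi, cols]


def _stripe_column_means(channels: dict[str, np.ndarray],
                         raw_red: np.ndarray,
                         trim_rows: float = 0.2,
                         edge_trim_px: int = 2
                         ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-column mean of a matrix-corrected stripe scan, film columns only.

    Film presence is detected from the *raw* red channel (the holder blocks
    direct light, so non-film columns read near zero; the matrix correction
    would lift them by up to ~1800 PV and must not be consulted). The
    top/bottom fraction of rows and a few columns at the film edges are
    trimmed to avoid cut and penumbra effects.
    """
    h = raw_red.shape[0]
    rows = slice(int(h * trim_rows), int(h * (1.0 - trim_rows)))
    col_median = np.median(raw_red[rows].astype(np.float64), axis=0)
    covered = col_median > MIN_VALID_PV
    if covered.any() and edge_trim_px:
        idx = np.flatnonzero(covered)
        # trim only at the boundaries of each contiguous run
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        keep = np.zeros_like(covered)
        for run in runs:
            if run.size > 2 * edge_trim_px:
                keep[run[edge_trim_px:-edge_trim_px]] = True
        covered = keep
    means = {name: ch[rows].mean(axis=0) for name, ch in channels.items()}
    return means, covered


def build_dose_transversal_correction(
        stripe_scans: Sequence[FilmScan] | dict[float, Sequence[FilmScan]],
        stripe_dose: float | None,
        matrix: MatrixCorrection, *,
        norm_roi: ROI | None = None) -> DoseTransversalCorrection:
    """Derive the dose-dependent transversal correction from stripe scans.

    A film stripe exposed to one uniform, known dose is scanned at several
    transversal positions spanning the bed. After matrix correction, the
    per-column mean PV of each placement is compared with the level the
    same stripe reads on the normalization columns:

        MD[x, d] = PV_corr(norm columns, d) - PV_corr(x, d)

    Overlapping placements are averaged; columns never covered are filled
    by linear interpolation between covered neighbours (constant beyond the
    outermost covered columns); the normalization columns are zero by
    construction.

    ``stripe_scans`` may be a dict mapping dose (Gy) to its stripe set to
    build a multi-level table; the implicit 0 Gy row is always all zeros.
    """
    if isinstance(stripe_scans, dict):
        sets = dict(stripe_scans)
    else:
        if stripe_dose is None:
            raise InputError("stripe_dose is required for a single stripe set")
        sets = {float(stripe_dose): list(stripe_scans)}
    for dose in sets:
        if dose <= 0:
            raise InputError(f"stripe dose must be positive, got {dose} Gy")

    if norm_roi is None:
        norm_roi = matrix.norm_roi
    width = matrix.shape[1]
    norm_cols = (norm_roi.x0, norm_roi.x0 + norm_roi.width)

    grid = [0.0]
    tables = {name: [np.zeros(width)] for name in CHANNELS}
    for dose in sorted(sets):
        scans = sets[dose]
        if not scans:
            raise InsufficientDataError(f"no stripe scans for {dose} Gy")
        acc = {name: np.zeros(width) for name in CHANNELS}
        cnt = np.zeros(width)
        ref = {name: [] for name in CHANNELS}
        per_scan = []
        for scan in scans:
            channels = matrix.apply(scan)
            means, covered = _stripe_column_means(channels, scan.red)
            per_scan.append((means, covered))
            norm_mask = np.zeros(width, dtype=bool)
            norm_mask[norm_cols[0]:norm_cols[1]] = True
            on_norm = covered & norm_mask
            if on_norm.any():
                for name in CHANNELS:
                    ref[name].append(means[name][on_norm].mean())
        if not ref["red"]:
            raise CoverageError(
                "no stripe placement covers the normalization columns; "
                "the reference level cannot be established")
        ref_level = {name: float(np.mean(vals)) for name, vals in ref.items()}
        for means, covered in per_scan:
            cnt[covered] += 1
            for name in CHANNELS:
                acc[name][covered] += ref_level[name] - means[name][covered]
        if not cnt.any():
            raise CoverageError("stripe scans cover no columns at all")
        for name in CHANNELS:
            row = np.full(width, np.nan)
            row[cnt > 0] = acc[name][cnt > 0] / cnt[cnt > 0]
            covered_idx = np.flatnonzero(cnt > 0)
            row = np.interp(np.arange(width), covered_idx, row[covered_idx])
            row[norm_cols[0]:norm_cols[1]] = 0.0
            tables[name].append(row)
        grid.append(dose)

    md = {name: np.vstack(rows) for name, rows in tables.items()}
    return DoseTransversalCorrection(md=md, dose_grid=np.array(grid),
                                     norm_columns=norm_cols,
                                     lot_id=matrix.lot_id)


# ---------------------------------------------------------------------------
# Iterative application


@dataclass
class CorrectedScan:
    """Fully corrected PVs and the bookkeeping of the fixed-point iteration."""

    channels: dict[str, np.ndarray]       # PV + M + MD at the converged dose
    background_channels: dict[str, np.ndarray]
    iterations: int
    max_dose_change_gy: float
    converged: bool
    dose_changes_gy: list[float] = field(default_factory=list)


def apply_corrections_iterative(
        scan: FilmScan, background: FilmScan | dict[str, np.ndarray],
        matrix: MatrixCorrection,
        mdcorr: DoseTransversalCorrection | None,
        curve: CalibrationCurve, *,
        channels: Sequence[str] = DOSE_CHANNELS,
        max_iter: int = 10, tol_gy: float | None = None,
        right_mask_from_col: int | None = None,
        on_out_of_range: str = "clamp") -> tuple[CorrectedScan, DoseMap]:
    """Correct an exposed scan and convert it to dose, iterating the
    dose-dependent term to its fixed point.

    Iteration 0 applies the matrix correction only (to both the exposed
    scan and its paired background), computes net OD per pixel and a first
    dose estimate as the mean of the requested channels' doses. Each
    further iteration re-applies ``PV + M + MD(x, D_prev)`` with the
    previous combined dose estimate and stops when the largest per-pixel
    dose change falls below ``tol_gy`` (default: 0.1 % of the median dose,
    at least 0.002 Gy). ``max_iter=0`` or ``mdcorr=None`` gives the
    matrix-only result.

    ``right_mask_from_col`` optionally invalidates columns from that index
    rightwards (the bed region with the largest artifact).

    ``background`` is the film's pre-irradiation scan; it is matrix-
    corrected here (an unexposed film needs no MD term). Alternatively a
    dict of *already corrected* background channel arrays may be passed —
    the four-orientation pipeline corrects the background once in its own
    scanned frame and re-orients it per exposed scan.
    """
    if isinstance(background, dict):
        pv_un = background
    else:
        if (background.scan_time and scan.exposure_time
                and (scan.exposure_time - background.scan_time).days > 7):
            import warnings
            warnings.warn("background was scanned more than 7 days before "
                          "irradiation", stacklevel=2)
        pv_un = matrix.apply(background)  # background is unexposed: MD = 0
    pv_ex0 = matrix.apply(scan)

    valid = np.ones(matrix.shape, dtype=bool)
    for name in channels:
        valid &= scan.channel(name) > MIN_VALID_PV
        valid &= pv_un[name] > MIN_VALID_PV

    def to_dose(pv_ex: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        per_channel = {}
        for name in channels:
            od = np.full(matrix.shape, 0.0)
            od[valid] = net_od(pv_un[name][valid], pv_ex[name][valid])
            per_channel[name] = od_to_dose(od, curve, name,
                                           on_out_of_range=on_out_of_range)
        return per_channel

    dose_ch = to_dose(pv_ex0)
    dose = np.mean([dose_ch[name] for name in channels], axis=0)
    pv_corr = pv_ex0

    changes: list[float] = []
    converged = mdcorr is None or max_iter == 0
    if tol_gy is None:
        med = float(np.median(dose[valid])) if valid.any() else 0.0
        tol_gy = max(0.002, 1e-3 * med)
    it = 0
    if mdcorr is not None:
        for it in range(1, max_iter + 1):
            pv_corr = {name: pv_ex0[name] + mdcorr.lookup(name, dose)
                       for name in channels}
            dose_ch = to_dose(pv_corr)
            new_dose = np.mean([dose_ch[name] for name in channels], axis=0)
            change = float(np.abs(new_dose - dose)[valid].max()) if valid.any() else 0.0
            changes.append(change)
            dose = new_dose
            if change < tol_gy:
                converged = True
                break
        else:
            it = max_iter
        if max_iter > 0:
            # sync PV_corr to the final dose so the additive identity
            # PV_corr = PV + M + MD(x, D) holds pointwise at the fixed point
            pv_corr = {name: pv_ex0[name] + mdcorr.lookup(name, dose)
                       for name in channels}

    if right_mask_from_col is not None:
        valid = valid.copy()
        valid[:, right_mask_from_col:] = False

    corrected = CorrectedScan(
        channels=pv_corr, background_channels=pv_un, iterations=it,
        max_dose_change_gy=changes[-1] if changes else 0.0,
        converged=converged, dose_changes_gy=changes)
    dmap = DoseMap(
        dose, valid=valid, orientation_tag=scan.orientation_tag,
        film_id=scan.film_id,
        provenance={"iterations": it, "converged": converged,
                    "tol_gy": tol_gy, "channels": list(channels),
                    "matrix_scans": matrix.n_scans,
                    "md": mdcorr is not None and max_iter > 0})
    return corrected, dmap


@dataclass
class CorrectedBackground:
    """A matrix-corrected background scan, re-orientable per exposed scan.

    The background is scanned once (normal orientation); for an exposed
    scan taken in another orientation the corrected background must be
    index-transformed into that scan's frame so that the net-OD ratio
    PV_un/PV_ex pairs pixels of the same film point. Exact for the symmetric, centered
    film placements the holder enforces.
    """

    channels: dict[str, np.ndarray]

    def for_orientation(self, tag: str) -> dict[str, np.ndarray]:
        from .readout_merge import orientation_transform
        return {name: orientation_transform(ch, tag)
                for name, ch in self.channels.items()}


def orientationless_background(background: FilmScan,
                               matrix: MatrixCorrection
                               ) -> CorrectedBackground:
    """Matrix-correct a background scan in its own scanned frame."""
    return CorrectedBackground(matrix.apply(background))


# ---------------------------------------------------------------------------
# Correction archive (portable directory or zip)


def save_corrections(matrix: MatrixCorrection,
                     mdcorr: DoseTransversalCorrection | None,
                     path: str | Path) -> Path:
    """Persist corrections as a directory (or .zip) of NPY arrays, an MD CSV
    and a JSON manifest."""
    path = Path(path)
    as_zip = path.suffix == ".zip"
    workdir = path.with_suffix(".tmpdir") if as_zip else path
    workdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "lot_id": matrix.lot_id,
        "n_scans": matrix.n_scans,
        "norm_roi": vars(matrix.norm_roi),
        "channels": list(CHANNELS),
        "has_md": mdcorr is not None,
    }
    for name in CHANNELS:
        np.save(workdir / f"matrix_{name}.npy", matrix.m[name])
    if mdcorr is not None:
        import pandas as pd
        rows = []
        for name in CHANNELS:
            for di, d in enumerate(mdcorr.dose_grid):
                for x in range(mdcorr.width):
                    rows.append((name, x, d, mdcorr.md[name][di, x]))
        pd.DataFrame(rows, columns=["channel", "x", "dose_Gy", "correction_PV"]
                     ).to_csv(workdir / "md.csv", index=False)
        manifest["md_dose_grid"] = mdcorr.dose_grid.tolist()
        manifest["md_norm_columns"] = list(mdcorr.norm_columns)
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if as_zip:
        with zipfile.ZipFile(path, "w") as zf:
            for f in sorted(workdir.iterdir()):
                zf.write(f, f.name)
        for f in workdir.iterdir():
            f.unlink()
        workdir.rmdir()
    return path


def load_corrections(path: str | Path
                     ) -> tuple[MatrixCorrection, DoseTransversalCorrection | None]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"correction archive not found: {path}")
    if path.suffix == ".zip":
        import tempfile
        tmp = Path(tempfile.mkdtemp())
        with zipfile.ZipFile(path) as zf:
            zf.extractall(tmp)
        path = tmp
    manifest = json.loads((path / "manifest.json").read_text())
    m = {name: np.load(path / f"matrix_{name}.npy") for name in CHANNELS}
    matrix = MatrixCorrection(
        m=m, norm_roi=ROI(**manifest["norm_roi"]),
        n_scans=manifest["n_scans"], lot_id=manifest.get("lot_id", ""))
    mdcorr = None
    if manifest.get("has_md"):
        import pandas as pd
        df = pd.read_csv(path / "md.csv")
        grid = np.array(manifest["md_dose_grid"])
        width = matrix.shape[1]
        md = {}
        for name in CHANNELS:
            sub = df[df.channel == name]
            table = np.zeros((len(grid), width))
            table[sub.dose_Gy.map({d: i for i, d in enumerate(grid)}).values,
                  sub.x.values] = sub.correction_PV.values
            md[name] = table
        mdcorr = DoseTransversalCorrection(
            md=md, dose_grid=grid,
            norm_columns=tuple(manifest["md_norm_columns"]),
            lot_id=manifest.get("lot_id", ""))
    return matrix, mdcorr
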
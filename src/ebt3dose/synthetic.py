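"""Synthetic scanner + film + dose-field simulator.

Generates ground-truth-paired 48-bit film scans so that every stage of the
read-out pipeline can be exercised without a scanner or a beam. The
simulator is the *inverse* of the analysis chain: a ground-truth dose field
is pushed through a known film response to pixel values, then degraded with
the scanner's position- and dose-dependent sensitivity structure, per-scan
drift, dust and noise.

Modelled effects and their default magnitudes:

* transversal scanner deficit: ~300 PV at the left edge, zero across the
  central normalization columns, rising to 1800 PV at the right edge
  (quadratic in distance from the normalization band);
* longitudinal deficit: up to 340 PV, not dose-dependent;
* dose-dependent lateral deficit on the right half: amplitude
  ``900 PV * D/(D + 1 Gy)`` at the right edge (600 PV at 2 Gy), zero at
  zero dose and over the normalization columns;
* per-scan drift of exposed film: +0.03 % per successive scan;
* film emulsion bands: longitudinal, multiplicative, strongest in blue;
* piece-to-piece background offsets, pixel noise, and per-orientation
  dust specks on the scanner glass.

Scanner artifacts are injected *additively* in PV (the same model class the
correction assumes); an optional multiplicative mismatch knob exists to
probe robustness and is off by default. All randomness flows from one
explicit seed and fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, ChannelFit, dose_to_od
from .errors import GeometryError, InputError
from .film_image_io import (CHANNELS, FULL_BED_HEIGHT, FULL_BED_WIDTH,
                            FilmScan, ROI, cm_to_px, normalization_roi,
                            write_film_tiff)
from .readout_merge import orientation_transform


def default_true_curve() -> CalibrationCurve:
    """Ground-truth rational dose-response used by the simulator.

    Chosen once so that, with the default backgrounds, a 2 Gy exposure
    reads ~26 200 PV in the red channel (the working point of the
    uncertainty budget) and 8 Gy is still on the invertible branch.
    """
    return CalibrationCurve(
        channels={
            "red": ChannelFit(a=0.0, b=-0.6027, c=9.723),
            "green": ChannelFit(a=0.0, b=-0.7937, c=12.70),
            "blue": ChannelFit(a=0.0, b=-2.778, c=27.78),
        },
        lot_id="SIM-LOT-01", quality="Co-60", dose_range=(0.0, 8.0),
        form="rational")


@dataclass
class ScannerModel:
    """Position- and dose-dependent sensitivity structure of the scanner."""

    width_px: int = FULL_BED_WIDTH
    height_px: int = FULL_BED_HEIGHT
    left_deficit_pv: float = 300.0
    right_deficit_pv: float = 1800.0
    longitudinal_deficit_pv: float = 340.0
    dose_lateral_amplitude_pv: float = 900.0   # right edge, saturating dose
    dose_lateral_half_gy: float = 1.0          # D/(D + half) dose dependence
    noise_sd_pv: float = 5.0
    drift_per_scan: float = 3.0e-4             # exposed film only
    multiplicative_mismatch: float = 0.0       # model-mismatch knob, off

    def __post_init__(self) -> None:
        self.norm_roi: ROI = normalization_roi(self.width_px, self.height_px)

    # -- deterministic sensitivity fields -----------------------------------

    def transversal_deficit(self) -> np.ndarray:
        """Base (unexposed-film) deficit per column, PV; zero on norm columns."""
        x = np.arange(self.width_px, dtype=np.float64)
        lo, hi = self.norm_roi.x0, self.norm_roi.x0 + self.norm_roi.width - 1
        out = np.zeros_like(x)
        left = x < lo
        out[left] = self.left_deficit_pv * ((lo - x[left]) / lo) ** 2
        right = x > hi
        out[right] = (self.right_deficit_pv
                      * ((x[right] - hi) / (self.width_px - 1 - hi)) ** 2)
        return out

    def longitudinal_deficit(self) -> np.ndarray:
        """Per-row deficit, PV; zero on the normalization rows."""
        y = np.arange(self.height_px, dtype=np.float64)
        lo, hi = self.norm_roi.y0, self.norm_roi.y0 + self.norm_roi.height - 1
        out = np.zeros_like(y)
        scale = max(lo, self.height_px - 1 - hi)
        top = y < lo
        out[top] = self.longitudinal_deficit_pv * ((lo - y[top]) / scale) ** 2
        bottom = y > hi
        out[bottom] = (self.longitudinal_deficit_pv
                       * ((y[bottom] - hi) / scale) ** 2)
        return out

    def base_deficit(self) -> np.ndarray:
        """(H, W) additive PV deficit for unexposed film."""
        return (self.transversal_deficit()[None, :]
                + self.longitudinal_deficit()[:, None])

    def lateral_gain_shape(self) -> np.ndarray:
        """Column shape of the dose-dependent deficit: 0 left of the
        normalization band, quadratic to 1 at the right edge."""
        x = np.arange(self.width_px, dtype=np.float64)
        hi = self.norm_roi.x0 + self.norm_roi.width - 1
        shape = np.zeros_like(x)
        right = x > hi
        shape[right] = ((x[right] - hi) / (self.width_px - 1 - hi)) ** 2
        return shape

    def dose_deficit(self, dose: np.ndarray) -> np.ndarray:
        """(H, W) additive PV deficit for a scanner-frame dose field."""
        f = dose / (dose + self.dose_lateral_half_gy)
        return (self.dose_lateral_amplitude_pv
                * self.lateral_gain_shape()[None, :] * f)


@dataclass
class FilmModel:
    """Film lot: background level, response curve and inhomogeneity."""

    background_pv: dict[str, float] = field(
        default_factory=lambda: {"red": 40000.0, "green": 40500.0,
                                 "blue": 38000.0})
    #: 1-SD relative piece-to-piece background offset.
    piece_offset_sd: dict[str, float] = field(
        default_factory=lambda: {"red": 1.0e-3, "green": 1.0e-3,
                                 "blue": 2.0e-3})
    #: Max relative deviation of the longitudinal emulsion bands.
    band_max_dev: dict[str, float] = field(
        default_factory=lambda: {"red": 3.0e-4, "green": 3.0e-4,
                                 "blue": 3.0e-3})
    curve: CalibrationCurve = field(default_factory=default_true_curve)
    lot_id: str = "SIM-LOT-01"

    @property
    def dose_range(self) -> tuple[float, float]:
        return self.curve.dose_range

    def od(self, dose, channel: str):
        """Exact ground-truth net OD for a dose (scalar or array)."""
        return dose_to_od(dose, self.curve, channel)

    def sample_piece(self, width_px: int, rng: np.random.Generator,
                     film_id: str = "") -> "FilmPiece":
        """Draw one physical film piece: offset + band pattern per channel.

        The emulsion-thickness pattern is a single smooth profile across
        the film width (a few low-order sinusoids), scaled per channel —
        blue being the most sensitive to it.
        """
        n_modes = 3
        freqs = rng.uniform(1.0, 4.0, n_modes)
        phases = rng.uniform(0.0, 2 * np.pi, n_modes)
        weights = rng.uniform(0.5, 1.0, n_modes)
        fx = np.arange(width_px) / max(width_px - 1, 1)
        shape = np.zeros(width_px)
        for f, p, w in zip(freqs, phases, weights):
            shape += w * np.sin(2 * np.pi * f * fx + p)
        peak = np.abs(shape).max()
        shape = shape / peak if peak > 0 else shape
        band = {ch: self.band_max_dev[ch] * shape for ch in CHANNELS}
        background = {
            ch: self.background_pv[ch]
            * (1.0 + self.piece_offset_sd[ch] * rng.standard_normal())
            for ch in CHANNELS}
        return FilmPiece(film_id=film_id, lot_id=self.lot_id,
                         width_px=width_px, background=background,
                         band=band, model=self)


@dataclass
class FilmPiece:
    """One physical piece of film: its background and inhomogeneity."""

    film_id: str
    lot_id: str
    width_px: int
    background: dict[str, float]
    band: dict[str, np.ndarray]      # per-column multiplicative deviation
    model: FilmModel

    def background_image(self, height_px: int, channel: str) -> np.ndarray:
        return (self.background[channel]
                * (1.0 + self.band[channel])[None, :]
                * np.ones((height_px, 1)))


# ---------------------------------------------------------------------------
# Dose fields


def uniform_field(dose_gy: float, shape: tuple[int, int]) -> np.ndarray:
    if dose_gy < 0:
        raise InputError("dose must be non-negative")
    return np.full(shape, float(dose_gy))


def flat_top_field(dose_gy: float, shape: tuple[int, int],
                   field_cm: tuple[float, float] = (10.0, 10.0),
                   penumbra_mm: float = 5.0) -> np.ndarray:
    """Flat-top field (e.g. 10 cm x 10 cm) with linear penumbra, centered."""
    h, w = shape
    fy, fx = cm_to_px(field_cm[1]), cm_to_px(field_cm[0])
    pen = max(cm_to_px(penumbra_mm / 10.0), 1)

    def edge_profile(n, half):
        d = np.abs(np.arange(n) - (n - 1) / 2.0)
        return np.clip((half + pen / 2.0 - d) / pen, 0.0, 1.0)

    return dose_gy * np.outer(edge_profile(h, fy / 2.0),
                              edge_profile(w, fx / 2.0))


#: Post-exposure darkening of the film relative to the 4-day read-out level:
#: fast rise over the first two days, +0.2 % from day 2 to 4, ~+1 % from
#: day 4 to 16. Piecewise-linear, clamped outside the sampled range.
_DARKENING_DAYS = np.array([0.0, 2.0, 4.0, 16.0])
_DARKENING_FACTOR = np.array([0.970, 0.998, 1.000, 1.010])


def post_exposure_od_factor(hours_since_exposure: float) -> float:
    """OD multiplier vs time since exposure, normalized to 1 at 96 h."""
    days = hours_since_exposure / 24.0
    return float(np.interp(days, _DARKENING_DAYS, _DARKENING_FACTOR))


# ---------------------------------------------------------------------------
# The scan simulator


@dataclass
class SimulationTruth:
    """Everything a test needs to verify a recovered quantity."""

    dose_film_frame: np.ndarray
    dose_scanner_frame: np.ndarray
    film_region: tuple[slice, slice]      # scanner-frame slices
    piece: FilmPiece
    orientation_tag: str
    speck_mask: np.ndarray | None         # scanner-frame bool, dusty pixels
    seed: int | None
    net_od: dict[str, np.ndarray] | None = None


def _film_region(scanner: ScannerModel, film_shape: tuple[int, int],
                 center_col: int | None) -> tuple[slice, slice]:
    fh, fw = film_shape
    if fh > scanner.height_px or fw > scanner.width_px:
        raise GeometryError(
            f"film {fh}x{fw} does not fit the bed "
            f"{scanner.height_px}x{scanner.width_px}")
    y0 = (scanner.height_px - fh) // 2
    if center_col is None:
        x0 = (scanner.width_px - fw) // 2
    else:
        x0 = int(round(center_col - fw / 2.0))
    if x0 < 0 or x0 + fw > scanner.width_px:
        raise GeometryError(
            f"film placement at center column {center_col} leaves the bed")
    return (slice(y0, y0 + fh), slice(x0, x0 + fw))


def simulate_scan(dose_field: np.ndarray, piece: FilmPiece,
                  scanner: ScannerModel, *,
                  orientation: str = "normal", scan_index: int = 0,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None,
                  center_col: int | None = None,
                  n_dust_specks: int = 0,
                  hours_since_exposure: float | None = None
                  ) -> tuple[FilmScan, SimulationTruth]:
    """Simulate one scanner read of a film piece carrying a dose field.

    ``dose_field`` is in the *film frame* and must match the piece width.
    The film is placed centered longitudinally; ``center_col`` sets the
    transversal placement (default: bed center). The orientation tag
    transforms film to scanner frame before the scanner's position-dependent
    degradation is applied; dust specks live on the scanner glass and are
    drawn independently per scan. Deterministic for a given seed.
    """
    dose_field = np.asarray(dose_field, dtype=np.float64)
    if dose_field.ndim != 2 or dose_field.shape[1] != piece.width_px:
        raise InputError(
            f"dose field shape {dose_field.shape} does not match the film "
            f"piece width {piece.width_px}")
    lo, hi = piece.model.dose_range
    if dose_field.min() < lo or dose_field.max() > hi:
        raise InputError(
            f"dose field exceeds the film's monotone response range "
            f"[{lo}, {hi}] Gy")
    if rng is None:
        rng = np.random.default_rng(seed)

    od_scale = (post_exposure_od_factor(hours_since_exposure)
                if hours_since_exposure is not None else 1.0)

    # Film-frame PV image per channel, then into the scanner frame.
    film_pv = {}
    net = {}
    for ch in CHANNELS:
        od = piece.model.od(dose_field, ch) * od_scale
        net[ch] = od
        film_pv[ch] = (piece.background_image(dose_field.shape[0], ch)
                       * np.power(10.0, -od))

    oriented_dose = orientation_transform(dose_field, orientation)
    region = _film_region(scanner, oriented_dose.shape, center_col)
    base = scanner.base_deficit()
    canvas_dose = np.zeros((scanner.height_px, scanner.width_px))
    canvas_dose[region] = oriented_dose
    dd = scanner.dose_deficit(canvas_dose)

    exposed = dose_field.max() > 0
    drift = (1.0 + scanner.drift_per_scan * scan_index) if exposed else 1.0

    speck_mask = None
    if n_dust_specks > 0:
        speck_mask = np.zeros((scanner.height_px, scanner.width_px),
                              dtype=bool)
        yy, xx = np.mgrid[0:scanner.height_px, 0:scanner.width_px]
        for _ in range(n_dust_specks):
            cy = rng.integers(region[0].start + 5, region[0].stop - 5)
            cx = rng.integers(region[1].start + 5, region[1].stop - 5)
            r = rng.uniform(1.0, 3.0)
            speck_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        speck_depth = rng.uniform(0.06, 0.12)

    channels = {}
    for ch in CHANNELS:
        canvas = np.zeros((scanner.height_px, scanner.width_px))
        oriented = orientation_transform(film_pv[ch], orientation)
        canvas[region] = oriented * drift
        deficit = base + dd
        if scanner.multiplicative_mismatch:
            deficit = deficit * (1.0 + scanner.multiplicative_mismatch
                                 * (canvas / 65535.0))
        film_mask = np.zeros_like(canvas, dtype=bool)
        film_mask[region] = True
        canvas[film_mask] -= deficit[film_mask]
        if speck_mask is not None:
            canvas[speck_mask & film_mask] *= (1.0 - speck_depth)
        if scanner.noise_sd_pv > 0:
            canvas[film_mask] += scanner.noise_sd_pv * rng.standard_normal(
                int(film_mask.sum()))
        channels[ch] = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)

    scan = FilmScan(red=channels["red"], green=channels["green"],
                    blue=channels["blue"], film_id=piece.film_id,
                    lot_id=piece.lot_id, orientation_tag=orientation,
                    scan_index=scan_index)
    truth = SimulationTruth(
        dose_film_frame=dose_field, dose_scanner_frame=canvas_dose,
        film_region=region, piece=piece, orientation_tag=orientation,
        speck_mask=speck_mask, seed=seed, net_od=net)
    return scan, truth


# ---------------------------------------------------------------------------
# Fixture generators


def generate_unexposed_stack(n: int, film: FilmModel, scanner: ScannerModel,
                             seed: int) -> list[FilmScan]:
    """``n`` unexposed full-bed scans of ``n`` distinct films, shared
    scanner field, independent noise — the input of the matrix correction."""
    if n < 2:
        raise InputError(f"an unexposed stack needs n >= 2 films, got {n}")
    rng = np.random.default_rng(seed)
    shape = (scanner.height_px, scanner.width_px)
    scans = []
    for i in range(n):
        piece = film.sample_piece(shape[1], rng, film_id=f"unexposed-{i:02d}")
        scan, _ = simulate_scan(uniform_field(0.0, shape), piece, scanner,
                                rng=rng)
        scans.append(scan)
    return scans


#: 5 cm stripe width at 72 dpi.
STRIPE_WIDTH_PX = cm_to_px(5.0)


def default_stripe_positions(scanner: ScannerModel,
                             n: int = 5) -> list[int]:
    """Evenly spaced stripe centers covering the bed left to right."""
    half = STRIPE_WIDTH_PX // 2
    return [int(round(c)) for c in
            np.linspace(half, scanner.width_px - half - 1, n)]


def generate_stripe_series(dose_gy: float, positions: Sequence[int],
                           film: FilmModel, scanner: ScannerModel,
                           seed: int, *,
                           reel_uniformity_sd: float = 0.002
                           ) -> tuple[list[FilmScan], SimulationTruth]:
    """One constant-dose stripe scanned at several transversal positions.

    The stripe is a single physical film exposed once on a rotating reel
    (dose uniform to ~0.2 % 1 SD), so its exposure pattern and emulsion
    bands travel with it between placements. Placements must lie fully on
    the bed; exact duplicates are rejected, partial overlap of adjacent
    placements is expected and later averaged.
    """
    if dose_gy <= 0:
        raise InputError("stripe dose must be positive")
    if len(set(positions)) != len(positions):
        raise GeometryError("duplicate stripe positions")
    rng = np.random.default_rng(seed)
    piece = film.sample_piece(STRIPE_WIDTH_PX, rng, film_id="stripe-2gy")
    shape = (scanner.height_px, STRIPE_WIDTH_PX)
    dose = dose_gy * (1.0 + reel_uniformity_sd * rng.standard_normal(shape))
    scans = []
    truth = None
    for pos in positions:
        scan, truth = simulate_scan(dose, piece, scanner, center_col=pos,
                                    rng=rng)
        scans.append(scan)
    assert truth is not None
    return scans, truth


def generate_calibration_set(doses_gy: Sequence[float], film: FilmModel,
                             scanner: ScannerModel, seed: int, *,
                             out_dir: str | Path | None = None,
                             piece_size_cm: tuple[float, float] = (5.0, 6.0)
                             ) -> tuple[list[dict], pd.DataFrame]:
    """Background + exposed scan pairs for a calibration exposure series.

    One film piece per dose level, placed centered; each piece gets its
    own pre-irradiation background scan (the pairing that makes net OD a
    per-piece quantity). Returns the scan records and a truth table of the
    exact per-channel net OD at each dose. Optionally writes TIFF + truth
    CSV fixtures to ``out_dir``.
    """
    doses = [float(d) for d in doses_gy]
    if not doses:
        raise InputError("empty calibration dose list")
    if not any(abs(d - 2.0) < 1e-9 for d in doses):
        import warnings
        warnings.warn("calibration series does not include the 2 Gy "
                      "working-point dose", stacklevel=2)
    rng = np.random.default_rng(seed)
    w, h = cm_to_px(piece_size_cm[0]), cm_to_px(piece_size_cm[1])
    records = []
    truth_rows = []
    for i, dose in enumerate(sorted(doses)):
        piece = film.sample_piece(w, rng, film_id=f"cal-{dose:g}Gy")
        bg, _ = simulate_scan(uniform_field(0.0, (h, w)), piece, scanner,
                              rng=rng)
        ex, _ = simulate_scan(uniform_field(dose, (h, w)), piece, scanner,
                              rng=rng)
        records.append({"dose_gy": dose, "background": bg, "exposed": ex,
                        "piece": piece})
        truth_rows.append({"dose_gy": dose,
                           **{f"od_{ch}": film.od(dose, ch)
                              for ch in CHANNELS}})
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec in records:
            stem = f"cal_{rec['dose_gy']:g}Gy"
            write_film_tiff(rec["background"], out_dir / f"{stem}_bg.tif")
            write_film_tiff(rec["exposed"], out_dir / f"{stem}_ex.tif")
        truth.to_csv(out_dir / "truth.csv", index=False)
    return records, truth


def generate_orientation_set(dose_field: np.ndarray, piece: FilmPiece,
                             scanner: ScannerModel, seed: int, *,
                             n_dust_specks: int = 0,
                             dusty_orientation: str | None = None
                             ) -> dict[str, tuple[FilmScan, SimulationTruth]]:
    """The four-orientation scan set of one exposed film.

    Dust specks, when requested, are injected into ``dusty_orientation``
    only (dirt on the glass between scans) or into every orientation
    independently when that is None.
    """
    from .film_image_io import ORIENTATION_TAGS
    rng = np.random.default_rng(seed)
    out = {}
    for tag in ORIENTATION_TAGS:
        dust = n_dust_specks if (dusty_orientation is None
                                 or tag == dusty_orientation) else 0
        out[tag] = simulate_scan(dose_field, piece, scanner, orientation=tag,
                                 rng=rng, n_dust_specks=dust)
    return out
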
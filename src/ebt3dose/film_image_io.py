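"""Reading, writing and basic statistics of 48-bit RGB film scans.

A film scan is a flatbed-scanner transmission image of a radiochromic film:
three 16-bit channel planes (red, green, blue) at a fixed 72 dpi geometry.
Full-bed scans are always 576 x 720 pixels, X (width) being the transversal
scanner axis — the one with the dose-dependent sensitivity artifact — and
Y (height) the longitudinal axis. Coordinates are 0-based with the origin
at the top-left corner; ROIs are half-open ``[x0, x0+w) x [y0, y0+h)``.

No colour management is ever applied: pixel values (PVs) are the scanner's
raw transmission intensities, higher PV meaning more transmitted light and
therefore lower dose.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile

from .errors import (BitDepthError, GeometryError, InputError,
                     InsufficientDataError)

#: Fixed scan geometry for a full scanner bed at 72 dpi.
FULL_BED_WIDTH = 576
FULL_BED_HEIGHT = 720
SCAN_DPI = 72
#: Pixel pitch in mm at 72 dpi (25.4 mm / 72).
PIXEL_PITCH_MM = 25.4 / SCAN_DPI

CHANNELS = ("red", "green", "blue")
ORIENTATION_TAGS = ("normal", "rot180", "flipped", "flipped_rot180")

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


def cm_to_px(length_cm: float, dpi: int = SCAN_DPI) -> int:
    """Convert a physical length in cm to pixels at the scan dpi (nearest px)."""
    return int(round(length_cm / 2.54 * dpi))


def mm_to_px(length_mm: float, dpi: int = SCAN_DPI) -> int:
    return int(round(length_mm / 25.4 * dpi))


@dataclass(frozen=True)
class ROI:
    """Rectangular half-open region of interest, 0-based, top-left origin."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise GeometryError(f"ROI must have positive size, got {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise GeometryError(f"ROI origin must be non-negative, got {self}")

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices for indexing a channel array."""
        return (slice(self.y0, self.y0 + self.height),
                slice(self.x0, self.x0 + self.width))

    def check_inside(self, width_px: int, height_px: int) -> None:
        if self.x0 + self.width > width_px or self.y0 + self.height > height_px:
            raise GeometryError(
                f"ROI {self} extends beyond image bounds {width_px}x{height_px}")

    @classmethod
    def centered(cls, width: int, height: int,
                 image_width: int = FULL_BED_WIDTH,
                 image_height: int = FULL_BED_HEIGHT) -> "ROI":
        """ROI of a given pixel size centered on the image."""
        return cls((image_width - width) // 2, (image_height - height) // 2,
                   width, height)

    @classmethod
    def centered_cm(cls, width_cm: float, height_cm: float,
                    image_width: int = FULL_BED_WIDTH,
                    image_height: int = FULL_BED_HEIGHT,
                    dpi: int = SCAN_DPI) -> "ROI":
        """Centered ROI specified in cm, converted at the fixed scan dpi."""
        return cls.centered(cm_to_px(width_cm, dpi), cm_to_px(height_cm, dpi),
                            image_width, image_height)


def normalization_roi(image_width: int = FULL_BED_WIDTH,
                      image_height: int = FULL_BED_HEIGHT) -> ROI:
    """The 3 cm x 4 cm normalization area in the middle of the scanner plate.

    All scanner corrections are expressed relative to this region: the
    matrix correction averages to zero over it and the dose-dependent
    transversal correction vanishes on its columns.
    """
    return ROI.centered_cm(3.0, 4.0, image_width, image_height)


def scoring_roi(image_width: int = FULL_BED_WIDTH,
                image_height: int = FULL_BED_HEIGHT) -> ROI:
    """The 35 mm x 40 mm central scoring area used for calibration read-out."""
    return ROI.centered(mm_to_px(35.0), mm_to_px(40.0), image_width, image_height)


@dataclass
class FilmScan:
    """One 48-bit RGB transmission scan of a film (piece, stripe or sheet).

    Channel arrays are stored (height, width); integer dtype for raw scans,
    float for derived (e.g. trend-averaged) scans.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    film_id: str = ""
    lot_id: str = ""
    orientation_tag: str = "normal"
    scan_time: datetime | None = None
    exposure_time: datetime | None = None
    scan_index: int = 0
    dpi: int = SCAN_DPI

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1 or self.red.ndim != 2:
            raise InputError(f"channel planes must share one 2D shape, got {shapes}")
        if self.orientation_tag not in ORIENTATION_TAGS:
            raise InputError(f"unknown orientation tag {self.orientation_tag!r}")
        for name in CHANNELS:
            ch = getattr(self, name)
            if np.issubdtype(ch.dtype, np.integer):
                if ch.min() < 0 or ch.max() > 65535:
                    raise InputError(f"{name} channel outside 16-bit range")

    @property
    def width_px(self) -> int:
        return self.red.shape[1]

    @property
    def height_px(self) -> int:
        return self.red.shape[0]

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise InputError(f"unknown channel {name!r}")
        return getattr(self, name)

    def channels(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in CHANNELS:
            yield name, getattr(self, name)

    def with_channels(self, channels: dict[str, np.ndarray], **meta) -> "FilmScan":
        """Copy of this scan with replaced channel planes (metadata preserved)."""
        return replace(self, red=channels["red"], green=channels["green"],
                       blue=channels["blue"], **meta)


@dataclass
class ROIStats:
    mean: float
    sd: float
    n: int


def roi_stats(scan: FilmScan, roi: ROI, channel: str) -> ROIStats:
    """Mean and population SD of the PVs inside a half-open ROI."""
    roi.check_inside(scan.width_px, scan.height_px)
    values = scan.channel(channel)[roi.slices].astype(np.float64)
    return ROIStats(float(values.mean()), float(values.std(ddof=0)), values.size)


# ---------------------------------------------------------------------------
# TIFF + JSON-sidecar I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _metadata_dict(scan: FilmScan) -> dict:
    return {
        "film_id": scan.film_id,
        "lot_id": scan.lot_id,
        "orientation_tag": scan.orientation_tag,
        "scan_time": scan.scan_time.strftime(_TIME_FMT) if scan.scan_time else None,
        "exposure_time": (scan.exposure_time.strftime(_TIME_FMT)
                          if scan.exposure_time else None),
        "scan_index": scan.scan_index,
        "dpi": scan.dpi,
    }


def write_film_tiff(scan: FilmScan, path: str | Path) -> Path:
    """Write a scan as a lossless 48-bit RGB TIFF plus a JSON metadata sidecar.

    The read-back equals the input bit-exactly. Float channel data (e.g.
    from trend averaging) is rounded to the nearest integer PV on write.
    """
    path = Path(path)
    stack = np.stack([np.asarray(ch) for _, ch in scan.channels()], axis=-1)
    if not np.issubdtype(stack.dtype, np.integer):
        stack = np.rint(stack)
    if stack.min() < 0 or stack.max() > 65535:
        raise InputError("pixel values outside the 16-bit range cannot be written")
    tifffile.imwrite(path, stack.astype(np.uint16), photometric="rgb",
                     compression="zlib")
    _sidecar_path(path).write_text(json.dumps(_metadata_dict(scan), indent=1))
    return path


def read_film_tiff(path: str | Path, metadata: dict | None = None) -> FilmScan:
    """Read a 48-bit RGB TIFF film scan.

    Rejects anything that is not 16-bit-per-channel RGB — no silent
    conversion is ever applied, since PVs are the measurement itself.
    Metadata is taken from the JSON sidecar, if present, updated by the
    explicit ``metadata`` mapping.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    image = tifffile.imread(path)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise BitDepthError(
            f"{path}: expected an RGB image, got shape {image.shape} "
            "(grayscale or non-RGB input is rejected)")
    if image.dtype != np.uint16:
        raise BitDepthError(
            f"{path}: expected 16 bits per channel, got dtype {image.dtype} "
            "(8-bit scans carry too little transmission resolution)")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if metadata:
        meta.update(metadata)
    for key in ("scan_time", "exposure_time"):
        if isinstance(meta.get(key), str):
            meta[key] = datetime.strptime(meta[key], _TIME_FMT)
    dpi = meta.pop("dpi", SCAN_DPI)
    if dpi != SCAN_DPI:
        warnings.warn(f"{path}: scan dpi {dpi} differs from the standard "
                      f"{SCAN_DPI} dpi geometry; physical-unit ROIs will be off",
                      stacklevel=2)
    known = {k: v for k, v in meta.items()
             if k in {"film_id", "lot_id", "orientation_tag", "scan_time",
                      "exposure_time", "scan_index"}}
    return FilmScan(red=image[..., 0], green=image[..., 1], blue=image[..., 2],
                    dpi=dpi, **known)


# ---------------------------------------------------------------------------
# Repeated-scan averaging


def average_repeated_scans(scans: Sequence[FilmScan]) -> FilmScan:
    """Combine repeated scans of one film into a single reading.

    With five or fewer scans the pixelwise mean is used. With more, the
    exposed film's sensitivity to the scanner light (+0.03 % per successive
    scan) biases a plain mean, so a per-pixel linear trend over the scan
    index is fitted and evaluated at the first scan's index instead.
    """
    if len(scans) == 0:
        raise InsufficientDataError("need at least one scan to average")
    first = scans[0]
    for s in scans[1:]:
        if (s.width_px, s.height_px) != (first.width_px, first.height_px):
            raise InputError("repeated scans must share dimensions")
        if s.film_id != first.film_id:
            raise InputError(
                f"repeated scans must be of one film: {s.film_id!r} vs "
                f"{first.film_id!r}")
    indices = np.array([s.scan_index for s in scans], dtype=np.float64)
    if len(scans) > 1 and not np.all(np.diff(indices) > 0):
        raise InputError("scan_index must be strictly increasing")

    out: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        stack = np.stack([s.channel(name).astype(np.float64) for s in scans])
        if len(scans) <= 5:
            out[name] = stack.mean(axis=0)
        else:
            # Per-pixel least-squares line over scan_index, evaluated at the
            # first index; removes the scanner-light drift on exposed film.
            x = indices - indices[0]
            xm = x.mean()
            denom = float(((x - xm) ** 2).sum())
            slope = np.tensordot(x - xm, stack, axes=(0, 0)) / denom
            intercept = stack.mean(axis=0) - slope * xm
            out[name] = intercept
    return first.with_channels(out, scan_index=int(indices[0]))
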
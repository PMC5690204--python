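"""2D absorbed-dose-to-water maps with masks and provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError
from .film_image_io import PIXEL_PITCH_MM


@dataclass
class DoseMap:
    """Absorbed dose to water per pixel (Gy).

    ``valid`` marks pixels where a dose could be determined (film present,
    PVs in range); ``provenance`` records how the map was produced
    (corrections applied, calibration identity, iteration count...).
    """

    dose: np.ndarray                      # (H, W) float64, Gy
    pixel_spacing_mm: float = PIXEL_PITCH_MM
    valid: np.ndarray | None = None       # (H, W) bool
    orientation_tag: str = "normal"
    film_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.dose.ndim != 2:
            raise InputError("dose map must be 2D")
        if self.valid is None:
            self.valid = np.ones(self.dose.shape, dtype=bool)
        elif self.valid.shape != self.dose.shape:
            raise InputError("valid mask shape must match the dose array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dose.shape

    def with_dose(self, dose: np.ndarray, **meta) -> "DoseMap":
        return replace(self, dose=np.asarray(dose, dtype=np.float64), **meta)


def save_dose_map(dmap: DoseMap, path: str | Path) -> Path:
    """Write a dose map as 32-bit float TIFF + JSON header (+ mask TIFF)."""
    path = Path(path)
    tifffile.imwrite(path, dmap.dose.astype(np.float32))
    tifffile.imwrite(path.with_suffix(".mask.tif"),
                     dmap.valid.astype(np.uint8) * 255)
    header = {
        "units": "Gy",
        "pixel_spacing_mm": dmap.pixel_spacing_mm,
        "orientation_tag": dmap.orientation_tag,
        "film_id": dmap.film_id,
        "provenance": dmap.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header, indent=1))
    return path


def load_dose_map(path: str | Path) -> DoseMap:
    path = Path(path)
    dose = tifffile.imread(path).astype(np.float64)
    header_path = path.with_suffix(path.suffix + ".json")
    header = json.loads(header_path.read_text()) if header_path.exists() else {}
    mask_path = path.with_suffix(".mask.tif")
    valid = tifffile.imread(mask_path) > 0 if mask_path.exists() else None
    return DoseMap(dose,
                   pixel_spacing_mm=header.get("pixel_spacing_mm", PIXEL_PITCH_MM),
                   valid=valid,
                   orientation_tag=header.get("orientation_tag", "normal"),
                   film_id=header.get("film_id", ""),
                   provenance=header.get("provenance", {}))


def export_dose_csv(dmap: DoseMap, path: str | Path) -> Path:
    """Plain-text matrix export (one row per image row, Gy)."""
    path = Path(path)
    np.savetxt(path, dmap.dose, fmt="%.6g", delimiter=",")
    return path
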
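"""Four-orientation film read-out: restoration, outlier rejection, merging.

The film is symmetric and can be scanned from either side, so one film can
be read in four orientations — normal, rotated 180°, flipped (mirrored),
and flipped + rotated. Each scan sees a *different* part of the scanner
bed, so after per-scan correction and dose conversion the four dose maps
are geometrically restored to the film frame and merged by mean dose.
Residual scanner nonuniformity averages down, and dust or dirt on the
scanner glass — which follows the *scanner* frame, not the film — shows up
in exactly one orientation and is rejected against the per-pixel median.

Scratches and permanent dirt on the film itself appear in all four
orientations at film-fixed positions and are deliberately not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dosemap import DoseMap
from .errors import GeometryError, InputError
from .film_image_io import ORIENTATION_TAGS

#: Index transforms per orientation tag (all are involutions, so the same
#: transform maps film frame -> scanner frame and back).
_TRANSFORMS = {
    "normal": lambda a: a,
    "rot180": lambda a: a[::-1, ::-1],
    "flipped": lambda a: a[:, ::-1],
    "flipped_rot180": lambda a: a[::-1, :],
}


def orientation_transform(array: np.ndarray, tag: str) -> np.ndarray:
    """Apply the pixel-exact index permutation for an orientation tag."""
    try:
        return np.ascontiguousarray(_TRANSFORMS[tag](array))
    except KeyError:
        raise InputError(
            f"unknown orientation tag {tag!r}; expected one of "
            f"{ORIENTATION_TAGS}") from None


def restore_orientation(dmap: DoseMap, tag: str | None = None) -> DoseMap:
    """Restore a dose map to the film frame (pixel-exact, no interpolation)."""
    tag = dmap.orientation_tag if tag is None else tag
    restored = dmap.with_dose(orientation_transform(dmap.dose, tag),
                              orientation_tag="normal")
    restored.valid = orientation_transform(dmap.valid, tag)
    restored.provenance = dict(dmap.provenance, restored_from=tag)
    return restored


@dataclass
class MergedDose:
    """Mean-dose merge of restored orientation maps."""

    dose: np.ndarray                 # (H, W) Gy
    excluded: np.ndarray             # (n, H, W) bool; True = orientation masked
    spread: np.ndarray               # (H, W) max - min of contributing maps
    unreliable: np.ndarray           # (H, W) bool; >2 orientations deviated
    tags: tuple[str, ...]

    @property
    def n_excluded_per_orientation(self) -> np.ndarray:
        return self.excluded.sum(axis=(1, 2))

    def as_dose_map(self, template: DoseMap | None = None) -> DoseMap:
        valid = None if template is None else template.valid
        return DoseMap(self.dose, valid=valid,
                       film_id=template.film_id if template else "",
                       provenance={"merged_orientations": list(self.tags)})


def merge_orientations(maps: Sequence[DoseMap], *,
                       rel_threshold: float = 0.02,
                       abs_threshold_gy: float = 0.04,
                       tags: Sequence[str] | None = None) -> MergedDose:
    """Merge restored orientation dose maps by outlier-masked mean.

    Per pixel, the median of the contributing maps is the robust reference;
    any map deviating from it by more than
    ``max(rel_threshold * |median|, abs_threshold_gy)`` is excluded and the
    mean is taken over the survivors. If fewer than two maps survive the
    pixel is flagged unreliable and all maps are kept (a single scan
    cannot adjudicate its own outliers).
    """
    if len(maps) < 2:
        raise InputError("merging needs at least two restored dose maps")
    if tags is None:
        tags = tuple(m.provenance.get("restored_from", m.orientation_tag)
                     for m in maps)
    tags = tuple(tags)
    if len(tags) != len(maps):
        raise InputError("one tag per map is required")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise GeometryError(f"restored maps must share dimensions, got {shapes}")
    stack = np.stack([m.dose for m in maps])       # (n, H, W)
    median = np.median(stack, axis=0)
    threshold = np.maximum(rel_threshold * np.abs(median), abs_threshold_gy)
    excluded = np.abs(stack - median) > threshold[None]

    n_keep = (~excluded).sum(axis=0)
    unreliable = n_keep < 2
    if unreliable.any():
        excluded[:, unreliable] = False            # keep everything there
    keep = ~excluded
    dose = (stack * keep).sum(axis=0) / keep.sum(axis=0)
    kept_vals = np.where(keep, stack, np.nan)
    spread = np.nanmax(kept_vals, axis=0) - np.nanmin(kept_vals, axis=0)
    return MergedDose(dose=dose, excluded=excluded, spread=spread,
                      unreliable=unreliable, tags=tags)


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class Profile:
    """1D dose profile: band-averaged values along one image axis."""

    positions: np.ndarray            # pixel index along the profile axis
    values: np.ndarray
    axis: str                        # "transversal" | "longitudinal"

    def normalized(self, center: float | None = None) -> "Profile":
        """Profile divided by its (interpolated) central value."""
        if center is None:
            center = 0.5 * (self.positions[0] + self.positions[-1])
        ref = float(np.interp(center, self.positions, self.values))
        if ref == 0:
            raise InputError("cannot normalize: zero central value")
        return Profile(self.positions.copy(), self.values / ref, self.axis)


def extract_profile(dmap: DoseMap, axis: str = "transversal", *,
                    position: int | None = None, width_px: int = 20,
                    normalize: bool = False) -> Profile:
    """Band-averaged 1D profile of a dose map.

    ``axis="transversal"`` profiles along X, averaging a band of
    ``width_px`` rows centered at ``position`` (default: image middle);
    ``axis="longitudinal"`` profiles along Y over a band of columns.
    """
    h, w = dmap.shape
    if axis == "transversal":
        extent, length = h, w
        if position is None:
            position = h // 2
    elif axis == "longitudinal":
        extent, length = w, h
        if position is None:
            position = w // 2
    else:
        raise InputError(f"unknown profile axis {axis!r}")
    lo = position - width_px // 2
    hi = lo + width_px
    if lo < 0 or hi > extent or width_px <= 0:
        raise GeometryError(
            f"profile band [{lo}, {hi}) outside map extent {extent}")
    if axis == "transversal":
        values = dmap.dose[lo:hi, :].mean(axis=0)
    else:
        values = dmap.dose[:, lo:hi].mean(axis=1)
    prof = Profile(np.arange(length, dtype=float), values, axis)
    return prof.normalized() if normalize else prof


@dataclass
class ProfileComparison:
    max_rel_diff: float
    mean_rel_diff: float
    region: tuple[float, float]


def compare_profiles(test: Profile, reference: Profile,
                     central_fraction: float = 0.8) -> ProfileComparison:
    """Maximum and mean |relative difference| over the central region.

    Both profiles are normalized at the center of the overlap (so a global
    scale factor cancels); the reference is resampled linearly onto the
    test grid.
    """
    lo = max(test.positions[0], reference.positions[0])
    hi = min(test.positions[-1], reference.positions[-1])
    if hi <= lo:
        raise InputError("profiles do not overlap")
    center = 0.5 * (lo + hi)
    half = 0.5 * central_fraction * (hi - lo)
    region = (center - half, center + half)
    t = test.normalized(center)
    r = reference.normalized(center)
    sel = (t.positions >= region[0]) & (t.positions <= region[1])
    ref_resampled = np.interp(t.positions[sel], r.positions, r.values)
    if np.any(ref_resampled == 0):
        raise InputError("reference profile crosses zero in the region")
    rel = np.abs(t.values[sel] / ref_resampled - 1.0)
    return ProfileComparison(float(rel.max()), float(rel.mean()), region)


def flatness(profile: Profile, central_fraction: float = 0.8) -> float:
    """Max |relative deviation from 1| of a center-normalized profile
    over the central fraction of its extent."""
    n = profile.positions.size
    margin = int(round(0.5 * (1.0 - central_fraction) * n))
    sel = slice(margin, n - margin)
    norm = profile.normalized()
    return float(np.abs(norm.values[sel] - 1.0).max())
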
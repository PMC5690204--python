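"""Net optical density, dose-response calibration and film QC rules.

The dose-carrying signal of radiochromic film is the net optical density

    OD_net = log10(PV_un / PV_ex)

of a film piece against its own pre-irradiation background. Dose is
recovered through a rational response function

    D(x) = (a + c*x) / (1 + b*x),        x = OD_net

fitted per colour channel and per film lot. Because the typeset source of
this form is ambiguous, an additive variant D(x) = a + c*x/(1 + b*x) is
also available (``form="additive"``); the rational fraction is the default.

Dose determination uses the red and green channels (averaged in *dose*
space, never in PV or OD, because the channels have different response
curves). The blue channel carries too little signal for dosimetry but is
the most sensitive to emulsion-thickness variation, so it drives the film
homogeneity QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
import json

import numpy as np
from scipy.optimize import least_squares

from .errors import (ConfigError, DomainError, ExtrapolationError,
                     FitQualityError, InputError, InsufficientDataError)
from .film_image_io import CHANNELS, FilmScan

DOSE_CHANNELS = ("red", "green")

#: Background-acceptance thresholds: relative deviation from the lot mean
#: above which a film piece is rejected from calibration.
QC_THRESHOLDS_PCT = {"red": 0.5, "green": 0.5, "blue": 1.0}

#: A lot calibration is considered stale this long after the fit.
CALIBRATION_VALIDITY = timedelta(days=91)


def net_od(pv_un, pv_ex):
    """Net optical density log10(PV_un / PV_ex).

    Accepts scalars or arrays. Negative values (exposed reading brighter
    than background) are returned as-is; the zero-dose clamp is applied
    downstream in :func:`od_to_dose`.
    """
    pv_un = np.asarray(pv_un, dtype=np.float64)
    pv_ex = np.asarray(pv_ex, dtype=np.float64)
    if np.any(pv_un <= 0) or np.any(pv_ex <= 0):
        raise DomainError("net OD requires strictly positive pixel values")
    result = np.log10(pv_un / pv_ex)
    return float(result) if result.ndim == 0 else result


def _rational(x, a, b, c):
    return (a + c * x) / (1.0 + b * x)


def _additive(x, a, b, c):
    return a + c * x / (1.0 + b * x)


_FORMS = {"rational": _rational, "additive": _additive}


@dataclass
class ChannelFit:
    a: float
    b: float
    c: float
    rms_residual_gy: float = 0.0
    max_residual_gy: float = 0.0


@dataclass
class CalibrationCurve:
    """Per-channel dose-response parameters for one film lot.

    ``dose_range`` is [Dmin, Dmax] in Gy; conversion beyond Dmax is refused
    by default because the rational form extrapolates wildly past the
    calibrated range.
    """

    channels: dict[str, ChannelFit]
    lot_id: str = ""
    quality: str = ""                 # beam quality Q label, e.g. "Co-60", "6MV"
    dose_range: tuple[float, float] = (0.0, 8.0)
    od_range: dict[str, tuple[float, float]] = field(default_factory=dict)
    calibration_date: datetime | None = None
    form: str = "rational"

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise InputError(f"unknown calibration form {self.form!r}")

    def channel_params(self, channel: str) -> ChannelFit:
        try:
            return self.channels[channel]
        except KeyError:
            raise InputError(f"no calibration for channel {channel!r}") from None

    def is_expired(self, at: datetime | None = None) -> bool:
        if self.calibration_date is None:
            return False
        at = at or datetime.now()
        return at - self.calibration_date > CALIBRATION_VALIDITY


def od_to_dose(x, curve: CalibrationCurve, channel: str, *,
               on_out_of_range: str = "raise"):
    """Convert net OD to absorbed dose to water (Gy) for one channel.

    Negative OD is clamped to 0 Gy (the zero-dose level of the film).
    Doses above the calibrated maximum are an extrapolation of the rational
    fit: ``on_out_of_range`` is ``"raise"`` (default), ``"clamp"`` to the
    range maximum, or ``"allow"``.

    Scalars in, scalar out; arrays in, array out.
    """
    if on_out_of_range not in ("raise", "clamp", "allow"):
        raise InputError(f"bad on_out_of_range {on_out_of_range!r}")
    p = curve.channel_params(channel)
    x = np.asarray(x, dtype=np.float64)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    denom = 1.0 + p.b * x
    if np.any(denom <= 0):
        raise DomainError(
            f"1 + b*x <= 0 at some OD values (b={p.b}); outside the fit domain")
    dose = _FORMS[curve.form](x, p.a, p.b, p.c)
    dose = np.where(x < 0, 0.0, dose)          # zero-level rule
    dose = np.maximum(dose, 0.0)
    dmax = curve.dose_range[1]
    over = dose > dmax
    if np.any(over):
        if on_out_of_range == "raise":
            raise ExtrapolationError(
                f"dose {float(dose.max()):.3f} Gy above calibrated maximum "
                f"{dmax} Gy; extrapolation is refused")
        if on_out_of_range == "clamp":
            dose = np.minimum(dose, dmax)
    return float(dose[0]) if scalar else dose


def dose_to_od(dose, curve: CalibrationCurve, channel: str):
    """Exact inverse of the fitted response (rational form): x = (D-a)/(c-b*D)."""
    if curve.form != "rational":
        raise InputError("closed-form inverse is only defined for the rational form")
    p = curve.channel_params(channel)
    dose = np.asarray(dose, dtype=np.float64)
    denom = p.c - p.b * dose
    if np.any(denom <= 0):
        raise DomainError("dose outside the invertible branch of the curve")
    result = (dose - p.a) / denom
    return float(result) if result.ndim == 0 else result


def fit_calibration(od, dose, channel: str = "red", *,
                    form: str = "rational", constrain_zero: bool = False,
                    weights=None, lot_id: str = "", quality: str = "",
                    calibration_date: datetime | None = None) -> CalibrationCurve:
    """Least-squares fit of the dose-response function for one channel.

    Parameters
    ----------
    od, dose
        Net OD values and their reference doses (Gy), >= 4 points.
    constrain_zero
        Force a = 0 so that OD 0 maps exactly to 0 Gy.
    weights
        Optional per-point weights (1/sigma); unweighted by default.

    The fitted curve must be monotone increasing over the data's OD range,
    otherwise a :class:`FitQualityError` is raised. Dmax is set to the
    largest calibration dose — extrapolation beyond it is not certified.
    """
    od = np.asarray(od, dtype=np.float64)
    dose = np.asarray(dose, dtype=np.float64)
    if od.shape != dose.shape or od.ndim != 1:
        raise InputError("od and dose must be 1D arrays of equal length")
    if od.size < 4:
        raise InsufficientDataError(
            f"need >= 4 calibration points, got {od.size}")
    if form not in _FORMS:
        raise InputError(f"unknown calibration form {form!r}")
    w = np.ones_like(od) if weights is None else np.asarray(weights, float)

    model = _FORMS[form]
    # Linear initialisation: D ~ a + c x, b = 0 (the nested linear model).
    A = np.vstack([np.ones_like(od), od]).T
    (a0, c0), *_ = np.linalg.lstsq(A, dose, rcond=None)

    if constrain_zero:
        def resid(p):
            return w * (model(od, 0.0, p[0], p[1]) - dose)
        sol = least_squares(resid, x0=[0.0, c0], xtol=1e-15, ftol=1e-15,
                            gtol=1e-15)
        a, (b, c) = 0.0, sol.x
    else:
        def resid(p):
            return w * (model(od, p[0], p[1], p[2]) - dose)
        sol = least_squares(resid, x0=[a0, 0.0, c0], xtol=1e-15, ftol=1e-15,
                            gtol=1e-15)
        a, b, c = sol.x

    residuals = model(od, a, b, c) - dose
    fitp = ChannelFit(float(a), float(b), float(c),
                      rms_residual_gy=float(np.sqrt(np.mean(residuals ** 2))),
                      max_residual_gy=float(np.abs(residuals).max()))

    od_lo, od_hi = float(od.min()), float(od.max())
    grid = np.linspace(max(od_lo, 0.0), od_hi, 256)
    curve_vals = model(grid, a, b, c)
    if np.any(np.diff(curve_vals) <= 0):
        raise FitQualityError(
            f"fitted {channel} curve is not monotone increasing over the "
            f"calibration OD range [{od_lo:.4f}, {od_hi:.4f}]")

    return CalibrationCurve(
        channels={channel: fitp}, lot_id=lot_id, quality=quality,
        dose_range=(float(dose.min()), float(dose.max())),
        od_range={channel: (od_lo, od_hi)},
        calibration_date=calibration_date, form=form)


def fit_calibration_multichannel(points: dict[str, np.ndarray], dose, **kwargs
                                 ) -> CalibrationCurve:
    """Fit all channels at once; ``points`` maps channel -> OD array."""
    merged: CalibrationCurve | None = None
    for channel, od in points.items():
        cur = fit_calibration(od, dose, channel, **kwargs)
        if merged is None:
            merged = cur
        else:
            merged.channels.update(cur.channels)
            merged.od_range.update(cur.od_range)
    if merged is None:
        raise InsufficientDataError("no channels to fit")
    return merged


def calibration_factor(d_w_q: float, od_m_q: float) -> float:
    """OD-dependent calibration factor N = D_w,Q / OD_m,Q (Gy per unit OD)."""
    if od_m_q == 0:
        raise DomainError("calibration factor undefined at zero OD")
    return d_w_q / od_m_q


# ---------------------------------------------------------------------------
# QC rules


@dataclass
class QCRuleResult:
    piece_id: str
    deviations_pct: dict[str, float]
    verdict: str                      # "accept" | "reject"
    rule: str = ""


def background_qc(piece_means: dict[str, dict[str, float]],
                  thresholds_pct: dict[str, float] | None = None
                  ) -> list[QCRuleResult]:
    """Accept/reject film pieces by background deviation from the lot mean.

    ``piece_means`` maps piece id -> {channel: mean background PV}. A piece
    is rejected when its relative deviation from the lot mean exceeds 0.5 %
    in red or green, or 1 % in blue (strictly greater than the threshold).
    """
    thresholds = dict(QC_THRESHOLDS_PCT)
    if thresholds_pct:
        thresholds.update(thresholds_pct)
    if len(piece_means) < 2:
        raise InsufficientDataError(
            "background QC needs >= 2 pieces to define a lot mean")
    lot_mean = {ch: float(np.mean([m[ch] for m in piece_means.values()]))
                for ch in CHANNELS}
    results = []
    for piece_id, means in piece_means.items():
        dev = {ch: (means[ch] - lot_mean[ch]) / lot_mean[ch] * 100.0
               for ch in CHANNELS}
        triggered = [ch for ch in CHANNELS if abs(dev[ch]) > thresholds[ch]]
        results.append(QCRuleResult(
            piece_id=piece_id, deviations_pct=dev,
            verdict="reject" if triggered else "accept",
            rule=("background deviation > "
                  + ", ".join(f"{thresholds[ch]}% ({ch})" for ch in triggered)
                  if triggered else "")))
    return results


@dataclass
class BlueBandReport:
    verdict: str                      # "accept" | "reject"
    max_deviation_pct: float
    profile: np.ndarray               # per-column blue mean PV
    relative_profile_pct: np.ndarray  # per-column deviation from mean, %
    band_columns: np.ndarray          # columns exceeding tolerance
    tolerance_pct: float
    warning: str = ""


def homogeneity_qc_blue(sheet_scan: FilmScan, tolerance_pct: float = 1.0,
                        rows: slice | None = None) -> BlueBandReport:
    """Blue-channel homogeneity control of an unexposed film sheet.

    Emulsion-thickness variation appears as longitudinal bands and is
    strongest in the blue channel, so the per-column blue mean profile is
    screened: if any column deviates more than ``tolerance_pct`` (strictly)
    from the sheet mean the piece is rejected and the band localized.
    """
    blue = sheet_scan.blue.astype(np.float64)
    if rows is not None:
        blue = blue[rows]
    warning = ""
    if sheet_scan.exposure_time is not None:
        warning = ("scan carries an exposure timestamp; homogeneity QC is "
                   "intended for unexposed film")
    profile = blue.mean(axis=0)
    sheet_mean = profile.mean()
    rel = (profile - sheet_mean) / sheet_mean * 100.0
    band_columns = np.flatnonzero(np.abs(rel) > tolerance_pct)
    max_dev = float(np.abs(rel).max())
    return BlueBandReport(
        verdict="reject" if band_columns.size else "accept",
        max_deviation_pct=max_dev, profile=profile,
        relative_profile_pct=rel, band_columns=band_columns,
        tolerance_pct=tolerance_pct, warning=warning)


#: Read-out timing profiles: (pre-read window, tolerance) in hours.
TIMING_PROFILES = {"4d": (96.0, 12.0), "48h": (48.0, 1.0)}


@dataclass
class TimingResult:
    verdict: str                      # "pass" | "warn"
    delta_hours: float | None
    window_hours: float
    tolerance_hours: float
    message: str = ""


def timing_check(exposure_time: datetime | None, scan_time: datetime | None,
                 profile: str = "4d", *, window_hours: float | None = None,
                 tolerance_hours: float | None = None) -> TimingResult:
    """Check the irradiation-to-read-out delay against the timing window.

    The standard protocol reads films 4 days (96 h) after exposure with a
    ±12 h tolerance; a faster 48 h profile with ±1 h tolerance is available
    for same-week read-outs. Missing timestamps produce a warning verdict,
    never an error.
    """
    if window_hours is None or tolerance_hours is None:
        try:
            w, t = TIMING_PROFILES[profile]
        except KeyError:
            raise InputError(f"unknown timing profile {profile!r}") from None
        window_hours = w if window_hours is None else window_hours
        tolerance_hours = t if tolerance_hours is None else tolerance_hours
    if exposure_time is None or scan_time is None:
        return TimingResult("warn", None, window_hours, tolerance_hours,
                            "missing timestamp(s); timing window not verified")
    delta_h = (scan_time - exposure_time).total_seconds() / 3600.0
    ok = abs(delta_h - window_hours) <= tolerance_hours
    return TimingResult(
        "pass" if ok else "warn", delta_h, window_hours, tolerance_hours,
        "" if ok else f"read-out at {delta_h:.1f} h is outside "
                      f"{window_hours:.0f} h ± {tolerance_hours:.0f} h")


# ---------------------------------------------------------------------------
# Calibration archive (JSON)


def save_calibration(curve: CalibrationCurve, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "lot_id": curve.lot_id,
        "quality": curve.quality,
        "form": curve.form,
        "dose_range_gy": list(curve.dose_range),
        "od_range": {ch: list(r) for ch, r in curve.od_range.items()},
        "calibration_date": (curve.calibration_date.isoformat()
                             if curve.calibration_date else None),
        "channels": {ch: vars(p) for ch, p in curve.channels.items()},
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_calibration(path: str | Path) -> CalibrationCurve:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"calibration file not found: {path}")
    payload = json.loads(path.read_text())
    date = payload.get("calibration_date")
    return CalibrationCurve(
        channels={ch: ChannelFit(**p) for ch, p in payload["channels"].items()},
        lot_id=payload.get("lot_id", ""), quality=payload.get("quality", ""),
        dose_range=tuple(payload.get("dose_range_gy", (0.0, 8.0))),
        od_range={ch: tuple(r) for ch, r in payload.get("od_range", {}).items()},
        calibration_date=datetime.fromisoformat(date) if date else None,
        form=payload.get("form", "rational"))
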
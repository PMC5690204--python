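"""Net OD, rational dose-response fitting, calibration factor and QC rules."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebt3dose import (CalibrationCurve, DomainError, FilmModel,
                      background_qc, calibration_factor, dose_to_od,
                      fit_calibration, homogeneity_qc_blue, load_calibration,
                      net_od, od_to_dose, save_calibration, timing_check)
from ebt3dose.calibration import ChannelFit
from ebt3dose.errors import (ExtrapolationError, FitQualityError,
                             InsufficientDataError)


def toy_curve(a=0.0, b=1.5, c=10.0, form="rational", dmax=8.0):
    return CalibrationCurve(channels={"red": ChannelFit(a, b, c)},
                            dose_range=(0.0, dmax), form=form)


class TestNetOd:
    def test_equal_pvs_give_zero(self):
        assert net_od(26000, 26000) == 0.0

    def test_decade_ratio_gives_unity(self):
        # 26000 PV is the ~2 Gy working point of the read-out chain
        assert net_od(26000, 2600) == pytest.approx(1.0, abs=1e-12)

    def test_brighter_exposed_reading_gives_negative_od(self):
        assert net_od(26000, 26500) == pytest.approx(-0.00827, abs=5e-6)

    def test_non_positive_pv_rejected(self):
        with pytest.raises(DomainError):
            net_od(0, 100)
        with pytest.raises(DomainError):
            net_od(100, -3)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1.0, 6e4), st.floats(1.0, 6e4), st.floats(1.001, 1.5))
    def test_strictly_monotone_in_both_arguments(self, un, ex, factor):
        assert net_od(un * factor, ex) > net_od(un, ex)
        assert net_od(un, ex * factor) < net_od(un, ex)


class TestOdToDose:
    def test_zero_od_with_zero_intercept(self):
        assert od_to_dose(0.0, toy_curve(), "red") == 0.0

    def test_rational_closed_form(self):
        # (0 + 10*0.26) / (1 + 1.5*0.26)
        assert od_to_dose(0.26, toy_curve(), "red") == pytest.approx(
            2.6 / 1.39, rel=1e-12)

    def test_additive_variant(self):
        curve = toy_curve(a=0.1, form="additive")
        assert od_to_dose(0.26, curve, "red") == pytest.approx(
            0.1 + 2.6 / 1.39, rel=1e-12)

    def test_negative_od_clamps_to_zero_dose(self):
        assert od_to_dose(-0.005, toy_curve(), "red") == 0.0

    def test_extrapolation_refused_then_clamped(self):
        curve = toy_curve(dmax=2.0)
        with pytest.raises(ExtrapolationError):
            od_to_dose(0.5, curve, "red")
        assert od_to_dose(0.5, curve, "red", on_out_of_range="clamp") == 2.0

    def test_pole_rejected(self):
        curve = toy_curve(b=-2.0)
        with pytest.raises(DomainError):
            od_to_dose(0.6, curve, "red")

    def test_round_trip_identity_on_dose_range(self):
        curve = FilmModel().curve
        dose = np.linspace(0.0, 8.0, 101)
        for ch in ("red", "green", "blue"):
            od = dose_to_od(dose, curve, ch)
            back = od_to_dose(od, curve, ch)
            np.testing.assert_allclose(back, dose, rtol=1e-9, atol=1e-12)


class TestFitCalibration:
    @pytest.mark.parametrize("params", [(0.0, 1.5, 10.0), (0.0, -0.6027, 9.723),
                                        (0.05, -0.7937, 12.70)])
    def test_exact_recovery_on_noise_free_data(self, params):
        a, b, c = params
        od = np.linspace(0.02, 0.6, 9)
        dose = (a + c * od) / (1 + b * od)
        curve = fit_calibration(od, dose, "red")
        p = curve.channels["red"]
        assert p.a == pytest.approx(a, abs=1e-6 * max(1, abs(a)))
        assert p.b == pytest.approx(b, rel=1e-6, abs=1e-6)
        assert p.c == pytest.approx(c, rel=1e-6)
        assert p.rms_residual_gy < 1e-9

    def test_linear_data_recovers_b_zero(self):
        od = np.linspace(0.05, 0.5, 8)
        dose = 0.2 + 11.0 * od
        p = fit_calibration(od, dose, "green").channels["green"]
        assert p.b == pytest.approx(0.0, abs=1e-7)
        assert p.c == pytest.approx(11.0, rel=1e-6)

    def test_constrained_zero_intercept(self):
        od = np.linspace(0.02, 0.6, 9)
        dose = 10.0 * od / (1 + 1.5 * od)
        p = fit_calibration(od, dose, "red",
                            constrain_zero=True).channels["red"]
        assert p.a == 0.0
        assert p.c == pytest.approx(10.0, rel=1e-6)

    def test_single_point_perturbation_bounded_by_local_slope(self):
        """A +1 % OD error at the 2 Gy point moves the refit there by a
        finite amount bounded by slope*dx, and inflates the residual."""
        curve0 = FilmModel().curve
        dose = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
        od = dose_to_od(dose, curve0, "red")
        clean = fit_calibration(od, dose, "red")
        od_pert = od.copy()
        od_pert[3] *= 1.01
        pert = fit_calibration(od_pert, dose, "red")
        d_clean = od_to_dose(float(od[3]), clean, "red")
        d_pert = od_to_dose(float(od[3]), pert, "red")
        p = clean.channels["red"]
        slope = p.c * (1 + p.b * od[3]) ** -2  # dD/dx of the rational form
        bound = slope * 0.01 * od[3]
        assert 0 < abs(d_pert - d_clean) < bound
        assert (pert.channels["red"].rms_residual_gy
                > clean.channels["red"].rms_residual_gy)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration([0.1, 0.2, 0.3], [1, 2, 3], "red")

    def test_non_monotone_data_raises_fit_quality(self):
        od = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
        dose = np.array([1.0, 2.0, 3.0, 2.5, 1.5, 1.0])
        with pytest.raises(FitQualityError):
            fit_calibration(od, dose, "red")

    def test_dmax_set_to_largest_calibration_dose(self):
        od = np.linspace(0.05, 0.5, 6)
        dose = 10 * od / (1 + 1.5 * od)
        curve = fit_calibration(od, dose, "red")
        assert curve.dose_range[1] == pytest.approx(dose.max())


class TestCalibrationFactor:
    def test_division(self):
        assert calibration_factor(2.0, 0.25) == 8.0

    def test_zero_dose(self):
        assert calibration_factor(0.0, 0.2) == 0.0

    def test_zero_od_rejected(self):
        with pytest.raises(DomainError):
            calibration_factor(2.0, 0.0)

    def test_consistent_with_fitted_curve_at_calibration_points(self):
        curve = FilmModel().curve
        dose = np.array([0.25, 1.0, 2.0, 4.0, 8.0])
        od = dose_to_od(dose, curve, "red")
        for d, x in zip(dose, od):
            n = calibration_factor(d, float(x))
            assert od_to_dose(float(x), curve, "red") / x == pytest.approx(
                n, rel=1e-9)


class TestBackgroundQc:
    BASE = {"red": 40000.0, "green": 40500.0, "blue": 38000.0}

    def _pieces(self, n=4):
        return {f"p{i}": dict(self.BASE) for i in range(n)}

    def test_identical_pieces_all_accepted(self):
        results = background_qc(self._pieces())
        assert all(r.verdict == "accept" for r in results)
        assert all(abs(d) < 1e-12 for r in results
                   for d in r.deviations_pct.values())

    def test_red_excess_above_half_percent_rejected(self):
        pieces = self._pieces(5)
        pieces["p0"]["red"] *= 1.0076  # ~ +0.6 % vs the lot mean incl. itself
        results = {r.piece_id: r for r in background_qc(pieces)}
        assert results["p0"].verdict == "reject"
        assert "red" in results["p0"].rule

    def test_blue_within_one_percent_accepted(self):
        pieces = self._pieces(5)
        pieces["p0"]["blue"] *= 1.0099  # +0.8 % vs lot mean incl. itself
        results = {r.piece_id: r for r in background_qc(pieces)}
        assert results["p0"].verdict == "accept"

    def test_exact_threshold_not_rejected(self):
        """The rule is 'more than': a deviation equal to the threshold
        passes, one just above fails. Exercised with binary-exact values
        (deviation exactly 0.390625 %) so the boundary is unambiguous."""
        pieces = {"a": {"red": 128.5, "green": 100.0, "blue": 100.0},
                  "b": {"red": 127.5, "green": 100.0, "blue": 100.0}}
        at = {r.piece_id: r for r in background_qc(
            pieces, thresholds_pct={"red": 0.390625})}
        assert all(r.verdict == "accept" for r in at.values())
        below = {r.piece_id: r for r in background_qc(
            pieces, thresholds_pct={"red": 0.39})}
        assert all(r.verdict == "reject" for r in below.values())

    def test_invariant_under_global_scale(self):
        pieces = self._pieces(5)
        pieces["p1"]["green"] *= 1.008
        v1 = [r.verdict for r in background_qc(pieces)]
        scaled = {k: {ch: v * 3.7 for ch, v in m.items()}
                  for k, m in pieces.items()}
        v2 = [r.verdict for r in background_qc(scaled)]
        assert v1 == v2

    def test_single_piece_rejected(self):
        with pytest.raises(InsufficientDataError):
            background_qc({"only": self.BASE})


class TestBlueBandQc:
    def _sheet(self, film, scanner, band_blue, rng):
        from ebt3dose import simulate_scan, uniform_field
        piece = film.sample_piece(576, rng)
        piece.band["blue"] = band_blue
        scan, _ = simulate_scan(uniform_field(0.0, (720, 576)), piece,
                                scanner, rng=rng)
        return scan

    def test_flat_sheet_accepted(self, film, ideal_scanner, rng):
        band = np.zeros(576)
        report = homogeneity_qc_blue(self._sheet(film, ideal_scanner, band,
                                                 rng))
        assert report.verdict == "accept"
        assert report.max_deviation_pct < 0.05

    @pytest.mark.parametrize("amp_pct", [1.5, 2.0])
    def test_band_above_tolerance_rejected_and_localized(
            self, film, ideal_scanner, rng, amp_pct):
        cols = np.arange(576)
        band = (amp_pct / 100.0) * np.exp(-0.5 * ((cols - 300) / 25.0) ** 2)
        report = homogeneity_qc_blue(self._sheet(film, ideal_scanner, band,
                                                 rng))
        assert report.verdict == "reject"
        assert report.max_deviation_pct == pytest.approx(amp_pct, rel=0.15)
        assert 250 < np.median(report.band_columns) < 350

    def test_exposed_film_flagged(self, film, ideal_scanner, rng):
        scan = self._sheet(film, ideal_scanner, np.zeros(576), rng)
        scan.exposure_time = datetime(2026, 1, 1)
        report = homogeneity_qc_blue(scan)
        assert "unexposed" in report.warning


class TestTimingWindow:
    T0 = datetime(2026, 3, 1, 12, 0)

    def _check(self, hours, **kw):
        return timing_check(self.T0, self.T0 + timedelta(hours=hours), **kw)

    def test_exact_four_days_passes(self):
        assert self._check(96).verdict == "pass"

    def test_tolerance_boundary(self):
        assert self._check(96 + 12).verdict == "pass"
        assert self._check(96 + 13).verdict == "warn"
        assert self._check(96 - 13).verdict == "warn"

    def test_fast_48h_profile(self):
        assert self._check(48.5, profile="48h").verdict == "pass"
        assert self._check(47.5, profile="48h").verdict == "pass"
        assert self._check(50.0, profile="48h").verdict == "warn"

    def test_missing_timestamps_warn_only(self):
        res = timing_check(None, self.T0)
        assert res.verdict == "warn" and "missing" in res.message


class TestArchive:
    def test_json_round_trip(self, tmp_path):
        curve = FilmModel().curve
        curve.calibration_date = datetime(2026, 6, 1)
        path = save_calibration(curve, tmp_path / "cal.json")
        back = load_calibration(path)
        assert back.form == curve.form
        assert back.dose_range == curve.dose_range
        for ch, p in curve.channels.items():
            q = back.channels[ch]
            assert (q.a, q.b, q.c) == (p.a, p.b, p.c)

    def test_expiry_after_three_months(self):
        curve = FilmModel().curve
        curve.calibration_date = datetime(2026, 1, 1)
        assert curve.is_expired(datetime(2026, 5, 1))
        assert not curve.is_expired(datetime(2026, 2, 1))
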
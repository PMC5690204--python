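"""The scanner/film simulator: determinism, ground truth, round trips."""

import numpy as np
import pytest

from ebt3dose import (FilmModel, GeometryError, InputError,
                      default_stripe_positions, dose_to_od, fit_calibration,
                      generate_calibration_set, generate_stripe_series,
                      generate_unexposed_stack, net_od, od_to_dose, roi_stats,
                      scoring_roi, simulate_scan, uniform_field)
from ebt3dose.errors import InsufficientDataError
from ebt3dose.synthetic import post_exposure_od_factor


def clean_film():
    """Film with no inhomogeneity at all (for exact-value checks)."""
    zeros = {ch: 0.0 for ch in ("red", "green", "blue")}
    return FilmModel(piece_offset_sd=dict(zeros), band_max_dev=dict(zeros))


class TestSimulateScan:
    def test_zero_dose_noise_free_center_equals_background(self, ideal_scanner):
        film = clean_film()
        piece = film.sample_piece(200, np.random.default_rng(1))
        scan, truth = simulate_scan(uniform_field(0.0, (100, 200)), piece,
                                    ideal_scanner)
        region = truth.film_region
        assert np.all(scan.red[region] == round(piece.background["red"]))
        # outside the film the holder blocks the light entirely
        outside = scan.red.astype(int).sum() - scan.red[region].astype(int).sum()
        assert outside == 0

    def test_deterministic_given_seed(self, film, scanner):
        a, _ = simulate_scan(uniform_field(2.0, (50, 60)),
                             film.sample_piece(60, np.random.default_rng(9)),
                             scanner, seed=77)
        b, _ = simulate_scan(uniform_field(2.0, (50, 60)),
                             film.sample_piece(60, np.random.default_rng(9)),
                             scanner, seed=77)
        for ch in ("red", "green", "blue"):
            np.testing.assert_array_equal(a.channel(ch), b.channel(ch))

    def test_dose_outside_film_range_rejected(self, film, scanner):
        piece = film.sample_piece(40, np.random.default_rng(2))
        with pytest.raises(InputError, match="range"):
            simulate_scan(uniform_field(9.5, (40, 40)), piece, scanner)

    def test_film_larger_than_bed_rejected(self, film, scanner):
        piece = film.sample_piece(600, np.random.default_rng(3))
        with pytest.raises(GeometryError):
            simulate_scan(uniform_field(1.0, (100, 600)), piece, scanner)

    def test_round_trip_identity_without_artifacts(self, ideal_scanner):
        """With all artifact amplitudes zero, pipeline-recovered dose equals
        the generated dose to quantization precision."""
        film = clean_film()
        piece = film.sample_piece(576, np.random.default_rng(4))
        dose_truth = 2.0
        bg, _ = simulate_scan(uniform_field(0.0, (720, 576)), piece,
                              ideal_scanner)
        ex, _ = simulate_scan(uniform_field(dose_truth, (720, 576)), piece,
                              ideal_scanner)
        roi = scoring_roi()
        for ch in ("red", "green"):
            od = net_od(roi_stats(bg, roi, ch).mean,
                        roi_stats(ex, roi, ch).mean)
            dose = od_to_dose(od, film.curve, ch)
            # half a PV step through the local calibration slope
            assert dose == pytest.approx(dose_truth, abs=2e-4)

    def test_dust_specks_darken_and_are_recorded(self, film, quiet_scanner):
        piece = film.sample_piece(300, np.random.default_rng(5))
        scan, truth = simulate_scan(uniform_field(2.0, (300, 300)), piece,
                                    quiet_scanner, n_dust_specks=4, seed=8)
        clean, _ = simulate_scan(uniform_field(2.0, (300, 300)), piece,
                                 quiet_scanner, seed=8)
        assert truth.speck_mask is not None and truth.speck_mask.any()
        dusty = truth.speck_mask
        assert (scan.red[dusty].astype(int)
                < clean.red[dusty].astype(int)).all()

    def test_drift_applies_to_exposed_film_only(self, quiet_scanner):
        film = clean_film()
        piece = film.sample_piece(100, np.random.default_rng(6))
        ex0, t = simulate_scan(uniform_field(2.0, (100, 100)), piece,
                               quiet_scanner, scan_index=0)
        ex3, _ = simulate_scan(uniform_field(2.0, (100, 100)), piece,
                               quiet_scanner, scan_index=3)
        r = t.film_region
        ratio = ex3.red[r].astype(float).mean() / ex0.red[r].astype(float).mean()
        assert ratio == pytest.approx(1.0 + 3 * 3e-4, abs=2e-5)
        un0, _ = simulate_scan(uniform_field(0.0, (100, 100)), piece,
                               quiet_scanner, scan_index=0)
        un3, _ = simulate_scan(uniform_field(0.0, (100, 100)), piece,
                               quiet_scanner, scan_index=3)
        np.testing.assert_array_equal(un0.red, un3.red)

    def test_post_exposure_darkening_curve(self):
        assert post_exposure_od_factor(96.0) == 1.0
        assert post_exposure_od_factor(48.0) == pytest.approx(0.998)
        # day 4 -> 16: about +1 %
        assert post_exposure_od_factor(16 * 24.0) == pytest.approx(1.010)
        assert post_exposure_od_factor(30 * 24.0) == pytest.approx(1.010)


class TestUnexposedStack:
    def test_minimum_size_enforced(self, film, scanner):
        with pytest.raises(InputError):
            generate_unexposed_stack(1, film, scanner, seed=0)

    def test_noise_free_scanner_corrects_to_zero_residual(self, quiet_scanner):
        """Matrix from a noise-free stack of band-free films leaves an
        independent band-free film perfectly flat (quantization only)."""
        from ebt3dose import build_matrix_correction
        film = clean_film()
        stack = generate_unexposed_stack(2, film, quiet_scanner, seed=30)
        matrix = build_matrix_correction(stack)
        extra = generate_unexposed_stack(2, film, quiet_scanner, seed=31)[0]
        corrected = matrix.apply(extra)["red"]
        target = corrected[matrix.norm_roi.slices].mean()
        assert np.abs(corrected - target).max() < 1.5

    def test_stack_size_reduces_matrix_noise_by_averaging_law(self, scanner):
        """Residual matrix noise scales ~ 1/sqrt(n): a 2-film matrix is
        ~ sqrt(5) noisier than a 10-film one, measured against the known
        deterministic deficit field of band-free films."""
        from ebt3dose import build_matrix_correction, normalization_roi
        film = clean_film()
        det = scanner.base_deficit()
        det = det - det[normalization_roi().slices].mean()
        resid = []
        for n, seed in ((10, 40), (2, 41)):
            m = build_matrix_correction(
                generate_unexposed_stack(n, film, scanner, seed=seed))
            resid.append((m.m["red"] - det).std())
        assert resid[1] / resid[0] == pytest.approx(np.sqrt(5), rel=0.15)


class TestStripeSeries:
    def test_positions_cover_bed_and_share_one_film(self, film, scanner):
        positions = default_stripe_positions(scanner)
        scans, truth = generate_stripe_series(2.0, positions, film, scanner,
                                              seed=50)
        assert len(scans) == len(positions)
        assert len({s.film_id for s in scans}) == 1
        covered = np.zeros(scanner.width_px, dtype=bool)
        for scan in scans:
            covered |= scan.red[360] > 1000
        assert covered[2:-2].all()

    def test_duplicate_positions_rejected(self, film, scanner):
        with pytest.raises(GeometryError, match="duplicate"):
            generate_stripe_series(2.0, [288, 288], film, scanner, seed=51)

    def test_out_of_bed_position_rejected(self, film, scanner):
        with pytest.raises(GeometryError):
            generate_stripe_series(2.0, [10], film, scanner, seed=52)

    def test_reel_dose_uniformity_level(self, film, quiet_scanner):
        _, truth = generate_stripe_series(2.0, [288], film, quiet_scanner,
                                          seed=53)
        rel_sd = truth.dose_film_frame.std() / truth.dose_film_frame.mean()
        assert rel_sd == pytest.approx(0.002, rel=0.10)

    def test_seed_repeatability_of_derived_md(self, film, scanner, matrix):
        from ebt3dose import build_dose_transversal_correction
        positions = default_stripe_positions(scanner)
        mds = []
        for seed in (60, 61):
            scans, _ = generate_stripe_series(2.0, positions, film, scanner,
                                              seed=seed)
            mds.append(build_dose_transversal_correction(scans, 2.0, matrix))
        diff = mds[0].md["red"][1] - mds[1].md["red"][1]
        # column estimates average ~430 rows; two independent films differ
        # by band structure (~8 PV full scale) plus averaged noise
        assert np.abs(diff).max() < 25.0


class TestCalibrationSet:
    DOSES = [0.25, 1.0, 2.0, 4.0, 8.0]

    def test_truth_table_matches_film_model_exactly(self, film, scanner):
        _, truth = generate_calibration_set(self.DOSES, film, scanner,
                                            seed=70)
        for _, row in truth.iterrows():
            for ch in ("red", "green", "blue"):
                assert row[f"od_{ch}"] == pytest.approx(
                    dose_to_od(row["dose_gy"], film.curve, ch), rel=1e-12)

    def test_noise_free_refit_recovers_parameters_exactly(self, ideal_scanner):
        film = clean_film()
        records, _ = generate_calibration_set(self.DOSES, film, ideal_scanner,
                                              seed=71)
        roi = scoring_roi()
        od, dose = [], []
        for rec in records:
            od.append(net_od(roi_stats(rec["background"], roi, "red").mean,
                             roi_stats(rec["exposed"], roi, "red").mean))
            dose.append(rec["dose_gy"])
        curve = fit_calibration(np.array(od), np.array(dose), "red")
        p = curve.channels["red"]
        q = film.curve.channels["red"]
        # quantization to 16-bit limits "exact" to ~1e-5 here
        assert p.b == pytest.approx(q.b, rel=1e-3)
        assert p.c == pytest.approx(q.c, rel=1e-4)
        assert od_to_dose(dose_to_od(2.0, film.curve, "red"), curve, "red"
                          ) == pytest.approx(2.0, rel=1e-4)

    def test_single_dose_raises_downstream_insufficiency(self, film,
                                                         ideal_scanner):
        records, _ = generate_calibration_set([2.0], film, ideal_scanner,
                                              seed=72)
        with pytest.raises(InsufficientDataError):
            fit_calibration([0.18], [2.0], "red")

    def test_missing_2gy_warns(self, film, ideal_scanner):
        with pytest.warns(UserWarning, match="2 Gy"):
            generate_calibration_set([1.0, 4.0], film, ideal_scanner, seed=73)

    def test_empty_dose_list_rejected(self, film, scanner):
        with pytest.raises(InputError):
            generate_calibration_set([], film, scanner, seed=74)

    def test_fixture_directory_written_and_reloadable(self, film,
                                                      ideal_scanner, tmp_path):
        from ebt3dose import read_film_tiff
        generate_calibration_set([1.0, 2.0], film, ideal_scanner, seed=75,
                                 out_dir=tmp_path)
        files = sorted(tmp_path.glob("*.tif"))
        assert len(files) == 4
        for f in files:
            scan = read_film_tiff(f)
            assert (scan.width_px, scan.height_px) == (576, 720)
        assert (tmp_path / "truth.csv").exists()
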
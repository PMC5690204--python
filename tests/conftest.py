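"""Shared fixtures: simulator models and derived corrections.

Session-scoped where derivation is expensive (matrix + MD from full-bed
stacks); all randomness is seeded so the suite is reproducible.
"""

import numpy as np
import pytest

from ebt3dose import (FilmModel, ScannerModel, build_dose_transversal_correction,
                      build_matrix_correction, default_stripe_positions,
                      default_true_curve, generate_stripe_series,
                      generate_unexposed_stack)


@pytest.fixture(scope="session")
def film():
    return FilmModel()


@pytest.fixture(scope="session")
def scanner():
    return ScannerModel()


@pytest.fixture(scope="session")
def quiet_scanner():
    """Noise-free, artifact-bearing scanner for exact-value checks."""
    return ScannerModel(noise_sd_pv=0.0)


@pytest.fixture(scope="session")
def ideal_scanner():
    """No artifacts, no noise: the identity instrument."""
    return ScannerModel(left_deficit_pv=0.0, right_deficit_pv=0.0,
                        longitudinal_deficit_pv=0.0,
                        dose_lateral_amplitude_pv=0.0, noise_sd_pv=0.0,
                        drift_per_scan=0.0)


@pytest.fixture(scope="session")
def true_curve():
    return default_true_curve()


@pytest.fixture(scope="session")
def unexposed_stack(film, scanner):
    return generate_unexposed_stack(10, film, scanner, seed=42)


@pytest.fixture(scope="session")
def matrix(unexposed_stack):
    return build_matrix_correction(unexposed_stack)


@pytest.fixture(scope="session")
def md_table(film, scanner, matrix):
    stripes, _ = generate_stripe_series(
        2.0, default_stripe_positions(scanner), film, scanner, seed=7)
    return build_dose_transversal_correction(stripes, 2.0, matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
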
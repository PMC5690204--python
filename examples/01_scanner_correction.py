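"""Derive and apply the two-phase scanner correction on simulated scans.

Builds the per-pixel matrix correction from ten simulated unexposed films,
the dose-dependent transversal correction from a 2 Gy stripe series, then
reads out a uniform 2 Gy full-bed film and reports how flat the recovered
dose is — with and without the dose-dependent term.
"""

import numpy as np

from ebt3dose import (FilmModel, ScannerModel, apply_corrections_iterative,
                      build_dose_transversal_correction,
                      build_matrix_correction, default_stripe_positions,
                      default_true_curve, extract_profile, flatness,
                      generate_stripe_series, generate_unexposed_stack,
                      simulate_scan, uniform_field)

film, scanner, curve = FilmModel(), ScannerModel(), default_true_curve()

# Phase one: matrix correction from an unexposed stack.
stack = generate_unexposed_stack(10, film, scanner, seed=1)
matrix = build_matrix_correction(stack)
m = matrix.m["red"]
print(f"matrix correction (red): left edge {m[360, 0]:+.0f} PV, "
      f"center {m[360, 288]:+.0f} PV, right edge {m[360, -1]:+.0f} PV")

# Phase two: dose-dependent transversal correction from a stripe series.
stripes, _ = generate_stripe_series(2.0, default_stripe_positions(scanner),
                                    film, scanner, seed=2)
md = build_dose_transversal_correction(stripes, 2.0, matrix)
print(f"MD at 2 Gy (red): right edge {md.md['red'][1, -1]:+.0f} PV "
      f"(zero over the normalization columns)")

# Read out a uniform 2 Gy film spanning the whole bed.
rng = np.random.default_rng(3)
piece = film.sample_piece(576, rng, "demo")
bg, _ = simulate_scan(uniform_field(0.0, (720, 576)), piece, scanner, rng=rng)
ex, _ = simulate_scan(uniform_field(2.0, (720, 576)), piece, scanner, rng=rng)

corrected, dmap = apply_corrections_iterative(ex, bg, matrix, md, curve)
_, dmap_m = apply_corrections_iterative(ex, bg, matrix, None, curve)

for label, d in (("matrix only", dmap_m), ("matrix + iterative MD", dmap)):
    prof = extract_profile(d, "transversal", width_px=400)
    print(f"{label}: mean dose {d.dose.mean():.4f} Gy, transversal "
          f"flatness (central 80 %) {flatness(prof) * 100:.2f} %")
print(f"iterations to fixed point: {corrected.iterations} "
      f"(last dose change {corrected.max_dose_change_gy * 1000:.2f} mGy)")
# The dose-dependent term is what flattens the right half of the bed:
# without it the profile deviates by a few percent, with it by ~0.1 %.
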
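# Methods

## Measurement model

A flatbed transmission scan of radiochromic film yields, per colour
channel, 16-bit pixel values (PVs): higher PV means more transmitted
light, i.e. less dose. The dose-carrying signal of a film piece is its net
optical density against its *own* pre-irradiation background scan,

    OD_net = log10(PV_un / PV_ex),

which cancels multiplicative film-background structure (emulsion bands,
piece-to-piece offsets) pixel by pixel. Dose is recovered through a
rational response

    D(x) = (a + c·x) / (1 + b·x),    x = OD_net,

fitted per channel and film lot by unweighted least squares
(`scipy.optimize.least_squares`, linear-model initialisation, tolerances
1e-15). In this parameterisation a realistic, saturating film response
(OD concave in dose) corresponds to b < 0; the fit is accepted only if the
curve is monotone increasing over the calibrated OD range and conversion
beyond the largest calibration dose is refused by default. The typeset
source of the rational form is ambiguous between a full fraction and an
additive variant `D = a + c·x/(1 + b·x)`; both are implemented
(`form="rational"` is the default, the choice is recorded in the
calibration archive). Negative net OD (exposed reading brighter than
background, possible at zero dose under noise) maps to 0 Gy by a clamp;
fits can optionally constrain a = 0 so D(0) = 0 exactly.

Dose determination uses the red and green channels, combined by averaging
their *doses* (never PVs or ODs — the channels have different response
curves, so only dose is commensurable). The blue channel carries too
little dose signal but is the most sensitive to emulsion-thickness
variation and is therefore used for film homogeneity QC only.

## Two-phase scanner correction

The scanner's sensitivity is corrected additively in PV space,

    PV_corr(x, y) = PV(x, y) + M(x, y) + MD(x, D),

matching the additive structure in which the artifact magnitudes are
observed. The corrections are relative to a 3 cm × 4 cm normalization area
in the middle of the bed: M averages to zero there, MD is zero on its
columns at every dose.

**Matrix correction M** (per pixel, per channel): from a stack of n ≥ 2
unexposed films, `M = mean(stack mean over norm ROI) − stack mean`.
Adding M to the stack mean flattens it exactly; a global offset common to
all input scans cancels. Film-specific structure (bands) enters M only
attenuated by 1/n, which is why ten films are the standard input.

**Dose-dependent transversal correction MD** (per column, per channel,
indexed by dose): a single film stripe exposed to one uniform dose
(rotating-reel exposure, ~0.2 % 1 SD) is scanned at several transversal
positions spanning the bed. After matrix correction, each placement's
per-column mean is compared with the level the same stripe reads on the
normalization columns; overlapping placements are averaged, uncovered
columns filled by linear interpolation, and film presence is detected on
the *raw* scan (the matrix correction would lift empty columns by up to
~1800 PV and must not be consulted for coverage). The table always
contains an all-zero row at 0 Gy — an unexposed film is fully corrected by
M alone. Lookup is exact in column and linear in dose, clamped beyond the
grid (constant extrapolation avoids wild behaviour above the highest
measured level). How far a single-dose table generalises across the dose
range is a property of the scanner, not assumed here: the dose grid is a
user input, and the shipped default derives the table at the 2 Gy working
point.

**Iteration**: MD is indexed by the very dose being measured, so the
correction is a fixed-point problem. Iteration 0 applies M only (to the
exposed scan and its background) and produces a first dose estimate as
the red/green mean; each further iteration applies `PV + M + MD(x, D_prev)`
with the *combined* dose estimate indexing every channel's table
(physically there is one dose field). The loop stops when the largest
per-pixel dose change falls below `tol = max(0.002 Gy, 0.1 % of the median
dose)` or after `max_iter = 10`; on the simulator's artifact model it
contracts and converges in 2–3 iterations. After convergence the stored
corrected PVs are re-synced to the final dose so the additive identity
holds pointwise.

The background scan is matrix-corrected with the same M before the OD
ratio — both readings are position-dependent measurements. For
orientations other than normal, the corrected background is re-oriented by
the pixel-exact index transform so the OD ratio pairs pixels of the same
film point; this is exact for the symmetric, centered placements the film
holder enforces.

## Four-orientation merge

The film is symmetric and readable from both sides, so one film yields
four scans: normal, rotated 180°, flipped, flipped+rotated (all four
transforms are involutions; restoration is pure index permutation, no
interpolation, and preserves the dose histogram exactly). Each scan is
corrected and converted to dose *first* — the four reads sit on different
parts of the bed and need different corrections — then restored and merged.
Per pixel, the median of the four is the robust reference; any orientation
deviating by more than `max(2 % of |median|, 0.04 Gy)` is excluded and the
mean is taken over the survivors. The threshold sits above the merged-map
noise and well below visible dust artifacts (a speck produces a ~10–25 %
local dose error). If fewer than two maps survive, the pixel keeps all
four and is flagged unreliable. Dust on the scanner glass is
orientation-specific and is caught this way; scratches or dirt on the film
itself appear in all four reads at film-fixed positions and are
deliberately *not* corrected. Registration is purely geometric — the film
holder centers the film — with no feature-based alignment and no sub-pixel
resampling.

## Uncertainty budgets

Components are relative standard uncertainties (%, 1 SD), assumed
uncorrelated and combined in quadrature step by step; a coverage factor k
(k = 2 ≈ 95 %) expands the combined value. Values are stored at full
precision and rounded to two decimals for display. The shipped three-step
absolute-dose budget (ionization-chamber reference dose 1.40 %, film
calibration 0.71 %, film measurement 1.00 %) is a documented input, not a
derivation: the package computes the accumulation (1.57 %, 1.86 %, 3.72 %
at k = 2), not the component magnitudes, which require instrument-side
analysis. The relative-dose figure quoted in the field additionally
contains a normalization component that cannot be recomputed from the
printed steps; it is documented here and not targeted.

## The simulator and what it does (not) show

The synthetic module inverts the analysis chain: ground-truth dose →
film response (the same rational curves, exactly invertible) → film
inhomogeneity → orientation geometry → scanner degradation → quantization
to 16 bits. Defaults define the study conditions and are frozen:

| parameter | default | rationale |
|---|---|---|
| bed geometry | 576 × 720 px, 72 dpi | fixed full-bed scan format |
| background PV (r/g/b) | 40000 / 40500 / 38000 | puts 2 Gy at ~26 200 PV in red, the working point of the budget |
| response curves (a, b, c) | red (0, −0.603, 9.72); green (0, −0.794, 12.70); blue (0, −2.778, 27.78) | monotone over 0–8 Gy; realistic channel sensitivity ordering red > green ≫ blue |
| transversal deficit | 300 PV left → 0 center → 1800 PV right, quadratic | the characterized artifact magnitudes |
| longitudinal deficit | ≤ 340 PV, quadratic, not dose-dependent | characterized magnitude |
| dose-dependent lateral term | 900 PV · D/(D + 1 Gy) at right edge (600 PV at 2 Gy), zero left of the norm band | reproduces a several-percent matrix-only dose error at 2 Gy, the regime the iterative correction exists for |
| pixel noise | 5 PV (1 SD) | consistent with sub-0.2 % short-term repeatability of PV means |
| drift | +0.03 %/scan, exposed film only | measured scanner-light sensitivity |
| emulsion bands (max dev) | 0.03 % r/g, 0.3 % blue | keeps good film inside the 0.5 %/1 % background QC rules with blue an order of magnitude more sensitive |
| piece offsets (1 SD) | 0.1 % r/g, 0.2 % blue | same reasoning |
| reel stripe uniformity | 0.2 % 1 SD, iid per pixel | exposure-rig specification; iid so column averaging suppresses it |
| dust specks | radius 1–3 px, 6–12 % PV drop | ~10–25 % local dose error, clearly above merge noise |
| post-exposure darkening | piecewise linear through (0 d, 0.970), (2 d, 0.998), (4 d, 1), (16 d, 1.010), as an optional OD multiplier | read-out timing sensitivity only; kinetics fitting is out of scope |

Artifacts are injected additively in PV — the same model class the
correction assumes. A multiplicative-mismatch knob exists for robustness
probing and is off by default, so passing tests show that the correction
recovers its own model class exactly and the injected magnitudes
faithfully; they do not show robustness to a scanner whose artifact is
structurally different, nor do they validate the specific smooth
interpolation chosen for the deficit between its characterized endpoint
magnitudes. Scanner-specific corrections must always be derived per
instrument, never transferred.

Every generator records its full ground truth (dose fields, band patterns,
speck masks), all randomness flows from one explicit seed, and fixtures
are bit-reproducible.

## Numerical choices and degenerate inputs

- ROIs are half-open, 0-based, top-left origin; physical ROIs convert at
  exactly 72 dpi with rounding to nearest pixel.
- Population SD for ROI statistics (descriptive pixel statistics).
- Repeated scans: ≤ 5 → pixelwise mean; > 5 → per-pixel linear trend over
  the scan index evaluated at the first scan (removes exposed-film drift).
  Averaging is done in PV; whether OD averaging would be preferable is an
  open protocol question and PV was chosen for linearity with the drift.
- PVs ≤ 1000 are treated as "no film / blocked light" and excluded from
  dose conversion (the holder blocks direct light).
- Scans are rejected unless they are RGB with 16 bits per channel; no
  colour management is ever applied.
- QC thresholds are strict inequalities ("more than"); boundary equality
  accepts.
- The 8-bit mask TIFFs and float32 dose TIFFs are written uncompressed;
  film scans are written with lossless deflate.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data:
10-scan full-bed stacks for the matrix correction, 5-placement stripe
series at 2 Gy for MD, single full-bed 2 Gy films for profile fidelity,
100-seed Monte Carlo for noisy calibration recovery and 8 seeds for the
merge averaging law. These sizes match the protocol's own scan counts
(ten unexposed films, three to five calibration dose levels) rather than
being scaled down from them.

## Known limitations

- The optical cause of the lateral artifact is not modelled; corrections
  are empirical and scanner-specific.
- Beam-quality conversion of calibrations, dose-rate dependence, and
  energy-dependence analysis are out of scope (instrument- and
  accelerator-side work).
- No TPS/DICOM-RT import or gamma-index analysis; profile comparison is
  the verification surface.
- Film-fixed defects (scratches, permanent dirt) are not corrected by the
  merge; in-fill smoothing of masked pixels is not attempted.
- Sub-pixel registration between orientations is out of scope; placements
  with odd centering offsets would be off by one pixel.
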
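# Methods

This note records the scientific model behind each stage, the defaults
and why they were chosen, what the simulator does and does not emulate,
and the numerical and design decisions a maintainer should know about.

## Scene simulator

The simulator's purpose is to provide scenes in which the true class,
depth and spectrum of every pixel are known, so that each downstream
stage can be validated as a parameter-recovery problem.

**Wavelength grid.** Default 274 uniform bands over 400–1000 nm
(≈ 2.2 nm sampling), matching a typical VNIR push-broom scanner.

**Endmembers.** Synthetic smooth curves, not measured coral spectra.
Per genus, a green-brown base shape (Gaussian peak at 565 nm, low blue
and NIR) is perturbed by up to three random Gaussian features confined
to 580–720 nm, then scaled by a brightness factor 0.95 − 0.10·(level−1)
so band-mean reflectance strictly decreases from bleaching level 1
(severely bleached, brightest) to 6 (healthy). Levels 1–2 additionally
receive bumps at 400 and 750 nm (amplitudes 0.18 and 0.09, σ = 30 nm),
reproducing the elevated blue/NIR response of bleached tissue.
Restricting genus-to-genus variation to the red/NIR keeps the
blue-green spectral slope shared across corals (R540/R480 ≈ 2.3–2.5),
which matters for the water-column model below. Backgrounds: bright
sand (0.40–0.52, slowly rising), dark benthos constructed as 0.22× the
sand shape plus a red-edge shoulder (spectrally correlated with sand in
the blue-green — the regime in which band-ratio bathymetry is valid),
dark water, and flat 0.9 spume. Real reefs additionally show pigment
fine structure, fluorescence and mixed pixels; none of these are
modelled, so passing tests demonstrate correctness of the pipeline's
arithmetic and its qualitative behaviour, not field-accuracy claims.

**Water column.** Two-way Lambert–Beer attenuation
R_obs(λ) = R_bottom(λ)·exp(−2k(λ)z) + offset(λ). Default
k(λ) = max(0.10 + 0.0012·(λ−480), 0.01) + 0.9·σ((λ−730)/25) m⁻¹ — rising
through the visible (k at 540 nm exceeds k at 480 nm by ≈ 0.07 m⁻¹,
the contrast the log-ratio depth index needs) with a strong NIR term;
the water-leaving offset is a small bluish spectrum (max 0.005).
Values are plausible for moderately clear coastal water but are design
choices, not fits to any measurement. Spume is rendered unattenuated
(foam floats). Noise is i.i.d. per-band Gaussian in reflectance units
before illumination scaling; 0.01 is the standard test level.

**Scene layout.** Non-sand classes are round blobs on a jittered tile
grid (no overlap, every class ≥ 1 pixel) over sand; depth is a smooth
0 → max-depth gradient along rows with a 2% sinusoidal cross-track
modulation (or a constant for controlled experiments). Standard test
conditions: 128×128 pixels, six coral classes (two genera × three
levels), 3 m maximum depth, 64 survey points.

## Radiometry

Reflectance = radiance / white-reference, clipped to [0, 1]; values
above 1 (glint) carry no meaning in this model and handling them is out
of scope. The optional "gamma increase" g ∈ [0, 0.75] is implemented as
the brightening power law v ↦ v^(1/(1+g)): monotone, endpoint-fixed,
and rank-preserving per band. It is off by default; it changes contrast
only, and the RBF-SVM is not scale-invariant, so enabling it is an
experiment, not a recommendation. Kernel γ and image gamma are
unrelated quantities despite the shared name.

## Bathymetry and water-column correction

The relative depth index ln(n·R_blue)/ln(n·R_green) uses the nearest
grid bands to 480/540 nm and n = 1000 (keeping the log arguments > 1
for typical reflectances; n is configurable). Pixels with a log
argument ≤ 1 are flagged invalid rather than propagated as NaNs. The
index is exactly albedo-independent only for spectrally flat bottom
changes; bottoms whose blue/green ratio itself differs shift the index,
which is why calibration points should come from the bottom type being
mapped, and why the depth-error test evaluates over the surveyed class
only. Natural log is used; any other base rescales the index and is
absorbed by the linear calibration.

The variance quadratic y(x) = −18.353x² + 10.805x + 0.238 (percent) is
evaluated at x = ln(R_green/R_blue) per pixel and floored at 0, since
it extrapolates negative outside its fitted range; its analytic maximum
is y ≈ 1.8283 at x ≈ 0.2944. Depth correction rescales each spectrum by
1/(1 − y/100) (capped and flagged if y ≥ 100). Two regime notes:
(a) with the green-peaked coral spectra above, x sits above the
quadratic's vertex for depths up to ≈ 2.5 m and *decreases* with depth,
so y — and hence the boost — increases with depth there, which is what
lets the correction shrink the divergence between same-class spectra at
1 m and 2.3 m; (b) beyond that regime y floors at 0 and the correction
becomes a no-op rather than misbehaving. The correction is a per-pixel
scalar rescale of at most ~1.9%; it is a second-order refinement, not
an inversion of the water column.

Band-ratio methods degrade quickly with depth; the pipeline warns when
the median calibrated depth exceeds 8 m. Full radiative-transfer
inversion (10–12 m capable) is explicitly out of scope.

## Signatures

Extraction averages all pixels in an odd window (default 3×3, absorbing
georeferencing jitter) around each survey point, grouped by
(genus, level). The match score between two signatures is the percent
of bands whose means agree within tolerance × amplitude, where the
amplitude is the larger peak-to-peak range of the two means (making the
score symmetric) and the default tolerance is 0.10. This is one
reasonable definition among several; it is kept as a small pluggable
function so a correlation-based score can replace it.

## Indices

All Table-style indices are normalized differences evaluated at
nearest grid bands (no interpolation — on a 2.2 nm grid the gain would
be negligible). The registry holds 34 bleaching-index definitions plus
the genus index; note the genus index's four-wavelength form
(R_540 − R_575)/(R_450 + R_586) groups difference-over-sum by analogy
with every two-band index. NDVI variants use NIR = 750 nm with
green = 550 nm or yellow = 600 nm; the colour names are bound to these
wavelengths as package defaults. The full registry needs 395–768 nm
coverage, which the 400–1000 nm sensor grid misses at 395 nm: on such
cubes `evaluate_table1` raises a coverage error listing the missing
wavelength, and the pipeline computes the evaluable subset and logs the
skip.

## Classification

`SVC(kernel="rbf")` with one-vs-one voting; defaults
γ = 1/(n_bands·Var) ("scale") and C = 10 — the hyperparameters are not
dictated by the method and are exposed in config. Unsupervised k-means
(seeded, n_init = 10) only *flags* pixels whose supervised label
disagrees with their cluster's majority label. Denoising applies
Savitzky–Golay smoothing along bands (default window 5, order ≤ 2)
followed by a per-band spatial median (default 3×3); windows of 1
disable a stage.

## Accuracy assessment

The overall-accuracy combination rule — 0 when the excessive-area flag
is set, else min(signature accuracy, points accuracy) — is the unique
simple rule consistent with every row of the reference assessment
tables the package reproduces in its fixture test. The EA criterion
itself (mapped area > 5 × reference prevalence, strict) and the 3×3
point-matching window are package choices, configurable; on synthetic
runs the truth raster supplies prevalence, and classes without a
reference prevalence are not EA-assessed. Points accuracy is reported
to 3 decimals and overall to 2, matching the mixed precision of the
reference tables (whose own last digits are not mutually consistent in
one cell; the fixture test therefore compares that column to one unit
in the last printed digit).

## Spume

Spume (sea foam) is modelled as a bright flat 0.9 surface spectrum. In
the contamination experiment, foam overlays coral whose in-water record
remains the class beneath: without exclusion those pixels enter
training, mapping and assessment and are misclassified, lowering the
affected classes' recall; rasterizing the spume polygons into an
exclusion mask and applying it to all three restores it. Pixel centers
are tested against polygons with boundary-inclusive point-in-polygon;
polygons are GeoJSON-ordered (x = longitude).

## Numerical conventions

Pixels are 0-based (row, col) with centers at integer coordinates;
geographic mapping is a north-up affine treated as planar (no datum).
`geo_to_pixel` rounds to the nearest pixel with ties toward −∞.
Nearest-band lookup breaks ties toward the lower index and rejects
targets farther than one grid spacing from any center. ENVI files are
little-endian, float32 by default (float64 and common integer types
supported), BIL or BSQ; unknown header keys round-trip verbatim.
Determinism: every stochastic step takes an explicit seed; fixed seeds
give bit-identical scenes, cubes, tables and maps.

## Known limitations

No radiative-transfer realism (no sun glint, tides, turbidity,
inelastic scattering), no mixed pixels or sensor geometry artifacts, no
orthorectification, no datum/projection handling, hard per-pixel
classification only (no spectral unmixing), and the water-column
correction is valid as a small perturbation in the shallow (≲ 2.5 m)
regime described above.
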
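# Methods

This note documents the models and numerical choices behind `torsomorph`:
what each stage computes, which parameters matter and why their defaults
are what they are, what the synthetic cohort generator does and does not
emulate, and the known limitations.

## Anatomical frame

The frame is built from four bony landmarks. Origin: midpoint of the
xiphoid process and the 9th thoracic vertebra (the torso centre).
Axis vocabulary follows scan-processing convention — the **transverse
axis** is the unit vector xiphoid→T9 (an anterior→posterior *direction*,
normal to the coronal plane, not the transverse plane); the **sagittal
axis** is ASIS left→right; the **longitudinal axis** is their cross
product, sign-corrected to point from the pelvis toward the chest.

The two defining landmark vectors are generally not orthogonal in a real
body, so one of them must bend. The default keeps xiphoid→T9 exact and
orthogonalizes the ASIS direction against it (Gram–Schmidt), because the
longitudinal axis is *derived* from those two vectors, making them primary;
`build_frame(..., keep="sagittal")` preserves the ASIS direction instead for
sensitivity analysis. On non-degenerate input the axes are orthonormal to
1e-9 and right-handed; landmark vectors within 1° of parallel are rejected.

Rigid equivariance is exact: applying any rotation + translation to cloud
and landmarks jointly leaves anatomical coordinates unchanged (tested to
1e-6 mm over random motions).

## Segmentation and slicing

The torso segment spans from the ASIS level (mean of the left/right ASIS
longitudinal coordinates — the pair is never exactly level) to the xiphoid
level, closed interval. 21 slice centres sit at equal 5% fractions of
segment length; each slice keeps points within ±1 mm (2 mm total thickness)
of its centre and drops the longitudinal coordinate.

**Reference-length standardization.** Absolute parameters (slice thickness
in mm, spline roughness in mm²) are not scale-equivariant: a uniformly
enlarged scan would put different points into a fixed 2 mm band. Before
slicing, the segment is therefore brought to a 400 mm reference length by
one uniform, shape-preserving scaling; "2 mm" thus means 2 mm on a 400 mm
segment (0.5% of segment length) for every participant. This makes the
whole extraction *exactly* invariant under uniform scaling of the input —
verified to 1e-6 over 50 random rigid+scale trials — while reproducing the
absolute protocol for a typical ~400 mm adult torso segment.

## Polar waveforms

Each slice is re-expressed about its own centroid (arithmetic mean of the
raw 2D points) as radius vs angle. Angle runs counter-clockwise from the
+sagittal axis viewed from above, so 90° is anterior; since every
participant shares the anatomical frame, any fixed convention preserves
comparability. Raw points are averaged in 360 uniform angular bins (1°);
empty bins are filled by periodic linear interpolation as long as no empty
run exceeds 15° — a wider gap indicates occlusion or a non-star-shaped
cross-section and is an error, since the scan pose is assumed compliant
(arms clear of the torso).

A periodic cubic smoothing spline (FITPACK `splrep` with `per=1`) is fitted
to the binned values and evaluated back on the uniform grid. The roughness
budget defaults to 1 mm² per angular sample; zero reproduces the binned
values exactly. The default was calibrated on a synthetic benchmark —
a circle with 2 mm Gaussian radial noise — where it must reduce the RMSE to
the true radius below 1 mm (it does; the test suite keeps this benchmark).
Because the budget is applied after reference-length standardization it is
scale-consistent across participants.

Whether the source protocol binned, ordered or spline-fit raw polar points
directly is not specifiable from the outside; the binning + periodic-spline
scheme above is this package's resolution, chosen for robustness to uneven
point density.

## Scale removal

Centroid size is the geometric-morphometrics scale measure: the square root
of the sum of squared distances of all 21×360 radius samples from their
slice centroids. One scale factor brings every torso to centroid size
S₀ = 1 (the common value is immaterial — descriptors are centred before
PCA — only its equality across participants matters). A plain
sum-of-distances variant is available (`scaling_variant="sum"`) because the
two readings of the scaling step differ in the literature; root-sum-of-
squares is the formal definition and the default. Centroid size is computed
on the uniformly resampled radii, not the raw points, so scanner-dependent
point-density variations do not leak into scale.

## Fourier descriptors

With the 1/N convention, c_k = (1/N) Σⱼ rⱼ·exp(−2πi·k·j/N), k = 0..9.
Retaining the DC term is deliberate: after whole-torso scale normalization,
per-slice DC encodes the relative girth profile along the torso
(waist-to-chest taper) — genuine shape information the PCA must see. The
k = 1..10 variant is available (`include_dc=False`). No phase or modulus
normalization is applied: the anatomical frame already fixes orientation,
and discarding phase would destroy anterior/posterior asymmetry. Rotating a
torso about the longitudinal axis by φ multiplies c_k by exp(−ikφ) — a
tested equivariance, kept as meaningful shape information rather than
removed.

Descriptors flatten slice-major (10 real parts, then 10 imaginary parts per
slice; 420 reals). The c₀ imaginary entries are structurally zero for a real
waveform; they carry zero variance, contribute nothing to the PCA, and are
clamped to zero on inversion.

Band-limited waveforms (k ≤ 9) survive the forward/inverse pair exactly;
for general waveforms the reconstruction deficit equals the discarded
high-frequency energy (Parseval), both tested.

## Shape-feature PCA

Covariance PCA (columns centred, not variance-scaled): all 420 descriptor
entries share one dimensionless unit post-scaling, and column
standardization would inflate noise-dominated high-frequency terms.
Components are ordered by decreasing variance; retention keeps the smallest
leading set reaching 95% cumulative explained variance. The retained-count
and the stepwise candidate pool (first 11 PCs) are configured
independently. Loading signs are fixed (largest-magnitude entry positive)
so scores and regression coefficients are reproducible. Scores are exactly
uncorrelated across components — the "independent shape features" property.

PC-extreme torsos are reconstructed as mean ± magnitude·loading, inverted
slice-by-slice and lofted into a triangle-strip tube over the shared angle
grid (end caps omitted; slice centroid offsets are not part of the
descriptor, so rings are coaxial). Per-vertex deviations are radius
differences from the mean torso at the same (slice, θ), written to PLY as
the float "quality" property.

## Statistics

Indices: BMI = mass/stature², WHR = waist/hip, WHT.5R = waist/√stature,
with stature and waist in metres; skinfolds and their sum in mm. Z-scoring
uses the sample SD (n−1). Correlations are pairwise-complete Pearson r with
two-sided p from the t transform.

Regressions are OLS (statsmodels) with listwise deletion per model; `n_used`
is always reported, and with 6 of 43 participants missing skinfolds the
default cohort reproduces df = (1, 35) single-predictor models.
Standardized β are computed from the SDs of the complete-case sample
actually fitted — this keeps the single-predictor identity R² = β² exact
per model even when deletion shrinks a pre-standardized table. Collinearity
diagnostics per predictor: VIF = 1/(1 − R²ⱼ) with R²ⱼ from the centred
regression of predictor j on the others (intercept included), tolerance its
reciprocal. Durbin–Watson is computed over residuals in input row order;
on cross-sectional data it is order-dependent, which is documented rather
than hidden.

**Stepwise selection.** Forward-with-backward: the candidate with the
smallest partial-F p-value enters if it clears the entry criterion; any
included predictor with p > p_remove (default 0.10) is then dropped;
iterate to a fixed point (p_enter < p_remove prevents cycling). The entry
criterion defaults to a Bonferroni family correction,
p < p_enter / n_remaining: with an 11-candidate pool of pure noise the
empty model is kept at family rate ≈ 1 − p_enter (≥ 90% of seeds, a tested
calibration), whereas the classic per-candidate rule
(`entry_correction="none"`, as in legacy statistics packages) admits at
least one noise variable with probability ≈ 1 − 0.95¹¹ ≈ 43%. Genuine
signal (p ≪ 0.05/11) is selected identically under both rules.

Model families (10 models): each of BMI, WHR, waist girth, WHT.5R alone;
stature+mass+waist+hip jointly; stepwise over the first 11 shape PCs; each
index plus the stepwise-selected PCs. Combined models always satisfy the
nested-model property R²_combined ≥ R²_index.

## Synthetic cohort generator

The generator defines the package's study conditions. A torso surface is

r(θ, z) = base(f) · (1 + Σₘ aₘ·wₘ(f)·cos(kₘθ + φₘ)),   f = height fraction,

with base(f) = 140 mm · (1 + 0.08·cos 2πf): hips and chest wide, waist
narrow, over a 400 mm ASIS→xiphoid segment. Default modes: anterior
weighting (k=1, peak at 90°, SD 0.040), ellipticity (k=2, SD 0.030) and a
girth-taper mode (k=0, w = cos πf, SD 0.012). Modes are mutually orthogonal
on the (slice, θ) grid by construction — the same functional space the
Fourier descriptors span, so injected modes map to exactly known descriptor
directions and recovery is testable without approximation. The k=0
amplitude SD is set smaller because a DC mode enters the waveform at full
weight while k ≥ 1 harmonics split across ±k; the chosen SDs keep the
descriptor-space variances well separated and ordered. Surface points are
sampled at 0.35 points/mm² with 1 mm radial Gaussian noise (≈ 600 points
per 2 mm band); each scan then receives a random rigid motion and uniform
scale (0.8–1.25) so the invariances are genuinely exercised. Landmarks are
placed on the deformed surface (xiphoid/T9 anterior/posterior at the top
level, the ASIS pair antero-lateral at the bottom level).

Anthropometrics are drawn from a correlated Gaussian around cohort-style
means (stature 179.8 ± 7.2 cm, mass 82.9 ± 16.2 kg, waist 86.06 ± 10.19 cm,
hip 100.36 ± 7.3 cm) with a published-table correlation structure. The
skinfold sum is linear in the mode-amplitude z-scores and the waist
z-score plus Gaussian noise (defaults give SD ≈ 26 mm about a 52 mm mean
and a waist–SSF correlation ≈ 0.72), floored at 5 mm and split across the
three sites with jittered shares that sum exactly to the total. By default
6 of 43 participants have their skinfold triplet withheld, reproducing
n = 37 regressions. The `r2_preset` helper decouples waist and sets the
mode coefficients so the shape modes explain a planned fraction (e.g. 0.50)
of SSF variance — the target the recovery tests must hit.

Two routes share all shape mathematics: sampled point clouds (full
pipeline), and exact radii on the 21×360 analysis grid (the fast route for
statistical experiments at n = 2000, where sampling hundreds of millions of
surface points would add nothing). The two agree to ~1e-3 in descriptor
units; the residual is the sampling noise of each slice centroid
(SE ≈ (r/√2)/√n_slice), which leaks into the k=1 coefficients.

**What the generator does not emulate:** non-star-shaped cross-sections
(arms touching the torso), posture variation, scanner occlusion and holes,
landmark palpation error, asymmetric or non-harmonic shape variation, and
any nonlinear shape–adiposity relationship. Passing tests therefore
demonstrate correctness of the geometry, descriptor algebra and statistics
under the stated generative model — not field performance on real scans.

## Problem sizes and determinism

Cohort-level tests run at n = 43 (point-cloud route) and n = 150–2000
(analytic-profile route); the null-calibration suite uses 200 seeds at
n = 200. All randomness flows through `numpy.random.Generator` seeded from
explicit spec seeds (per-participant child streams via `SeedSequence`), so
every cohort is reproducible bit-for-bit and re-running any stage on the
same inputs produces byte-identical CSV output.

## Known limitations

- The slice-thickness interpretation (relative to a 400 mm reference
  segment) is a package decision; for segment lengths far from 400 mm the
  absolute band width deviates from 2 mm accordingly.
- Durbin–Watson on cross-sectional data depends on row order; it is
  reported for completeness of the diagnostic set, not as a substantive
  test.
- Descriptors discard slice-centroid offsets between slices (lateral
  shear/lean of the torso column is not represented), matching the
  radius-waveform formulation.
- The stepwise entry correction is a deliberate deviation from legacy
  per-candidate entry; use `entry_correction="none"` to reproduce the
  legacy behavior.
- PCA identifiability: when two modes have comparable descriptor-space
  variances, finite-sample correlations between their amplitudes rotate
  the recovered components within the mode subspace (the subspace itself
  is recovered to < 5° principal angles at 10:1 signal-to-noise).
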
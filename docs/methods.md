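# Methods

## Signal model and fit

The package models the asymmetric spin-echo (ASE) signal in two regimes
only: the spin echo (τ = 0) and the mono-exponential long-τ regime
(τ > `fit_tau_min`, default 15 ms):

    log S(0) = log S0 − TE·R2
    log S(τ) = log S0 − TE·R2 + DBV − R2′·τ

The short-τ quadratic qBOLD regime is deliberately not modelled: the
reference protocol acquires τ = −16…64 ms in 8 ms steps but fits only the
spin echo and τ = 16…64 ms, and the DBV estimate is precisely the offset
between the spin echo and the long-τ intercept.  Requests for signal in
(0, 15] ms raise an explicit unsupported-regime error; the phantom
generator emits the −16, −8 and +8 ms volumes only for file-format
realism (as the long-τ model evaluated at |τ|), flags them in metadata,
and the fitting stage never consumes them.

Each voxel is a 3-unknown weighted least-squares problem with design rows
(0, 0, 1) for the spin echo and (1, −τᵢ, 1) for the long-τ samples, solved
in closed form for all voxels at once.  Standard deviations come from the
model-based covariance σ̂²(AᵀWA)⁻¹ with σ̂² the weighted residual sum of
squares on n − 3 degrees of freedom.  This is exact when the per-row noise
variance is proportional to 1/wᵢ, which is the structure the inverse-τ
weighting asserts (later echoes have decayed further and carry more
log-signal noise); the tests validate the formula under that structure.
Whether the residual variance should instead be unweighted is not
determined by the analysis the package reproduces; the weighted form was
chosen as the internally consistent one.

Weighting: `inverse_tau` assigns wᵢ = 1/τᵢ to long-τ rows; 1/τ is
undefined at the spin echo, which receives the largest long-τ weight
(1/min τ).  Weights are normalised to mean 1 (estimates are invariant to
the scale; the normalisation only stabilises reporting).  A `uniform`
scheme (OLS) is available.  Whether the original analysis weighted the
spin-echo row at all is unknowable from its description; both options are
exposed and the default is the monotone one.

Estimates are **not** clamped to physical ranges: negative DBV or R2′
excursions at low SNR propagate into downstream medians, and [dHb] is
undefined (NaN) wherever DBV ≤ 0.  Voxels with any non-positive or
non-finite fit-row signal are excluded (the log is undefined) rather than
floored, and counted in the fit report.

## [dHb] and error propagation

[dHb] = (R2′/DBV)/k with k = (4/3)·π·γ·Δχ0·κ·B0 ≈ 26.62 s⁻¹ per g/dL
(Δχ0 = 0.264×10⁻⁶, κ = 0.03 per g/dL, γ = 2.675×10⁸ rad s⁻¹ T⁻¹,
B0 = 3 T; all configurable).  The (4/3)π grouping is the standard
static-dephasing form δω = (4/3)πγΔχ0κ[dHb]B0 with R2′ = DBV·δω, chosen
for dimensional consistency.  [dHb] standard deviations use first-order
independent-ratio propagation,
σ_dHb = |dHb|·√((σ_R2′/R2′)² + (σ_DBV/DBV)²); whether the estimator
covariance between R2′ and DBV should enter is an open modelling choice —
the independent form is documented, validated against Monte Carlo within
5% for relative input errors ≤ 10%, and a Monte-Carlo mode can be built
from the same primitives.

## Preprocessing

Sub-slice collapse averages each group of four 1.25 mm sub-slices into one
5 mm slice.  Smoothing is strictly 2D in-plane (Gaussian, FWHM 2.3 mm
matching the in-plane resolution, reflection padding); slices are 5 mm
slabs and through-slice smoothing would mix them.  Brain masking replaces
an external brain-extraction tool with a threshold-and-largest-component
heuristic (fraction × 98th percentile, 26-connectivity, slice-wise hole
filling) — adequate because phantoms and pre-masked data are the intended
inputs.  Motion correction and registration are out of scope; inputs must
arrive co-registered and a supplied motion score is carried as metadata.

## ROIs

The presenting lesion: threshold ADC < 620×10⁻⁶ mm²/s, keep the largest
26-connected component, smooth the binary mask with a 1 mm Gaussian,
re-binarise at 0.5, re-cluster.  The 0.5 level (the half-maximum contour)
and the 26-connectivity are configurable because the original procedure
does not pin them down.  Automated largest-cluster selection stands in for
clinician-guided cluster identification.  Mirroring is a grid flip about
the centre plane of the midline axis in place of nonlinear template
registration; phantoms are generated midsagittally symmetric so the
convention is exact there.  Tissue outcomes are pure set algebra
(core = presenting ∩ final, growth = final \ presenting, contralateral =
mirror(presenting ∪ final)), so |core| + |growth| = |final| always.

## Statistics

Voxel level: values pooled across subjects per ROI without subject
weighting; Kruskal–Wallis (tie-corrected, χ² approximation) with
Tukey–Kramer post hoc comparisons computed on the pooled ranks — the
behaviour of common analysis environments after a rank test; raw-value
post hoc is available.  Patient level: one median per (subject, ROI) cell
gives an unreplicated two-way layout, so the ANOVA uses tissue outcome
plus subject block with no interaction term (not estimable without
replication), and the post hoc reuses the residual mean square and its
(k−1)(n−1) degrees of freedom.  Paired Cohen's d = mean(Δ)/SD(Δ); the
two-tailed paired t-test satisfies t = d·√n exactly.  Serial comparisons
normalise core/growth medians within scan by the contralateral median.
α = 0.05 throughout; medians use the mean-of-central-pair convention;
DBV is a fraction internally and percent in reports.

## Phantom generator

The phantom emulates the study conditions, not anatomy: an ellipsoidal
brain on a 96×96×9 grid (the acquisition matrix and slab count) with
2.3×2.3×5 mm voxels, two symmetric ventricles, and an ellipsoidal lesion
(final infarct ≈ 5.6×10³ voxels at the default size, with the core
ellipsoid strictly inside it) confined to one hemisphere so the mirrored
contralateral ROI is valid.  Default class parameters follow the reference
cohort's group means (core R2′ 5.4 s⁻¹, DBV 0.054; growth 4.5, 0.047;
contralateral 3.6, 0.041); S0/R2 are typical 3 T values and CSF is
FLAIR-attenuated with a long T2.  Core ADC (450×10⁻⁶ mm²/s) is the only
class below the lesion threshold, and ADC noise is off by default, so the
segmentation recovers the core geometry exactly and ROI tests are exact.
Noise is Gaussian magnitude noise with SD = (class spin-echo
amplitude)/SNR, default SNR 100; a Rician mode takes the magnitude of a
complex signal with that per-channel SD.  Gaussian is the default because
fitting operates on log-signals and the high-SNR magnitude limit keeps
the oracles tractable.  A CSF-nulling-failure confound can add a
decaying component to CSF voxels scaled by (1 − nulled fraction); its
decay rate is illustrative only, chosen to elevate apparent CSF R2′, the
direction of the real artefact.

What the phantom does **not** emulate: real anatomy, partial-volume
mixtures at class borders, spatially correlated noise, motion, or
macroscopic field gradients.  Passing tests therefore demonstrate
correctness of the estimation and statistics chain under the stated noise
model, not robustness to those real-data effects.

## Cohort generation and the power check

The cohort generator samples each subject's class truths as
class mean + shared subject effect + independent class residual.  The
between-subject SD (σ_b) and within-subject residual SD (σ_e) are
computed at run time from the bundled nine-patient medians table:
σ_e² is half the mean variance of the paired ROI differences and σ_b² is
the mean marginal variance minus σ_e², separately per parameter.  The
printed R2′, DBV and [dHb] columns of that table are mutually
inconsistent under the ratio relation (a median of voxel-wise ratios is
not the ratio of medians), so the generator samples (R2′, [dHb]) and
derives DBV = R2′/(k·[dHb]): the [dHb] class structure — the quantity the
patient-level comparison tests — is then matched to the reference cohort
by construction.  Values are floored at small physical minima (R2′ ≥ 0.5
s⁻¹, [dHb] ≥ 0.3 g/dL, CBF ≥ 2, DBV clipped to [0.005, 0.25]).

The power check simulates 100 independent nine-subject cohorts on a
reduced 48×48×9 grid (the geometry scales with the grid; core ≈ 390
voxels) at SNR 100, runs the full fit → ROI → median → two-way-ANOVA
chain on each, and reports the fraction with a significant [dHb] tissue
effect.  The reduced grid keeps the whole check under a minute; ROI
medians over hundreds of voxels are precise enough that the detection
rate is governed by the designed between-/within-subject structure, not
by fit noise.

## Numerical notes and limitations

* All solves are closed-form linear algebra; a rank-deficient design or a
  non-finite log-signal marks the voxel missing rather than aborting the
  map.  With exactly 3 fit rows the residual degrees of freedom vanish
  and std maps are undefined (NaN).
* Noise-free simulate → fit round trips recover parameters to ~1e-13
  relative error (float64); the tested contract is 1e-9.
* Binary-mask smoothing at σ = 1 mm on 2.3 mm voxels is sub-voxel, so
  re-binarisation at 0.5 preserves compact lesion shapes exactly; much
  larger σ/voxel ratios would erode convex corners.
* Grid mismatches between paired inputs are always errors; nothing is
  resampled silently.
* OEF and CMRO₂ are deliberately not computed (they require haematocrit
  or additional modelling); the short-τ regime, DICOM ingestion and any
  registration are likewise out of scope.
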
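# Methods

## The forward model and its inversion

A voxel's contrast enhancement is modelled as the convolution of the
arterial input function (AIF) with the voxel's scaled residue function,

    F_v(t) = CBF · (AIF ⊛ F_r)(t),

discretised on the acquisition grid (frame interval Δt) as the causal sum
`F_v(t_j) = Δt · CBF · Σ_{i≤j} AIF(t_i) F_r(t_j − t_i)`. The residue
function F_r — the fraction of tracer still intravascular t seconds after
an idealised impulse input — is mono-exponential `exp(−t/MTT)` in the
phantom (a box-car is available for sensitivity checks), shifted by the
voxel's bolus arrival delay.

Deconvolution writes the sum as a matrix equation `V = A r` and inverts it
by SVD with singular-value truncation:

* **sSVD** — A is the N×N lower-triangular Toeplitz matrix
  `A[i,j] = Δt·AIF[i−j]` (j ≤ i). Exact when tissue and AIF share an
  arrival time, but the causal structure penalises arrival-time mismatch.
* **bcSVD** — the AIF column is zero-padded to length 2N and wrapped into
  a 2N×2N circulant, `ā[i,j] = col[(i−j) mod 2N]`, whose top-left N×N
  block is exactly A. Time-shift invariance makes the inversion
  delay-insensitive: an arrival offset moves the recovered residue peak
  (including to negative lags, which wrap past index N) instead of
  corrupting its height.

Reciprocals of singular values below `truncation_fraction × max(S)` are
zeroed. The default fraction is **0.10**, the usual convention for
regularising against measurement noise; noiseless analyses (and the
round-trip identity `A·r = v`) use a fraction of 0, keeping every
numerically nonzero singular value. Raising the fraction can only degrade
reconvolution fidelity, never improve it.

## Perfusion parameters

From the recovered CBF-scaled residue r:

* **CBF** = max(r) (internal flow units, 1/s scale).
* **Tmax** = time of max(r); in bcSVD mode an argmax at index ≥ N is a
  negative lag and is clamped to 0 s, since negative tissue delays are
  non-physiological.
* **CBV** = ∫tissue / ∫AIF (trapezoid, baseline-subtracted curves),
  unitless.
* **MTT** — the residue transit time: the trapezoidal area of the decay
  segment that starts at the residue maximum (read circularly in bcSVD
  mode), divided by the maximum. At Δt = 1.5 s the alternative
  central-volume ratio CBV/CBF inherits the rectangle-rule bias of the
  discrete forward sum — roughly Δt/(2·MTT), i.e. ~19% at MTT 4 s — while
  the transit-time estimator stays within ~1%; the two agree as Δt → 0.
  `mtt_from="cvt"` selects the ratio if wanted.

Physiological display constants (hematocrit, tissue density) are not
applied: they cancel in rCBF and do not move Tmax, so the reported volumes
are unaffected. A scaling hook exists where absolute units are needed.

Curves are baseline-subtracted (mean of the first `baseline_frames = 4`
frames, ≈6 s of pre-contrast signal) before any matrix construction;
deconvolving raw HU offsets is meaningless.

## Volumes

* **Volume F**: masked voxels with rCBF strictly < 0.30, × voxel volume.
* **Volume T**: masked voxels with Tmax strictly > 6 s, × voxel volume.

Strict inequalities are deliberate at both thresholds. Volumes are
reported as integer mL (round half away from zero) with the exact value
retained. The rCBF denominator defaults to the median CBF over masked
voxels with Tmax ≤ 6 s (`global_median`) — robust and meaningful on the
phantom; a `contralateral` mode (opposite-hemisphere median across the
mid-sagittal plane) is provided for anatomical data, and `explicit_value`
for controlled experiments.

## Curve validity: rules, classifiers, pair selection

Feature set per curve: baseline, peak enhancement (max − baseline), time
to peak, FWHM (linear interpolation at half enhancement), local-maxima
count at a prominence floor of 0.1 × enhancement, decay fraction (share of
the enhancement shed within 15 s after the peak), and AUC.

Rule set (all failures reported, not just the first):

| rule        | condition                          | default      |
|-------------|------------------------------------|--------------|
| peak        | enhancement > threshold            | 80 HU        |
| single_peak | exactly one prominent local max    | —            |
| sharpness   | FWHM ≤ cap                         | AIF 12 s, VOF 20 s |
| decay       | decay fraction ≥ floor             | 0.40         |
| early_peak  | AIF peak ≤ fraction of scan length | 2/3          |

The 80 HU rule is applied to baseline-subtracted enhancement: absolute HU
depends on the tissue baseline under the ROI, which would make the rule
scanner- and placement-dependent (an absolute mode is available). The
qualitative rules ("sharp", "fast attenuation", "early") needed numeric
form; the defaults above were fixed once from the phantom's physiological
ranges and are all configurable.

The trainable layer holds sklearn-style estimators: one gradient-boosted
IV classifier per vessel kind (XGBoost; Gaussian-noise augmentation with
content-derived per-curve seeds), and an MLP LV classifier separating
arterial from venous shapes (veins peak later and higher). Training
canonicalises the row order of the feature matrix, so fitted models are
invariant to the order curves are supplied in; all randomness is seeded.
Decision threshold is 0.5 for both. The hyperparameters reported for the
original clinical tuning are kept as a config preset
(`CLINICAL_IV_PRESET`) rather than defaults, since they were tuned to a
different data distribution.

Pair selection keeps AIF candidates that pass the rules, the AIF-IV model
and are called arterial by LV (this last requirement is what rules out
vein-with-vein or artery-with-artery pairs), and symmetrically for VOF;
surviving cross pairs must show a venous peak 3–12 s after the arterial
peak. AIF rank: earlier peak, then higher enhancement; VOF rank: higher
enhancement. No survivor ⇒ `invalid curve` warning — a result, not an
exception, and the CLI exits 0 with it.

## ROI correction

"Within an eight-voxel radius" is read as a 3D Euclidean ball of radius 8
in voxel units (correction is observed in-plane and across slices); a
Chebyshev box is available via `metric="chebyshev"`. The selected voxel
maximises baseline-subtracted trapezoidal AUC; raw-HU AUC would be
dominated by the tissue baseline rather than the bolus. Ties break to the
voxel nearest the original landmark, then lexicographically, so the search
is fully deterministic. Enlarging the radius can only raise the achieved
AUC.

The heuristic localiser (a classical stand-in for a learned landmark
model, so the CLI can run fully automatically) ranks masked voxels by AUC
and splits arterial from venous candidates at the masked median time to
peak, enforcing ≥ 3 voxels pairwise separation.

## Preprocessing

Motion correction is an exhaustive integer-translation search (±3 voxels
per axis) maximising Pearson correlation with the reference frame
(default: first frame), with ties to the smaller shift — deterministic,
idempotent, and sufficient for translational motion; a finer registrar can
be plugged in where rotations matter. A constant reference frame (e.g. a
zero-baseline phantom) skips correction with a warning. Out-of-field
voxels take the nearest edge value. The temporal MIP is max − min over
time per voxel; z-score normalisation uses brain-mask statistics when a
mask is given, whole-volume otherwise (the masking convention is a choice;
both are exposed).

## The phantom: what it emulates, and what it does not

The generator emulates a 30-frame, Δt = 1.5 s (45 s) acquisition on a
64×64×8 grid at 1×1×4 mm (a desk-scale stand-in for clinical 512×512×27;
full-size generation is supported). The arterial bolus is a peak-normalised
gamma-variate (amplitude 150 HU, onset 6 s, shape α = 2, scale β = 1.5 s;
analytic peak at t0 + αβ = 9 s); the venous curve is the arterial one
delayed 4.5 s, dispersed (β × 1.3) and amplified (× 1.5), placing the
arteriovenous peak delay inside the 3–12 s window. Tissue classes: normal
(CBF 0.04 s⁻¹, MTT 4 s), core (CBF at 20% of normal, MTT 8 s) and
penumbra (CBF at 50%, MTT 6 s, arrival delay 7.5 s), painted into disjoint
boxes of exactly 3000 and 10000 voxels — 12.0 and 40.0 mL. Five arterial
and three venous single-voxel vessels are planted in normal tissue,
pairwise ≥ 3 voxels apart. Noise is additive i.i.d. Gaussian in HU
(default 0; 2 HU is the "clean but noisy" setting, ≥ 15 HU produces
jagged curves); corruption modes (multi-peak, jagged, truncated bolus,
flat) reproduce the curve pathologies that should trip the validity layer.

What it deliberately does not model: anatomy (no skull, no hemispheric
asymmetry), scanner physics (beam hardening, photon noise statistics),
contrast pharmacokinetics beyond the gamma-variate, recirculation, partial
volume, or rotational motion. Passing tests therefore demonstrate the
correctness of the algorithms under their stated model — not clinical
performance, which requires clinical data.

## Statistics

Lin's concordance correlation coefficient uses population (1/n) moments;
`ddof=1` is available and differs only when means differ. Exactly
identical sequences short-circuit to CCC = 1. Bootstrap CIs are percentile
(2.5/97.5 over paired resamples), seeded. The two-proportion z-test uses
the pooled standard error (so z² equals the uncorrected chi-square), and
the 2×2 log-odds contrast is the difference of cell log-odds with no
continuity correction — the value a single-predictor logistic model (or
GEE with independent working correlation) estimates for a method effect.
Landmark distances support in-plane (2d) and full 3d modes; 3d is the
default because slices are anisotropic.

## Delay-robustness experiment design

The claim that motivates the circulant construction is insensitivity to
arrival-time variation. Two regimes behave differently and the evaluation
covers both:

* **Tissue later than AIF** (positive lag): with this phantom's AIF —
  zero for the four pre-contrast frames — the Toeplitz system is
  rank-deficient with room to represent positive shifts causally, so sSVD
  shows no systematic penalty; bcSVD reads the planted delay back as Tmax
  within one frame, which is the clinically used quantity. Its CBF error
  is delay-*independent* (a flat regularisation bias), while sSVD's varies
  with delay.
* **Tissue earlier than the measured AIF** (negative lag — an AIF sampled
  at a late-arriving vessel): the causal system cannot represent the
  required negative shift at all. Measured on the phantom, sSVD CBF errors
  reach 60–170% while bcSVD stays at its flat 7–20% regularisation bias
  and locates the (negative) lag correctly. The voxelwise
  bcSVD-beats-sSVD comparison is run in this regime, at the default 0.10
  truncation with 2 HU noise.

## Problem sizes and runtime

Tests and the acceptance script run the 64×64×8×30 phantom (28 800 brain
voxels), 400-curve training sets with 100-curve held-out sets, and
4 × 2 whole-brain map computations for the delay experiment; the whole
acceptance script completes in a few seconds on one CPU because the
truncated pseudo-inverse is built once per AIF and applied to all voxels
as a single matrix product.

## Known limitations

* CBF/CBV are in internal units; absolute quantification (mL/100 g/min)
  would need hematocrit/density scaling and a calibrated AIF.
* The integer-translation motion model ignores rotation.
* The heuristic localiser assumes vessels dominate the AUC ranking; on
  anatomical data a trained localiser should replace it (the pipeline
  accepts any landmark provider).
* The rule thresholds beyond 80 HU and 3–12 s are package conventions,
  quantified once; clinical deployment would calibrate them.
* `global_median` rCBF referencing assumes most masked tissue is normal;
  extensive bilateral disease would bias it (use `contralateral` or an
  explicit reference).
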
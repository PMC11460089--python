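# Methods

This note documents the models, numerical choices and limitations behind
`dlifkit`, module by module.

## Temporal sampling and units

Time zero is the injection start; frames are contiguous `(start, duration)`
pairs and every curve value is the duration-weighted mean over its frame,
attached to the frame midpoint.  The default acquisition is 24×5 s, 9×20 s
and 11×300 s (60 min); truncating at 45 min keeps 41 frames.  All activity
values are SUV [g/ml] after ingestion — raw kBq/ml is accepted only at the
`suv_normalize` boundary, where SUV = concentration / (injected dose / body
weight).  Voxel spacing defaults to 0.5 mm isotropic (typical of
small-animal PET reconstructions); it is configurable because acquisition
protocols vary.  Dynamic images are `(T, X, Y, Z)` in memory and standard
`(X, Y, Z, T)` NIfTI on disk; the center crop rounds offsets down, so
128×92×92 → 64×48×48 uses offsets (32, 22, 22).

## Kinetic forward model

The arterial input is the Feng bolus form
`Cp(t') = (A1·t' − A2 − A3)e^{λ1 t'} + A2 e^{λ2 t'} + A3 e^{λ3 t'}`,
`t' = t − delay`, with λ1 ≤ λ2 ≤ λ3 < 0 enforced structurally.  The default
parameters (A1 = 200 SUV/min, A2 = 3, A3 = 1.2 SUV, λ = −4, −0.25,
−0.015 min⁻¹, delay 0.25 min) give a ~21 SUV peak near 30 s and a tail near
0.6 SUV at 45 min, typical of a 30-s bolus in a mouse.

Tissue curves come from the irreversible two-tissue compartment model
evaluated as `Ct = (1 − vB)·h ∗ Cp + vB·Cp` with impulse response
`h(t) = K1/(k2+k3)·[k3 + k2 e^{−(k2+k3)t}]` (h = K1 when k2+k3 = 0, the
pure-accumulation limit).  The convolution uses a uniform 0.01-min internal
grid with a trapezoid end-correction, which makes the constant-input case
exact and matches a stiff ODE integration of the same system to better than
0.5% away from the bolus onset; the vB·Cp term is evaluated analytically at
the requested times rather than interpolated.

## Patlak analysis

The transformed coordinates are y = Ct/Cp and x = (∫₀ᵗ Cp dτ)/Cp, with the
running integral computed by trapezoid over frame midpoints plus an initial
triangle from (0, 0) to the first midpoint — accurate for 5-s early frames
and fully deterministic.  The line is fitted by unweighted ordinary least
squares over frames with midpoint ≥ t* (default 10 min, configurable, since
published protocols vary) that also satisfy Cp > 1% of the Cp peak (the
`cp_floor` guard against late-frame division blow-ups).  Regional and
voxelwise fits share one vectorized OLS code path; voxels outside the mask
or with no signal over the retained frames are NaN.

Known, quantified biases of the estimator (not implementation defects): the
slope of a voxel containing blood volume is (1 − vB)·Ki, not Ki; a
bi-exponential input tail tilts the line slightly for tissues with small
k2+k3; and frame discretization contributes ~1%.  With the phantom defaults
below these add up to ≤ ~5% per organ.

## Digital phantom

The phantom emulates a dynamic FDG mouse acquisition: ellipsoidal organs
(whole-body, liver, myocardial shell with an enclosed blood cavity, vena
cava, brain, bladder) rasterized on a 64×48×48 grid at 0.5 mm, one shared
input function, organ-specific kinetics, per-frame Gaussian smoothing, and
additive Gaussian noise with SD `noise_scale·sqrt(value/duration)` clipped
at zero — a reconstructed-PET-like count-statistics proxy that makes 5-s
frames visibly noisier than 300-s frames.  `noise_scale` defaults to 0.15
(≈ unit-relative noise at the blood peak in 5-s frames, < 1% in late 300-s
frames); no published noise level exists for this setting, so the value is
a documented choice exercised over a range in tests.

Default organ kinetics live in `data/organ_kinetics.yaml`.  They are
plausible fasted-mouse FDG fixture values — myocardium Ki ≈ 0.124 and brain
Ki ≈ 0.018 ml/g/min, matching the magnitudes seen in regional influx
studies — and are deliberately placed inside the validity regime of Patlak
analysis (k2+k3 ≥ ~0.6 min⁻¹, vB ≤ 0.03) so that graphical-analysis
recovery against ground truth is a meaningful check.  They are simulation
inputs, not measured claims.  The geometry gives the blood structures
realistic diastolic-scale sizes (2.2–2.4 mm LV cavity semi-axes, 1.25 mm
vena-cava radius) relative to the default 1.2 mm FWHM PSF of a
reconstructed small-animal image; much smaller structures would be
dominated by partial-volume spill, which the PSF parameter lets you study
explicitly.  The injection is modelled implicitly through the input
function's delay and upslope; infusion-pump dynamics are not simulated.

`sample_population` draws per-animal lognormal multipliers (unit mean):
amplitude CV 0.2 shared across A1–A3, decay CV 0.1 per eigenvalue, K1 CV
0.2, and k2/k3 at half the kinetics CV (efflux and trapping rates vary less
across animals than delivery), plus dose CV 0.17 and weight CV 0.15 for the
metadata.  The resulting ground-truth Ki spread per organ is ~20–25% CV.
An `uds_mode` toggle scales myocardial K1 up by 1.5 to mimic an unfasted
cohort.  All randomness flows through explicit seeds; identical spec + seed
is bit-identical.

What the phantom does **not** model: anatomical realism, scanner physics
(randoms, scatter, dead time, attenuation), motion, spatially correlated
reconstruction noise, or time-shifted injections.  Tests that pass on it
therefore validate the estimators and the pipeline plumbing, not
performance on real data.

## VOI delineation and the IDIF

All rules are deterministic given image + configuration: the vena cava is a
0.6 mm-radius sphere at the argmax voxel of the 20–60 s mean image (ties
break on the lowest flat index); the myocardium is a threshold VOI at 50%
(configurable within the conventional 40–60% band) of the
background-corrected maximum inside a heart search box (bounding box of the
hottest 0.1% voxels of the 25–45 min static image, dilated by 3 voxels);
the left ventricle is the cavity enclosed by the myocardium mask —
morphological fill minus the mask — optionally reduced to its core by a
wall margin (default 1.5 mm ≈ 1.25 PSF FWHM) because spill-in from the hot
wall decays with distance on the PSF scale.  The brain sphere (2 mm) is
placed at the brain centroid in phantoms; visual placement on real data is
out of scope.

The IDIF is a Feng-model fit to early vena-cava points (midpoint ≤ 90 s,
covering the bolus peak) plus late left-ventricle points (≥ 10 min, the
clean tail).  Two deliberate numerical choices: the model is
*frame-averaged* before computing residuals, so it is consistent with what
a PET frame measures (fitting the instantaneous curve to frame means biases
the peak); and the eigenvalue ordering is enforced through a
log-difference parameterization rather than constraints, with two start
points and the lower-cost valid solution kept.  A fit producing a negative
curve is rejected; non-convergence from all starts raises a fit error with
diagnostics.

## Network

The architecture follows the feature ladder 64×48×48 → 32×24×24 → 16×12×12
→ 8×6×6 → 4×3×3 with filter counts 2, 4, 8, 16 (the doubling rule fixes the
first layer at 2 given the final 16), 3×3×3 same-padded kernels and 2×2×2
pooling — the unique standard choice that realizes a 4×3×3 endpoint from a
64×48×48 input.  The per-frame dense reduction is 576 → 128 → 32 (hidden
width 128 chosen as the geometric middle ground); the temporal stage is a
same-padded 1-D convolution with 16 filters and kernel 3; the head maps
16·41 → 41.  The output rectifier is softplus by default — activity
concentrations are non-negative, and the smooth rectifier avoids dead
output units under MSE — with plain ReLU available by configuration.
Initialization is He-normal from an explicit seed; batch size defaults to 4
(matching the granularity of 4-sample test folds); batch-norm momentum is
0.1.  Input volumes enter un-normalized: the first batch-norm layer absorbs
the SUV scale.

The engine is pure numpy with explicit backpropagation (convolutions via
27-offset slice accumulation, pooling via argmax routing), verified against
central finite differences in the test suite, and fully deterministic under
fixed seeds.  Training, 17-fold-style cross-validation (seeded permutation,
remainders spread one per fold) and multi-seed ensembles (per-run curves,
mean, mean ± z·SD band) are thin loops over it.

A reduced profile (`SCALED_ARCH`: 16×16×16 input, embedding 64 → 32) ships
for CPU-scale experiments: with 32 coarse-phantom training scans and 50
epochs it reaches held-out predicted-vs-true curve correlations ≈ 0.99 in
a few minutes per run.  Problem sizes in the test suite and the acceptance
script use this profile; the full-size architecture is exercised
structurally (shapes, parameter sizes) rather than trained.

## Evaluation statistics

Orthogonal (Deming) regression with error-variance ratio λ = 1 (exposed in
the signature; no basis for another value) via the closed-form slope on
centered second moments; Pearson r on the compared pairs; the signed
average error mean((ref − est)/ref)·100, so over-estimation gives negative
error; a two-sided paired t-test at α = 0.05 with zero-variance differences
flagged degenerate (P reported as 1) rather than raised; Q-Q points at
plotting positions (i − 0.5)/n.  The cohort report computes per-scan and
pooled curve fits, voxelwise-influx fits under both input functions, flags
scans with voxelwise slope outside 1 ± 0.4, and tabulates regional Ki as
mean ± SD **and** mean ± t-based 95% CI half-width (both emitted because
"mean ± 1 confidence interval" phrasing in the literature is ambiguous).
Scatter plots subsample to 1000 seeded points for display; statistics
always use all points.

## Degenerate inputs and tie rules

Empty schedules are valid (zero frames); Patlak needs ≥ 2 usable points and
raises a fit error otherwise; Deming regression raises on constant x or a
zero cross-moment with equal variances; argmax ties in peak-voxel search
and max-pooling resolve to the first (lowest-index) occurrence; an LV
margin that would empty the cavity falls back to the deepest cavity voxels.

## Known limitations

- The phantom's simplifications above; in particular, noise is independent
  across voxels, while reconstructed PET noise is spatially correlated, so
  VOI-mean noise levels are optimistic.
- Patlak results carry the (1 − vB) and finite-t* biases described above;
  no partial-volume or metabolite correction is implemented.
- Full nonlinear compartment fitting of measured data and reversible
  (k4 > 0) models are out of scope.
- The network engine targets CPU-scale experiments; it is not optimized for
  GPU-scale training, and full-size (64×48×48) training runs, while
  functional, are slow.
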
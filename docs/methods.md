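# Methods

## Signal model and ΔR2* conversion

A T2*-weighted gradient-echo EPI signal under a susceptibility contrast
agent obeys SI(t) = SI_0 · exp(−TE · ΔR2*(t)) with ΔR2* proportional to
local agent concentration.  The package inverts this as

    ΔR2*(t) = −ln(SI_t / SI_0) / TE      [1/s]

so that the bolus passage is a positive peak (the tracer-kinetic
convention; the same relation is sometimes printed without the minus and
with the ratio inverted).  SI_0 is the arithmetic mean of the first
`baseline_frames` frames.  The baseline window (default 200 frames) and
the bolus start frame (default 240) are independent parameters: SI_0 may
legitimately use fewer frames than the acquisition's full pre-injection
period.  TE is carried in seconds internally; the CLI accepts
milliseconds through an explicit `--te-ms` flag.

Voxels with any non-positive intensity, or a non-positive baseline, are
flagged *degenerate* and excluded from maps rather than raising: a
voxel-wise pipeline must not abort on single bad voxels.

## The bolus mixture model

Each voxel's ΔR2* series is fitted with the sum of

* a **gamma-variate first pass** g(t) = k (t−t0)^α e^{−(t−t0)/β} for
  t > t0 (0 before), the classical bolus-tracking form — unimodal with
  peak at t0 + αβ; and
* a **logistic recirculation plateau** h(t) = s / (1 + e^{−r(t−tc)}).

In small animals the recirculation time is a few seconds, so second and
later passes are not resolved as peaks; they accumulate as a monotone
plateau below the tissue response.  Ignoring it inflates the area under
the curve and hence rCBV.  The "linear mixture" is the unweighted sum;
the mixing coefficients are absorbed into the amplitudes k and s, and
all seven parameters are fitted jointly per voxel.

### Optimisation

Fitting is damped least squares (MINPACK Levenberg–Marquardt via
`scipy.optimize.least_squares(method="lm")`) with an analytic Jacobian.
Positivity of k, α, β, s, r is enforced by optimising their logarithms —
box constraints by smooth reparameterisation, which keeps the problem
unconstrained for LM.  The fit uses **all** frames by default; the
baseline frames anchor the model's zero level (`fit_from_frame`
restricts the window when desired).

Two further choices matter and were made after observing the fit's
failure modes on synthetic data:

1. **Sigmoid centre constraint.**  The centre is parameterised as
   tc = t0 + αβ + e^θ, i.e. strictly after the first-pass peak.
   Physically, recirculated agent cannot precede the first pass; without
   the constraint the optimiser can park a step-like sigmoid on the
   bolus rise itself and trade mass with the gamma tail, which biases
   rCBV low by ~10% at realistic noise.  The constraint removes this
   class of degenerate optima without restricting plausible solutions.
2. **Two-stage initialisation.**  A heuristic guess (bolus arrival from
   the 10%-of-peak run, α and β from the peak delay d and half-maximum
   width w via the Gaussian approximation FWHM ≈ 2.355 √α β, plateau
   from the late-frame mean, r = 4/width) seeds a gamma-only fit on the
   first-pass window (through the peak plus one width, where
   recirculation is negligible); its result seeds the joint
   seven-parameter fit.  Single-stage fitting from the heuristic guess
   alone lands in inferior local minima on ~30% of noisy voxels.

Convergence: relative RSS change below `ftol` = 1e−6 (or step size below
`xtol` = 1e−8), at most 200 iterations.  The 1e−6 default reflects that
with noise-dominated residuals LM can crawl along a flat valley at
per-step relative improvements ~1e−7 that are far below any practical
relevance; noiseless fits still terminate at machine-precision RSS
(~1e−25) because their per-step reduction stays large until the floor.
Optimizer exceptions are caught and reported as `valid=False` with the
best iterate.  Optional seeded multi-start restarts exist but default to
off — the two-stage initialisation made them unnecessary on the phantom.

### Bolus detection

A voxel is fitted only if its global ΔR2* maximum is positive, occurs at
or after the bolus start frame, and exceeds `noise_floor` (default 3)
times the baseline ΔR2* standard deviation.  With ~600 post-baseline
frames, the maximum of pure noise exceeds 3σ often, so out-of-brain
voxels are only partially rejected by this floor — a brain mask remains
the caller's responsibility, exactly as in scanner practice.  Spurious
background fits that do pass have rCBV far below tissue level.

## Perfusion metrics

* **rCBV** = ∫ g = k β^{α+1} Γ(α+1), evaluated in log space.  The
  *fitted gamma* is integrated, not the raw curve: the mixture model
  exists precisely to exclude recirculation from the volume estimate.
* **MTT** = FWHM of the fitted gamma, found by Brent root-finding on the
  log-shape a·u − e^u (u = ln x) on both sides of the peak; log space
  keeps the left crossing solvable for very small α.  Proportional to
  the true mean transit time, not an absolute transit time.
* **rCBF** = rCBV / MTT with MTT in seconds; the identity
  rCBF · MTT = rCBV holds to machine precision by construction.
* **TTP** = argmax frame of the *raw* ΔR2* series minus the index of the
  last baseline frame (`bolus_start_frame − 1`; all indices 0-based).
* **BAT** = first frame of the contiguous ≥10%-of-peak run that ends at
  the argmax.  On clean or monotone data this equals the literal "first
  frame reaching 10% of the maximum"; anchoring the search at the peak
  makes it robust to isolated baseline noise excursions, which at 1%
  signal noise (ΔR2* noise ≈ 2 s⁻¹ against a 20 s⁻¹ peak) would
  otherwise place the arrival inside the baseline for most voxels.

Maps carry NaN at invalid voxels; the validity mask is written as its
own volume, and a JSON sidecar records acquisition parameters, fit
counts and the package version.

## Group statistics

* **Whole-brain scalar test**: mean of each metric over valid in-mask
  voxels per subject; the two groups are compared by the difference of
  group means under label permutation — equivalent to permuting the
  group factor in a two-group linear model.
* **Voxel-wise test**: pooled-variance two-sample t per voxel;
  uncorrected p from each voxel's permutation distribution and
  family-wise-error corrected p from the distribution of the maximal |t|
  over the mask (max-statistic correction; cluster enhancement methods
  are deliberately out of scope).

When the number of distinct labelings C(n, n_A) is within the
permutation budget, the null is enumerated exactly and p = #{|T| ≥
|T_obs|}/C(n, n_A) (the observed labeling is included, so p > 0 and is a
rational with the enumeration size as denominator).  Otherwise labelings
are sampled with a seeded generator and the add-one estimate
p = (1 + #{|T_perm| ≥ |T_obs|})/(1 + n_perm) is used.  Comparisons use a
1e−12 relative tie tolerance so that exact mirror labelings are not lost
to floating-point summation order; p-values are then invariant under
reordering subjects within groups, as exchangeability requires.

## The digital phantom

`PhantomSpec` describes geometry, acquisition, tissue classes, noise and
seed; everything downstream is a deterministic function of it.

* **Acquisition defaults**: TE 5 ms, TR 1 s, 850 frames, SI_0 from the
  first 200 frames, bolus start at frame 240 — a realistic rodent EPI
  bolus-tracking protocol (14 min scan, 4 min baseline).
* **Geometry**: a 50×50×16 grid holding an ellipsoidal brain (92% of the
  half-extent per axis); an inner in-plane column of half the normalised
  radius is labelled "striatum" (deep gray), the remainder "cortex".
  The column construction keeps both classes present on thin test grids.
* **Class responses** (chosen to be physiologically plausible at this
  time resolution, amplitudes giving a 7–10% peak signal dip at TE 5 ms):

  | class | t0 (s) | α | β (s) | peak (s⁻¹) | s (s⁻¹) | tc (s) | r (s⁻¹) | SI_0 |
  |-------|-------|---|-------|-----------|---------|--------|---------|------|
  | cortex | 242 | 3.0 | 8.0 | 20 | 3.0 | 292 | 0.30 | 800 |
  | striatum | 246 | 2.5 | 7.0 | 14 | 2.2 | 290 | 0.30 | 900 |

  Arrival times are staggered across classes within the ~8-volume
  injection interval so the BAT map has spatial structure.  The deep
  gray first pass is slightly narrower than the cortical one (transit in
  deep gray is not longer than cortical), and the recirculation plateau
  centres ~26 s after each class's first-pass peak — recirculation lag
  is a systemic property and should not vary across tissue.  The
  recirculation sigmoids are steep/late enough that their tails in the
  SI_0 window are < 1e−11 of the peak; a slowly-rising logistic that
  leaks into the baseline would make exact round-trip recovery
  impossible by construction (the logistic is nowhere exactly zero).
* **Noise** is additive Gaussian on the *signal* (optionally Rician),
  with standard deviation expressed as a fraction of each class's SI_0
  (default 1%), matching magnitude-MRI physics and exercising the
  log-transform's noise propagation: baseline ΔR2* noise has
  sd ≈ sd_signal/(SI_0·TE).
* **Ground truth** maps are analytic: rCBV/MTT/rCBF from the closed
  forms on the class parameters; TTP/BAT by applying the frame-index
  definitions to the noise-free class curve on the acquisition grid.
* **Group studies**: `generate_group_study` applies multiplicative
  effects to chosen class parameters of group B (e.g. scaling t0 delays
  the bolus and lengthens TTP) with per-subject independent seeded
  noise.

### What the phantom does and does not emulate

It reproduces the acquisition timing, signal physics of the
log-transform, tissue heterogeneity, staggered arrival, recirculation,
baseline-only background and sensor noise.  It does **not** model
vascular anatomy, partial-volume mixing, motion, EPI ghosting or
distortion, T1 leakage, or arterial input variability.  Passing recovery
tests therefore validates the *estimation machinery* under the stated
signal model, not robustness to acquisition artefacts — on real data,
motion correction and brain extraction must happen upstream.

## Problem sizes used in the shipped checks

The full-resolution noiseless recovery check runs the complete
50×50×16×850 phantom (~16k voxel fits, about two minutes).  Noisy
recovery uses an 8×8×2 sub-grid at the full 850-frame time axis; the
acceptance script uses 10×10×4.  Null calibration uses 100–200 replicate
12-subject studies on 32-voxel grids with 500 permutations each.  These
sizes give stable medians and rates while keeping the whole suite fast
on a single CPU.

## Known limitations

* rCBV/MTT/rCBF are relative quantities; no arterial input function is
  estimated, so absolute quantification (ml/100 g/min) is out of scope.
* TTP and BAT operate on the raw series and are frame-quantised; for
  curves that are nearly flat around their maximum, the raw argmax is
  intrinsically unstable under noise (jitter of several frames), a
  property of the definition rather than the implementation.  The fitted
  curve's peak time (t0 + αβ) is available from the fit for users who
  prefer a model-based TTP.
* At 5% signal noise (per-frame peak SNR ≈ 2) the voxel-wise fit
  degrades sharply — many voxels fail validity or collapse to narrow
  spike solutions; medians are no longer trustworthy.  This is the
  expected behaviour of voxel-wise nonlinear fitting at that SNR, and
  the recovery tests assert only monotone degradation there.
* The scalar permutation test assumes exchangeability under the null;
  covariate adjustment and repeated-measures designs are not supported.
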
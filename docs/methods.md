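# Methods

This note documents the models, numerical choices and limitations behind
`petvoi`. It is written for a reader who wants to know exactly what the
package computes and what passing its tests does and does not demonstrate.

## Kinetic model and Logan analysis

**Forward model (phantom only).** Synthetic voxel time-activity curves
(TACs) follow the simplified reference tissue model (SRTM):

    C_T(t) = R1·C_R(t) + k2·(1 − R1/DVR) ∫₀ᵗ C_R(u) e^{−(k2/DVR)(t−u)} du

with delivery ratio R1 (unitless), efflux rate k2 (1/min) and distribution
volume ratio DVR = BP + 1 ≥ 1. SRTM was chosen as the generator because its
DVR parameter is precisely the quantity reference-region Logan analysis
estimates, giving an exact ground truth for parameter-recovery tests. The
reference input C_R is an analytic biexponential rise-and-decay curve,
peak-normalized, with the peak placed at 300 s and shape rates (0.02,
0.5)/min. These input-curve constants and the defaults R1 = 1, k2 = 0.1/min
are generic placeholders with realistic orders of magnitude, not measured
tracer kinetics; they are exposed in the API and can be replaced wholesale.

The convolution is evaluated on a fine grid (default 0.5 s, ≤ 1 s enforced)
with an exact-decay, trapezoidal-update first-order recursion, and frame
values are duration-weighted averages over each frame (not instantaneous
samples) — matching how a scanner integrates counts. Halving the grid step
changes frame values by < 0.1% (tested).

**Logan fit.** For each target/reference TAC pair the package forms
cumulative trapezoidal integrals over frame midpoints, anchored at (0, 0),
and regresses y = ∫C_T/C_T on x = ∫C_R/C_T by ordinary least squares over
the frames whose *midpoint* is ≥ `t_start` (default 900 s; for the default
schedule the same frames, 11–18, are selected whether one thresholds
midpoints or frame starts). The slope is the DVR estimate; the intercept is
reported in minutes. No k2′ correction term is applied to the reference
input — a known source of small negative bias (the noiseless grid
DVR ∈ {1.0, 1.2, 1.5, 2.0} recovers within 1.2%, tested at 5%). Voxels with
a non-positive value in any used frame cannot enter the log-domain fit and
are flagged NaN (counted in the log) rather than silently zeroed; whether
the historical analysis sampled midpoints or frame ends is not documented
anywhere we know of, so midpoints were chosen and fixed.

**Perfusion sum.** The early-frame image is the duration-weighted sum of
all frames fully contained in a window; the default window [0, 360 s)
selects exactly frames 1–7 of the 18-frame schedule (six 30 s, four 180 s,
five 600 s, three 1200 s frames; 7500 s total).

## VOI geometry and normalization metrics

* Surface-drawn ROIs become 3D VOIs by including every voxel whose center
  lies within a Euclidean distance (default 9 mm, measured in mm so
  anisotropic voxels are handled correctly) of a drawn voxel center,
  optionally intersected with a restriction mask. Computed with an exact
  Euclidean distance transform; validated against brute-force lattice
  enumeration. Geodesic (along-surface) distance is *not* used.
* Deformations are dense per-voxel displacement fields in mm, applied by
  pull-back (backward) resampling: nearest-neighbour for labels/VOIs,
  trilinear for DVR images; out-of-grid lookups take background 0.
  Inverses are computed by fixed-point iteration v = −u∘(id+v), which
  converges quickly for the smooth, small-amplitude fields generated here.
* Dice overlap κ = 2·#(A∩B)/(#A+#B) on bilateral structures; undefined
  (error) only when both masks are empty.
* "Variance reduction" is defined as 1 − mean_var(B)/mean_var(A), where
  mean_var is the across-subject per-voxel sample variance averaged over
  the brain mask. The phrase "average absolute voxel-to-voxel variance"
  admits other readings; this mask-averaged per-voxel variance ratio is the
  one implemented, and the ratio itself is what the report carries.

## Synthetic cohort and study conditions

The default cohort is 23 subjects — 10 control, 6 MCI, 7 AD — with MMSE
drawn per group from rounded, [0, 30]-clipped normals (means/SDs 29±1,
27±1, 23±2). Regional DVR for the nine VOIs (listing order: upper parietal,
posterior frontal, prefrontal, occipital-parietal, posterior temporal,
upper temporal, lower temporal, medial temporal, posterior cingulate) is
N(1.10, 0.05) per subject and region, plus group effects of +0.05 (MCI) and
+0.12 (AD) on regions 4, 5, 8 and 9 — the occipital-parietal, posterior
temporal, medial temporal and posterior cingulate VOIs classically
implicated in amyloid/tangle progression. Draws below 1 are clipped to 1
with a logged warning. The effect sizes are invented design values sized so
that a 23-subject discriminant analysis has usable signal; they are
config-exposed and claimed as nothing more. Between-subject variation is
independent across regions; real regional binding is spatially correlated,
so the phantom likely overstates how much information distinct regions add.

The label phantom is a deterministic spherical-shell geometry: a cortical
ribbon split into nine angular sectors around a white-matter core, with a
disjoint sphere below standing in for cerebellar cortex. It preserves the
topology the analysis needs (ribbon-shaped VOIs, a reference region outside
the cerebrum) and nothing else about brain anatomy.

Deformation fields are Gaussian-smoothed white noise (kernel SD
"smoothness", default 12 mm) rescaled to a maximum displacement "amplitude"
(default 3 mm); requiring amplitude < smoothness keeps displacement
gradients ≪ 1, and the finite-difference Jacobian determinant is verified
positive in tests (100/100 seeds). These are stand-ins for diffeomorphic
registration output, not a model of registration error: they are spatially
stationary, small, and known exactly — so overlap and variance metrics here
measure resampling and inversion error only, not registration failure.

Image noise is multiplicative Gaussian with per-frame SD
`noise_sd · value · sqrt(d_max/d_f)` (d_f the frame duration), so short
early frames are noisier, emulating count statistics; the default
`noise_sd` = 0.05 gives 5% relative noise on the longest frames. There is
no scanner physics (resolution, scatter, attenuation, reconstruction).

## Discriminant analysis

LDA uses class means with the pooled within-class covariance
Σ = Σ_g (n_g−1)S_g/(N−G) and the rule
argmax_g [μ_gᵀΣ⁻¹x − ½μ_gᵀΣ⁻¹μ_g + ln π_g]. Priors default to equal
(proportional available). If Σ is singular (detected by a failed Cholesky),
a ridge Σ + λI with λ = 10⁻⁶·tr(Σ)/p (absolute 10⁻⁶ when the trace
vanishes) engages and is logged; predictions then degrade gracefully to the
largest-prior class for totally uninformative features.

LOOCV refits on each leave-one-out sample. The production path forms every
fold's means and pooled scatter by algebraic downdating of the full-sample
fit and solves all folds in one batched call; it is exactly equivalent to
refitting and is verified against a literal per-fold refit oracle (and
sklearn on balanced groups, where the covariance conventions coincide).

The exhaustive search fits all 511 non-empty subsets of the nine regional
features, optionally each augmented with MMSE, and ranks by LOOCV %
(descending), then resubstitution % (descending), then fewer features, then
lexicographic order — the last two being deterministic tie-breaks of our
choosing. Percentages are reported to 0.1 (22/23 → 95.7).

Permutation tests shuffle the group labels (group counts preserved), refit
on each permutation and compare resubstitution % (LOOCV optionally); the
p-value is the plain exceedance fraction #(null ≥ true)/n_perm, reported as
"P < 1/n_perm" when no permutation does as well. No +1 correction is
applied; note the conservative alternative (#+1)/(n+1) and that, because
classification % at n = 23 is a heavily tied lattice statistic, this
tie-counting exceedance p is sub-uniform (conservative) under the null —
a mid-p variant would be calibrated, but the plain definition is kept as
the specified statistic. A permutation with a degenerate fit is scored at
the modal-class rate and logged.

## Two-arm experiment

Each subject's DVR map is computed in the common phantom space, then carried
into "subject space" by that subject's known deformation φ. Arm A
("unwarped"/individual VOIs) extracts regional means in subject space using
the common VOIs carried through φ and then perturbed by a second, smaller
"drawing-error" field (default amplitude 2.5 mm) — the synthetic analogue
of individually created VOIs and their manual variance, not a
reimplementation of cortical surface mapping. Arm B ("warped"/common VOIs)
resamples the subject DVR map back through the numerically inverted φ and
reuses the single common VOI set. With zero noise, zero deformation and
zero VOI error the two arms are provably identical (tested). Dice is
summarized for 12 structures (9 VOIs, white matter, gray matter = the
cortical union, whole brain = cerebrum) by warping the subject label volume
back and comparing to the common labels; the variance-reduction metric
compares the misaligned subject-space DVR volumes (set A) with the
realigned ones (set B) inside the brain mask, with unfittable background
voxels set to 0 before resampling.

All child seeds derive deterministically (CRC-32) from the master seed and
stage/subject identifiers, so a run is a pure function of its
configuration; reports round-trip losslessly through JSON.

## Problem sizes and defaults

The default experiment grid is 32³ voxels at 1 mm — the smallest phantom
that comfortably holds all 11 regions (each ≥ 50 voxels) — and the default
permutation count in `RunConfig` is 2000, chosen so a full two-arm run
(23 subjects × 18 frames, 4 exhaustive searches, 4 permutation tests)
completes in seconds; the acceptance script raises permutations to 10 000.
Replicate-based properties (e.g. the common-space arm matching or beating
the individual-VOI arm) are evaluated over 50 seeded end-to-end runs.

## Known limitations

* No registration is performed; deformations are generated, so the
  pipeline validates the *analysis* around spatial normalization, not any
  registration algorithm.
* The phantom's geometric regularity and region-independent noise make the
  discriminant problem cleaner than clinical data; absolute classification
  percentages on the phantom say nothing about clinical performance, only
  the *ordering* of the arms under controlled misalignment does.
* Logan analysis without a k2′ term carries a small DVR-dependent bias and,
  under noise, the well-known negative bias of log-domain graphical
  methods.
* MMSE and regional DVR are generated independently given the group label,
  whereas clinically they are correlated through disease severity; the
  phantom therefore slightly overstates MMSE's added value to a PET model.
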
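# Methods

`midecode` re-creates, end to end, a motor-imagery decoding analysis: a
block-design fMRI experiment in which subjects imagine three right-hand
actions (aiming, squeezing, extension–flexion) or rest, per-run GLM
t-contrasts of each imagery condition against rest, ROI-wise multivoxel
decoding of the imagined action type, a whole-brain searchlight, and group
inference. Because no real data ship with the package, every stage runs
against a synthetic study whose statistical structure matches what the
analysis assumes; this note records the models, conventions and their
rationale.

## The synthetic study

**Design.** A cohort of `n_subjects` (default 20) each completes `n_runs`
(default 20) runs of eight trials — exactly two per condition — at
TR 2.5 s with 50 volumes per run. A trial is a 2.5 s instruction, a 1 s
delay, and an imagery/rest phase of 6.5 s jittered uniformly by ±1.25 s
(half a TR), followed by a rating gap (default 4 s; the rating-phase
duration is a free knob because no canonical value exists). Condition
orders are pseudo-random with a Latin-square rotation of the base order
across subjects, so orders are counterbalanced while per-run counts stay
fixed. Instruction and delay are left as unmodelled baseline, matching a
GLM that carries only the four condition regressors.

**Signal model.** Each signal ROI holds one unit-norm weight vector per
imagery condition, drawn once per subject and fixed across runs (cross-run
decodability requires a stable pattern). The voxel time series is

    y_v(t) = baseline
           + Σ_c (boxcar_c ⊛ HRF)(t) · (offset_c + amplitude_c · w_{c,v})
           + drift(t) + ε_v(t),   ε ~ N(0, white_sd²) i.i.d.

with the rest condition carrying neither pattern nor offset. The
`uniform_offsets` term adds the same value to every ROI voxel; it exists
specifically to exercise the mean-centering control (a purely univariate
signal must die under centering, a pattern signal must not). A
`pattern_correlation` dial ρ mixes a shared component into the three
condition patterns (`p_c = √(1−ρ)·u_c + √ρ·u₀` with orthonormal u), so
pattern similarity — and with it decodability — can be varied continuously;
the generator reports the realised pairwise correlations.

Default amplitude is 0.5 in signal units against `white_sd = 1` and
baseline 100, i.e. sub-percent signal change spread over a 27-voxel ROI —
enough for clearly above-chance but non-ceiling decoding, in the spirit of
the modest accuracies (a few percent above chance) such experiments
report. Drift defaults to a single 300-s cosine of amplitude 1.

**Motion, EMG, ratings.** Motion parameters are six mean-reverting AR(1)
walks (φ = 0.3, step SD 0.02), generated independently of the task and
re-sampled until the maximum |cosine| between any mean-centered motion
column and any condition regressor is below 0.3 — the same inclusion
criterion the analysis checks. A pure random walk almost never passes this
criterion at 50 volumes (its power is concentrated at the lowest
frequencies, where the task regressors also live), which is why the walk is
mean-reverting. EMG is stationary Gaussian noise with an identical
distribution during imagery and rest — the generator's ground truth is the
null finding that imagery involves no overt muscle activity. Vividness
ratings are i.i.d. draws on the 7-point scale with the same distribution
for all imagery conditions (default mean 6.2 > 5.5).

**What the generator does not emulate.** Physiological noise (cardiac,
respiratory), spatial noise correlations, susceptibility artifacts,
motion-induced image displacement (motion enters only as confound
regressors), between-subject anatomical variability (all subjects share one
grid, so normalization is moot), and scanner drift nonstationarity. Tests
passing on this generator therefore validate the *analysis machinery* —
estimator correctness, cross-validation bookkeeping, error control — not
robustness to real-data artifacts.

## First-level GLM

The per-run design holds four boxcar regressors spanning the imagery/rest
interval, convolved with a canonical double-gamma HRF, six motion
covariates, a discrete-cosine high-pass basis and an intercept.

* **HRF**: difference of two gamma densities parameterised by their mode
  (peak 6 s, undershoot 16 s, unit dispersions, undershoot ratio 1/6),
  scaled so the peak equals 1. Mode parameterisation (shape =
  delay/dispersion + 1) puts the maximum exactly at the stated peak delay.
* **Convolution** on a fine grid (dt = TR/16), scaled by dt to approximate
  the continuous convolution (so event superposition is exactly additive),
  sampled at volume midpoints t = (i + 0.5)·TR; no slice-timing model.
* **High-pass**: DCT-II columns cos(πk(n+½)/N) for k = 1..K with
  K = ⌊2T/cutoff⌋ (T = run length, cutoff 128 s), i.e. the filter is
  implemented as nuisance regressors, equivalent to residualising. The
  constant belongs to the intercept. Cutoffs at or below 2·TR are rejected.
* **Estimation**: plain OLS; t = c'β̂ / √(σ̂² c'(X'X)⁻¹c) with
  σ̂² = RSS/(n − rank X). No AR(1) prewhitening — a stated simplification;
  the generator's noise is white, so OLS is efficient here, but t-values on
  real (autocorrelated) data would be optimistic.
* **Degenerate voxels** (zero residual variance, e.g. data exactly in the
  column space) get t = 0 plus a flag, and flagged voxels are dropped from
  pattern vectors, keeping all downstream features finite.
* **Contrasts**: rest is modelled explicitly and each imagery condition is
  contrasted against it (c = e_cond − e_rest), three maps per run.
* **Smoothing**: separable Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in mm
  taken from the affine, reflect boundary. 5-mm smoothing before the GLM is
  the default (mirroring a conventional preprocessing order) and can be
  disabled; see the dissociation caveat below.

## ROI decoding

t-values inside an ROI are vectorised per contrast map — three response
vectors per run — and optionally mean-centered (each vector's spatial mean
subtracted). A PCA is fitted to the vectors and each vector's scores on the
first five components are the classifier features; components follow a
deterministic sign convention (largest-magnitude loading positive) and, if
the rank is below five, score columns are padded with zeros (with a
warning). The classifier is a Gaussian equal-covariance LDA: pooled
within-class covariance stabilised with a ridge ε·tr(Σ)/d·I (ε = 1e−6),
empirical priors, ties broken by the fixed condition order. Cross-validation
leaves one run out, so each fold classifies the held-out run's three
vectors; accuracy is the proportion correct over all 3·n_runs assignments
against chance 1/3.

By default the PCA is fitted once on the full pattern set *before* the
split, replicating the stated order of the original analysis; this leaks
(unsupervised) test information into the features. The leakage-free variant
(`pca_within_fold=true`) re-fits the PCA per fold and is tested to never
touch test rows. On null data the default shows no measurable bias at the
study's size (the chance-recovery study covers 1/3), which is why fidelity
was kept as the default.

## Searchlight

A lattice ball of radius 5 voxels (the experiment's value) is centered on
every gray-matter voxel; patterns are the mean-centered t-vectors of the
in-mask sphere voxels, and the identical PCA+LDA+leave-one-run-out
machinery yields an accuracy that is written, minus chance, at the seed.
Seeds with fewer than two usable voxels are NaN; spheres with fewer voxels
than components run with padded scores. On desk-scale grids (10–12 voxels
per axis) a radius-5 sphere covers nearly the whole volume, so the
simulation studies use radius 2, and the localization study radius 1 — the
searchlight's spatial uncertainty is roughly its radius, and only at
radius 1 does that uncertainty stay inside a 3³-voxel ROI. The run-wise
contrast maps are the pattern source everywhere, for internal consistency
with the ROI analysis; a per-trial GLM would be a straightforward extension
point.

Group inference smooths each subject's accuracy map (FWHM 1 mm,
NaN-renormalised), computes a voxelwise one-sample t against zero, forms
clusters at the one-sided p < 0.001 threshold with face (6-neighbour)
connectivity (18/26 available), and corrects at cluster level by
permutation instead of random-field theory: under the null the subject maps
are sign-symmetric, so the maximum cluster size over ≥ 1000 random
sign-flips gives an exact FWE-corrected p = (1 + #{null max ≥ observed}) /
(1 + n_perm). Sign flips leave per-voxel sums of squares unchanged, which
makes the permuted t-maps a cheap closed-form update. Fewer than 100
permutations triggers a warning (p resolution).

## Group and behavioural statistics

Per-ROI accuracies are tested against 1/3 across subjects with two-sided
one-sample t-tests. The Holm–Bonferroni family is all non-control ROIs
within a variant, hemispheres counted separately (the default atlas gives a
family of four); the Heschl-gyrus-analogue control ROIs are tested
separately, outside the family, mirroring how a control analysis is
reported. Vividness ratings enter a one-way repeated-measures ANOVA on
per-subject condition means (F = MS_cond/MS_cond×subj; repeated measures
because the design is within-subject). EMG is rectified and integrated
(trapezoid) over 5-s epochs from each phase onset; per-subject condition
means enter paired t-tests of each imagery condition against rest, Holm
over the three comparisons. The amplitude analysis averages ROI t-values
over voxels and runs per condition and subject and runs the same RM-ANOVA
per ROI, Holm across ROIs.

## Numerical and design choices

* All randomness flows from one integer seed through keyed
  `numpy` generators (seed, stream, subject, run), so every output is a
  pure function of (config, seed) and stages can be re-run independently.
* Voxel indices are 0-based, onsets are seconds from run start, the affine
  is the only source of world coordinates (default 3-mm isotropic).
* Mean-centering dissociation caveat: 5-mm smoothing turns a spatially
  uniform ROI offset into a boundary gradient that *survives* mean
  centering and is condition-specific — a genuine, easily overlooked
  confound. The dissociation simulations therefore run unsmoothed, where
  the offset removal is exact by construction.
* Zero-variance columns in the motion-QC cosine count as 0 with a warning;
  an all-zero motion table is valid (cosine 0).
* The one-sample t of constant data equal to the null returns (t=0, p=1);
  constant data off the null is an error.

## Simulation-study sizes

The package's simulation studies (test suite and `scripts/acceptance.py`)
use desk-scale problems chosen to keep each study in seconds-to-minutes:
full-scale cohorts of 20 subjects × 20 runs on 12³ grids for chance
recovery and the headline decoding quantities; 8–10 subjects × 10 runs on
10³ grids for the amplitude sweep, dissociation and localization studies;
100–200 replicate cohorts for the error-control and behavioural-null rates
(binomial-CI comparisons at those counts). These sizes are the package's
own choices; all of them scale up by editing the study config.

## Known limitations

OLS without prewhitening; no sphericity correction beyond the basic
RM-ANOVA; no per-trial GLM for the searchlight; permutation (not RFT)
cluster correction, so results carry Monte-Carlo resolution 1/(n_perm+1);
the synthetic gray-matter mask is a box, not an anatomical ribbon; and the
generator's white spatial noise makes decoding easier than on real data at
matched amplitude — absolute accuracies here are not calibrated to any
empirical effect size.
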
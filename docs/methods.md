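# Methods

`facemvpa` implements a multi-level multivariate pattern analysis (MVPA)
of face information in event-related fMRI, exercised end-to-end on
synthetic data with planted spatial structure. This note records the
models, the defaults and why they hold, the numerical choices, and what
the synthetic validation does and does not establish.

## Experimental model

The simulated experiment shows faces from five categories (cinema,
music, politics, sport — the four familiar subcategories — plus
unfamiliar), eight identities per category. Each of the 16 runs contains
40 stimulus trials (every identity exactly once, so 8 per category) of
4 s: a face event (1 s stimulus + 1 s blank) followed by a letter event
(1 s + 1 s). Between trials lie 35–39 null periods of 0–10 s; the first
10 s and last 4 s of each run are always null. Null scheduling is
uniform-random subject to these constraints rather than
efficiency-optimized: optimal jitter improves estimator efficiency but
is irrelevant to the correctness properties tested here. Null durations
are whole seconds, with one duration adjusted by at most the TR so every
run length is a whole number of TR = 2 s volumes.

## Signal model

Betas follow `β[run, condition, voxel] = signal[condition, voxel] + ε`,
with `ε ~ N(0, σ²)` i.i.d. and the signal run-stable (between-run signal
variability is assumed absent; only noise varies across runs). Signal
lives in three ball-shaped regions (radius 14 mm) tapered by a Gaussian
radial profile `w(d) = exp(−d²/2s²)`, `s = radius/2`:

* **familiarity** — a non-negative bump `a·w` added to every familiar
  condition, so the familiar-vs-unfamiliar contrast is positive and
  peaks at the region center;
* **subcategory** — one random spatial pattern per familiar category,
  constrained to sum to zero across the four categories at each voxel,
  with no pattern for unfamiliar faces. The constraint makes the
  familiarity contrast exactly zero in expectation here, keeping the
  three information families separable by construction;
* **identity** — per familiar identity, `a·w·(γ·z_cat + z_id)` with the
  category component `z_cat` shared by a category's eight identities
  (zero-sum across categories) and the identity perturbation `z_id`
  zero-sum within each category. The nesting (γ = 0.2) makes both
  subcategory and identity information decodable from one dataset while
  keeping the identity region's category leakage well below the
  subcategory region's own signal.

Templates are drawn once per dataset from a seeded stream and are
independent of any voxel mask, so masked and unmasked generation agree
voxel-for-voxel. All randomness in the package descends from one integer
seed through labelled substreams.

Default study conditions (the `studies` module): 20³ grid at 3.5 mm
isotropic, 16 runs, 8 subjects, noise SD 1, amplitudes 1.5 / 0.3 / 0.6
(familiarity / subcategory / identity) in noise-SD units. Amplitudes
were fixed once by a pilot localization scan under the design premise
that searchlight localization succeeds. The subcategory amplitude is the
delicate one: the searchlight statistic is Kendall's tau-a against a 4×4
categorical model, which saturates at its ceiling 24/45 as soon as all
four diagonal sdRSM entries exceed all six off-diagonal entries; at
higher amplitudes the map top flattens into a plateau and the argmax is
no longer informative about the region center. 0.3 keeps the map graded.

Time-series are `X·β + drift + noise`, with `X` the boxcar event trains
convolved with the canonical double-gamma HRF (response peak 6 s,
undershoot 16 s, ratio 1/6; sampled at 16× oversampling), the letter
event as a separate regressor source, and optional random per-voxel
coefficients on the nuisance columns as drift. Fitting the generating
design back to a noiseless series recovers β to ~1e-11, which pins down
the design-matrix conventions (first 4 frames discarded on both sides).

## Analysis chain

* **GLM** — per-run OLS on a design of task regressors (6 for the
  category model, 41 for the identity model) plus linear trend,
  quadratic trend, mean confound, and optional motion columns.
  Prewhitening is unnecessary under the white-noise simulation, so OLS
  is the exact model; intensity normalization scales the in-mask grand
  mean to 100.
* **Correlation MVPA** — patterns are mean-subtracted across conditions,
  runs split into two halves, per-half condition means correlated across
  halves (Pearson) into an N×N split-data RSM, averaged over 100 random
  distinct half-partitions (sampled without replacement; half A
  canonically contains run 0). CDI = mean diagonal − mean off-diagonal.
  Model correlation is Kendall's tau-a between the symmetrized sdRSM's
  diagonal-plus-upper-triangle vector and the same entries of an
  identity-matrix model; tau-a is the variant that tolerates the model's
  massive ties, at the cost of a ceiling below 1 (see above). Tau is
  computed on the permutation-averaged sdRSM, not averaged over
  per-split taus. Undefined correlations (zero-variance patterns)
  propagate as missing values, never as zeros.
* **Classification MVPA** — six pairwise linear soft-margin SVMs
  (C = 1, no feature scaling beyond the mean subtraction) with
  leave-one-run-out cross-validation; a decision score of exactly zero
  counts as an error (conservative, deterministic). Group inference for
  both MVPA branches is a one-sample t-test across subjects with
  Benjamini–Hochberg FDR across tests.
* **Searchlight** — every in-mask voxel gets its k = 100 nearest in-mask
  voxels by metric distance (squared distances quantized at 1e-6 mm²,
  ties broken by voxel index: deterministic). The per-center statistic
  is computed on mean-subtracted patterns restricted to the neighborhood
  (subtraction before restriction; the order is fixed). A vectorized
  path computes model-tau maps for whole volumes and is tested for
  equality against the generic per-center route.
* **Topography** — each information family is mapped repeatedly over
  random run splits (univariate familiar-vs-unfamiliar t across the runs
  of each half; searchlight model-tau per split for subcategory and
  identity), maps averaged across subjects, and the in-mask argmax
  recorded in RAS mm. Separation of the three peak clouds is tested by
  per-axis Kruskal–Wallis and pairwise two-tailed Mann–Whitney
  (Bonferroni), ANOSIM on the Euclidean dissimilarity matrix with an
  add-one permutation p-value, explicit-parameter 3-D Gaussian mixtures
  (component moments set directly from group statistics, no EM) compared
  by AIC with k(3+6+1)−1 free parameters, and Dice overlap of
  thresholded maps. Singular covariances are ridge-regularized by
  1e-6·trace/3 so degenerate noiseless clouds do not crash.
* **Connectivity** — per run, voxel series are residualized against the
  stimulus regressor, motion, and the top-5 PCA time-courses of the
  white-matter and ventricle/CSF voxel sets, z-scored per voxel, and
  concatenated. Seed maps are Pearson correlations with the mean seed
  series, Fisher r-to-z transformed, thresholded at r = 0.12; the
  winner-take-all domain is the union of the thresholded masks, and each
  voxel goes to the seed with the largest joint multiple-regression
  coefficient (betas averaged across subjects first; exact ties to the
  lowest seed index). Voxels fully absorbed by the regressors get zero
  residuals rather than amplified numerical noise.
* **V1 control** — stimuli are equalized to the set-average luminance
  histogram (rank matching) and Fourier amplitude spectrum (phase
  retained), three rounds, each round histogram-then-spectrum. Ending a
  round on the spectrum step means the output amplitude spectra agree
  exactly, which is the property the control depends on; the histogram
  residual after convergence is negligible. C1 features are magnitudes
  of a 4-orientation × 8-size (7–21 px) Gabor bank, max-pooled over
  adjacent scale pairs and 50%-overlapping spatial cells (8–14 px);
  filter borders are zeroed where the convolution overlaps padding so a
  uniform image yields exactly zero features. Classification is a
  one-vs-one linear SVM with leave-one-sample-per-class-out folds and a
  label-permutation chance test.

## Validation scope and known limitations

The synthetic generator emulates the statistical skeleton the analyses
assume — event timing, HRF-convolved responses, run-stable patterns,
i.i.d. Gaussian noise, spatially compact signals. It deliberately omits
physiological noise, motion, temporal autocorrelation, surface geometry,
and between-run signal drift. Passing tests therefore establish that the
statistics are computed correctly and behave as designed under their own
assumptions, not that the pipeline is robust to real-data violations of
those assumptions.

Two findings from the validation deserve emphasis:

1. **tau-a ceiling.** Against a binary model, tau-a cannot exceed
   N·M/C(n,2) (0.533 for the 4×4 model, 0.114 for 32×32), and at high
   SNR whole map neighborhoods sit at the ceiling. Searchlight tau maps
   are therefore useful localizers only below saturation.
2. **Peak-cloud comparisons confound location with dispersion.** With
   co-located signal regions, the three analyses still produce peak
   clouds with slightly different centroids and spreads (each analysis
   has its own statistic-specific jitter, and with 8 subjects the
   realized templates bias each cloud at the sub-voxel level; peaks from
   overlapping run splits of the same data are also mutually dependent,
   violating the permutation test's exchangeability assumption). ANOSIM
   detects these differences far above its nominal rate — in our
   co-located simulations it rejects at roughly 50–80% instead of 5% —
   even though its calibration is exact for i.i.d. points under label
   shuffling. A significant ANOSIM on harvested peaks should therefore
   be read as "the peak distributions differ", not specifically "the
   peak locations differ". The corresponding acceptance check is left
   failing by design rather than weakened.

The univariate peak is intrinsically jittery in a way amplitude cannot
fix: the t statistic divides by an estimated SD, so argmax jitter is
driven by SD-estimation noise (8 runs per half) rather than by SNR.
Subject-averaging tames it; per-split peaks still scatter within the
region.

## Problem sizes

Tests and the acceptance checks run the full pipeline at reduced counts
chosen as this package's own desk-scale conditions: 12–20 run-split
peaks per family (not 500), 999–1000 ANOSIM permutations, 8 simulated
subjects, 8 seeds per planted/co-located condition, 2000 null ROIs for
the CDI calibration, and 200 permutations/datasets for the chance-level
calibrations. The statistics scale to larger counts unchanged; the
searchlight hot path is vectorized (batched float32 correlation plus a
sort/bisection tau count) so a full 500-permutation harvest over a
3072-voxel mask is minutes, not hours.
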
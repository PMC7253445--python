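# Methods

## The model

`scpm` implements seed connectome-based predictive modeling: predicting a
per-participant subjective outcome (stressor-induced change in rated stress or
arousal, or a chronic-stress questionnaire score) from stressor-modulated
*background* connectivity between one seed region and the rest of the brain.

The chain has four statistical stages.

**1. Background connectivity.** Functional connectivity computed on residual
timeseries after removing everything synchronized with the task: per run, an
OLS regression removes an intercept, six rigid-body motion parameters, white
matter / CSF / global mean signals (each with its backward-difference
temporal derivative), one-hot spike regressors for motion outliers, and the
trial-evoked response modeled as an image on/off boxcar convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, undershoot ratio 1/6,
unit peak) plus its derivative. Residuals are bandpass filtered to
0.01–0.1 Hz with a 4th-order Butterworth applied forward–backward per run;
the stimulus presentation rate (one image per 6 s, 0.17 Hz) lies above the
passband and is attenuated below 10% RMS. Runs are concatenated pairwise into
132-s epochs (baseline, early, mid, late), the seed-ROI mean timeseries is
Pearson-correlated with every voxel, r is clipped at 1−1e−7 and Fisher
z-transformed, and each image epoch's map is referenced to the baseline
epoch (S−B), optionally contrasted against the neutral condition
((S−B)−(N−B)).

**2. Group cluster definition.** Per participant, the condition difference of
the differential maps (epoch-pooled Stressor minus Neutral) is tested against
zero with a voxelwise one-sample t (optional covariate residualization, e.g.
sex). Voxels at p < 0.001 are grouped by face adjacency, positive and
negative effects kept apart (bi-sided NN1 clustering). The minimum cluster
extent controlling family-wise error at α = 0.05 comes from a sign-flip
permutation null of the maximum cluster size: the returned extent is the
smallest k with P(max null size ≥ k) ≤ α, i.e. one voxel above the (1−α)
quantile of the null — the quantile itself does not control FWER with
integer-valued sizes.

**3. The predictive model.** Features are cluster means of the relative
differential maps (windows: all image epochs averaged, or early only). In
each cross-validation fold (leave-one-out, or seeded 10-fold), clusters whose
Spearman correlation with the training outcomes has two-sided p < 0.05 are
split by sign into positive and negative networks; each network is summarized
by its mean ("network strength") and an OLS line predicts the held-out
participants. If no cluster passes the screen — routine under shuffled
outcomes — the fallback keeps the clusters above the largest gap in the
magnitude-ordered correlations (all-equal magnitudes degenerate to the single
strongest). Predictive power is the Spearman correlation r_s between
predicted and observed outcomes; significance is the add-one permutation
estimator p = (1 + #{null r_s ≥ observed}) / (1 + n_perm) over full pipeline
re-runs on shuffled outcomes (selection inside folds each time), one-sided
per network.

**4. Consistency.** Clusters selected in every fold of a model are its
every-fold network. Across a family of models sharing the participants, each
cluster's observed statistic is the number of models whose every-fold
network (sign-matched) contains it; the null applies *linked* shuffles — one
participant relabeling per iteration applied to every outcome simultaneously,
preserving outcome–outcome correlations while severing their joint link to
the brain. Anatomically overlapping every-fold clusters across seeds are
connected groups under voxel-set intersection (≥ 1 shared voxel by default).

## Conventions and numerical choices

- Two-sided selection p-values (both signs are kept and partitioned after).
- The fallback ranks absolute correlations; the source procedure's
  "strongest to weakest" does not fix signed vs absolute, and absolute is the
  reading consistent with partitioning by sign afterwards.
- A fold whose network receives no clusters predicts the training-outcome
  mean; `network_strength` itself refuses an empty network. A fully constant
  predicted vector scores r_s := 0 (conservative). This keeps every
  permutation iteration's null r_s defined.
- Rank correlations are computed from integer-doubled ranks with exact
  integer sums, so the batched permutation engine and the per-fold loop are
  bit-identical — the largest-gap fallback compares successive differences
  and must not depend on float summation order. The two paths are tested for
  exact agreement and against a nested-loop re-implementation.
- Spearman p-values use the t approximation with n−2 df (as
  `scipy.stats.spearmanr`); partial Spearman residualizes ranks on an
  intercept plus covariate ranks and uses n−2−k df. Collinear covariates are
  dropped with a warning.
- Framewise displacement is the Power convention: sum of absolute
  frame-to-frame translation differences plus 50 mm times the absolute
  rotation differences; runs with mean FD > 1.5 mm are excluded. This is a
  transparent surrogate for MCFLIRT's RMS displacement, not a reproduction
  of it.
- The longitudinal ROI axis is the first principal axis of the voxel cloud,
  oriented toward the grid's +y (anterior); anterior/posterior thirds are
  thirds of the projection *extent*. A grid axis can be forced.
- The 0.01 Hz preliminary high-pass is subsumed by the bandpass (same floor).
- Per-run filtering uses Gustafsson edge handling and per-run demeaning:
  standard odd-padding transients are unacceptably large on 66-sample runs
  (0.17 Hz leaked ~43% RMS; with Gustafsson ~6%).
- Smoothing is a plain spatial Gaussian (FWHM = 2.355 σ); iterative
  blur-to-target-FWHM is not reproduced. FWHM 0 is the identity and the
  synthetic studies use it — on a 2 mm grid with 3-voxel planted clusters,
  smoothing only blurs the planted boundary.
- Cluster ids order by descending size, then lexicographic peak coordinate,
  so feature columns are reproducible.
- Voxel indices are 0-based internally; world mm coordinates exist only at
  the NIfTI boundary via the affine.
- All randomness flows from explicit integer seeds (`numpy` Generator); the
  linked-shuffle test and k-fold assignment record theirs.

## The synthetic-data generator

No public dataset accompanies the design this package targets, so the
generator is first-class.

**Feature level.** Participant × cluster matrices are i.i.d. standard normal;
the outcome is `beta · mean(pos clusters) − beta · mean(neg clusters) + ε`,
ε ~ N(0, noise_sd²). Defaults: n = 60 participants and 73 clusters (the
scale of a full-seed cluster set), planted networks of one positive and one
negative cluster, beta = 1, noise_sd = 0.3. With a single planted cluster
per network the per-cluster population correlation is ≈ 0.69 — a strong,
recoverable effect; spreading the same beta over k clusters divides the
per-cluster correlation by roughly √k, and multi-cluster plantings are used
where the property under test concerns network aggregation.

**Timeseries level.** A 24 × 24 × 16 voxel grid at 2 mm, TR 1 s, and per
condition two 66-s baseline runs plus six 66-s image runs (5-s images, 1-s
ISI). Per run a latent band-limited signal s(t) is synthesized by inverse
FFT of a white spectrum restricted to 0.01–0.1 Hz (exact band control; ≥95%
periodogram power in-band by construction). Seed voxels carry s(t) plus 5%
sensor noise; each planted cluster voxel is ρ·s + √(1−ρ²)·d with d an
independent band-limited distractor, plus the evoked response, a fixed
mixture of the confound columns, and white noise. Baseline runs use the
neutral-condition coupling in both conditions, so the planted S−B and
(S−B)−(N−B) differentials both equal atanh(ρ_stress) − atanh(ρ_neutral).
Motion confounds are a small random walk with frame jitter; tissue/global
confound signals are broadband — band-limited confounds would eat the scarce
in-band degrees of freedom of 66-sample runs during regression, an artifact
of the run length rather than a property of real data. The evoked response
is injected into seed *and* cluster voxels so the evoked-removal null
actually tests removal.

**Ratings.** Integer 9-point stress/arousal/focus ratings per run: under the
stressor, stress and arousal rise by `drift` per image epoch from a baseline
level; neutral stays flat; focus is high in both conditions. Gaussian noise
is added before rounding and clipping to [1, 9].

**What the generator does not emulate:** hemodynamic nonlinearity, spatial
autocorrelation of noise, scanner drift and physiological noise spectra,
true motion-induced intensity artifacts, registration error, and
heavy-tailed rating behavior. Passing tests demonstrate the statistical
machinery is correct and calibrated under the planted model; they do not
certify performance on real acquisitions.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks use: 500 replicates (n_perm = 200) for type-I
calibration; 50 replicates for planted power/recovery; group studies of
8–16 simulated participants on the default grid for the end-to-end
connectivity checks (20 evoked-only null datasets; one planted-coupling
study of 10). The demo pipeline simulates 16 participants with
participant-varying stressor coupling in (0.4, 0.9) and ratings whose drift
is linear in atanh(ρ). These sizes are the package's chosen desk-scale
study conditions; the generator's statistical regime, not the replicate
count, is what the assertions are about.

## Known limitations

- The group stage replaces a full linear mixed-effects model (condition ×
  epoch × sex, participant random effect) with epoch-pooled participant-level
  condition differences tested by one-sample t / sign-flip permutation. This
  is exact under exchangeability but ignores epoch-level trends.
- The cluster-extent null is a permutation surrogate, not a smoothness-based
  Monte-Carlo; its FWER statement is conditional on the observed sample.
- With 60 participants and ~73 candidate clusters, threshold selection
  co-opts ~2 noise clusters per network per fold; network strength is
  diluted and typical planted-model permutation p-values land near 0.01–0.05
  even for strong planted effects. This mirrors the statistical regime of
  comparable published analyses and is a property of the method, not a bug.
- Sex-interaction models and atlas-based anatomical labeling are out of
  scope.
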
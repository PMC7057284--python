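# Methods

This note documents the models, defaults and numerical choices behind
`fairdecode`, and what the synthetic studies do and do not establish.

## Study design emulated by the generator

Each synthetic study has 31 proposers in two cohorts (19 and 12 subjects,
emulating two samples scanned on different systems). A subject plays 48
trials — 12 per cell of game {UG, DG} × opponent {human, computer} — and
on each trial chooses an offer on the 0–14 € grid in steps of 2 €. Trial
timing follows the task structure: 8 s wait screen, up to 6 s decision
phase, 8 s response window (22 s per trial); the keypress time is drawn
uniformly within the decision phase, so the 6 s pre-response analysis epoch
reaches back into the wait screen by a trial-specific amount. Repetition
time is 2 s; a 48-trial run lasts ~1076 s (538 volumes).

### Behavior model

Each subject carries a latent selfishness s ∈ [0, 1], spread evenly across
the sample. Noise-free cell means are

* UG, human: 10 € (everyone offers high under the rejection threat);
* DG, human: 10 − gap, with gap = s · 8 € plus a constant +2 € for
  cohort 2 (reproducing the higher offer difference in the second sample,
  which is what makes the cohort covariate non-trivial);
* computer opponent: both games shifted down by a social premium
  (1 − s) · 4 €, so *prosocial* subjects show the larger human-vs-computer
  dictator gap — the source of the negative opponent × offer-gap
  interaction in the DG regression.

Trial offers add Gaussian noise (sd 1.5 €) and snap to the 2 € grid. The
closed-form expectation of a snapped offer (Gaussian bin probabilities) is
exposed as `expected_cell_means` and used as the Monte-Carlo oracle in
tests. The constants (10, 8, 2, 4, 1.5 €) were fixed once to give realistic
magnitudes: group mean gap ≈ 4–5 €, between-subject spread covering
near-zero to near-maximal gaps.

### Neural signal model

Two fixed spatial patterns live on a compact "signal" block of voxels
inside an ellipsoidal brain: UG = c + d, DG = c − d, where c (common
response) and d (condition difference) are random Gaussian fields with a
spatial correlation length of ~1.2 voxels, normalized to unit RMS per
voxel. Spatial smoothness matters: the searchlight stage smooths trial
maps at fwhm 8 mm before decoding, and a spatially white difference
pattern would be cancelled by that very smoothing; real activation
patterns are spatially coherent at roughly this scale.

A subject's pattern amplitude is `signal_amplitude_max · gap / max_gap` —
monotone in the offer gap by construction, which is the causal link the
recovery analyses test. Amplitude is expressed in **t-contrast units**:
in pattern-level studies the trial t-maps are white noise (sd 1) plus the
amplitude-scaled pattern; in BOLD-level studies the amplitude is divided
by the RMS norm of the HRF-convolved epoch regressor (times the noise sd),
so the t-patterns estimated by the GLM carry the same contrast. The
default `signal_amplitude_max = 0.45` makes the most selfish subjects
approach ceiling accuracy in the signal ROI while the least selfish sit at
chance, and keeps the searchlight sensitive despite sphere dilution
(≤ 27 signal voxels inside a 123-voxel sphere at the 12³ desk grid).

BOLD runs add white Gaussian noise (sd 1) everywhere and a slow cosine
drift (period 192 s, per-voxel amplitude up to 1) that the high-pass
filter and nuisance regressors largely absorb. A small white-matter-like
block and the out-of-brain background provide the two nuisance series.

What the generator does **not** emulate: physiological noise spectra,
motion, spatial inhomogeneity, autocorrelated (AR) noise, multi-band
acquisition, or anatomical variability. Passing tests therefore establish
the *statistical machinery* — absence of leakage, calibration of nulls,
recovery under the stated signal model — not robustness to scanner
artifacts.

## Pattern estimation (least-squares-all GLM)

One joint design with one regressor per trial (48 columns), each the
HRF-convolved boxcar over the 6 s preceding that trial's keypress, sampled
at volume times; fast responses truncate the epoch at trial onset. The
double-gamma HRF uses the conventional canonical parameters (peak delay
6 s, undershoot delay 16 s, dispersions 1 s, undershoot ratio 6; unit
peak), exposed as keyword arguments. β → t conversion uses the whole-model
residual variance (one model, as in least-squares-all), not per-trial
models.

The Gaussian high-pass filter subtracts a Gaussian-weighted running-line
fit with σ = FWHM/(2√(2 ln 2)) converted to volumes, then restores the
series mean. Its interior transfer is analytic — the residual of a cosine
of frequency f has amplitude 1 − exp(−2π²σ²f²) — which gives a gentle
roll-off: at 100 s FWHM (σ ≈ 42.5 s) a 256 s cosine is attenuated by
~58 %, a 10 s cosine passes ≥ 99 %. Tests assert exactly this transfer.
The filter is applied to the data *and* to the trial/nuisance regressors
(never the intercept) before fitting, so filtering cannot bias the trial
estimates. Rank-deficient designs are rejected with the offending columns
named; zero residual variance yields capped t-values with a warning.

## Decoding

Cross-validation is 6-fold, stratified by class in chronological blocks
(trials 1–2 of each class per fold), limiting temporal-autocorrelation
leakage; a seeded random stratified scheme is available. Per fold, three
steps are fit on the training trials only: per-voxel z-scoring (a
per-pattern mode needing no fitting is provided), one-way ANOVA top-k
selection (k = 1000; ROIs smaller than k use all voxels; individual
cluster ROIs skip selection entirely), and a linear SVM with C = 1.
Degenerate selection scores (zero within-class variance) rank as +∞ when
the class means differ. A deliberately broken `selection_scope="all"` mode
fits selection on all trials before cross-validation; it exists only so
the suite can demonstrate the optimistic bias that nesting prevents
(≈ +0.13 accuracy on pure-noise data in the default configuration).

## Brain–behavior statistics

The partial correlation residualizes both variables on an intercept plus
the covariates (here a cohort dummy) and correlates the residuals;
p comes from t = r√(df)/√(1 − r²), df = n − 2 − k, two-sided. Residuals
with near-zero variance are flagged degenerate rather than producing
spurious ±1. FDR is Benjamini–Hochberg, applied within one network's ROIs
per condition. The Fisher-z comparison of social vs non-social
correlations uses the independent-samples formula even though the two
conditions share subjects; this is anti-conservative and flagged as such —
a dependent-samples correction would need the cross-condition correlation,
which the procedure deliberately keeps simple.

## Searchlight and permutation inference

Spheres use Euclidean distance in voxel units (radius 3 → 123 voxels in
the open interior); all sphere voxels enter the classifier. Trial t-maps
are smoothed (fwhm 8 mm, converted by the header voxel size, 3.5 mm
default) *before* the searchlight. Group inference shuffles the behavior
rows across subjects — jointly with their cohort label, preserving the
behavior–cohort relationship (shuffling behavior alone is available) —
recomputes the voxelwise partial-correlation map per shuffle, and takes a
one-sided (positive) empirical p with add-one smoothing,
p = (1 + #{r_null ≥ r_obs}) / (1 + B); a two-sided flag exists. One-sided
is the default because the hypothesis is directional (higher decodability
in more selfish subjects). Desk-scale default B = 500 (p floor 1/501); an
exhaustive mode enumerates all n! reassignments for n ≤ 8 and is the
oracle in tests. Cluster reports threshold p < α (default 0.005), label
26-connected components, and keep clusters above 15 voxels, reporting
size, peak r and peak coordinate.

## Problem sizes and calibration checks

The test suite and `scripts/acceptance.py` run at desk scale: a 12³ voxel
grid (ellipsoidal brain ≈ 670 voxels, signal block 27 voxels), 14³ where a
mask larger than 1000 voxels is needed, 500 permutations, 50 replicate
studies for ROI-level recovery power, 3 (script) or 2 (suite) replicate
searchlight studies, and 200 replicate null studies for the type-I rate.
At these sizes the zero-amplitude calibration holds (ROI and searchlight
accuracies 0.50 ± 0.02; permutation p-values uniform within KS < 0.05;
type-I rate within [0.02, 0.09] at α = 0.05), ROI recovery is positive and
significant in ≥ 90 % of replicates, and the cluster report recovers the
planted block with median Dice > 0.3 — the Dice ceiling is ≈ 0.39 at this
scale because the reported cluster is necessarily the sphere+smoothing
halo around the 27-voxel truth, so values just above 0.3 mean essentially
complete recovery.

## Known limitations

* Accuracy from 24 trials is coarse (granularity 1/24), which bounds the
  achievable brain–behavior correlation; real studies face the same limit.
* The independent-samples Fisher-z comparison is anti-conservative (above).
* The high-pass roll-off at 100 s FWHM leaves an appreciable fraction of
  drifts slower than ~5 min; the nuisance regressors absorb much of the
  remainder in the synthetic runs.
* No AR(1)/prewhitening, motion regressors or slice-timing correction;
  inputs are assumed preprocessed and mask-aligned.
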
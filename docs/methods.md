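# Methods

This note documents the models implemented in `fixsearch`, the choices made
where the design was genuinely open, and what the synthetic-session
simulator does and does not emulate.

## Fixation-aligned analysis model

Every eye fixation during the search epoch is treated as a trial. Response
windows are referenced to fixation onset and half-open in ms:

| window | interval | role |
|---|---|---|
| `feature` (early) | [50, 150) | visual feature coding / encoding models |
| `attention` (late) | [150, 225) | attentional modulation |
| `baseline` | [−150, 0) relative to cue onset | baseline subtraction |
| `cue_response` | [50, 200) relative to cue/array onset | responsiveness, SI |

Windowed rates are spike counts divided by window length; the spike-density
function convolves spike times with the causal EPSP-like kernel
`K(t) = (1 − e^(−t/1 ms)) · e^(−t/20 ms)`, normalized to unit area so the
trace estimates rate in spikes/s. The normalization is a package choice; it
cancels in every normalized quantity.

All contrast indices share one form, `(a − b) / (a + b)`: the attention
index passes (target, distractor), while desynchronization and
Granger-causality contrasts pass (distractor, target) so that a *reduction*
on target fixations is positive.

## Unit screening

Visual responsiveness uses one-sided Wilcoxon rank-sum tests of cue-window
and array-window rates against baseline (α = 0.05); the pair of p-values
then assigns the receptive-field class (focal foveal / broad foveal /
peripheral / unclassified). The category selectivity index
`SI = (R_face − R_house)/(R_face + R_house)` operates on baseline-subtracted
responses and clamps to ±1 when the two responses have opposite signs;
category classes additionally require a two-sided rank-sum p < 0.05 and
|SI| > 0.13. The peripheral-RF branch is evaluated from search-task
responses only; the synthetic sessions contain no separate saccade-mapping
task.

Attention selectivity is a *paired* two-sided Wilcoxon signed-rank test.
The pairing unit is the stimulus: for each stimulus fixated at least once
in each role, its mean late-window rate as a target is paired with its mean
rate as a distractor. The source analysis states the test but not the
pairing unit; stimuli are the natural repeated entity across roles and
match the per-stimulus-pair geometry analyses, so that is the default here.

## Axis-coding detection

The encoding model regresses per-stimulus firing rates (early window, mean
over distractor fixations) on the stimulus feature matrix (n_stimuli × D,
D = 512 by default) by partial least squares with 4 components. The PLS
algorithm is SIMPLS on centered X and y, implemented directly in numpy
because the permutation procedure performs on the order of 10^5 small fits
and per-call overhead dominates; for a univariate response SIMPLS
coincides with NIPALS PLS1, which the test suite uses to cross-check
coefficients against scikit-learn.

Significance comes from a split-and-permute test: in each of `n_perm`
(default 1000) runs, the rate vector is shuffled relative to the feature
rows, the stimuli are split 50/50 into train/test, and the Pearson
correlation between predicted and actual held-out rates enters the null
distribution. A unit is flagged when the observed (unshuffled) correlation
exceeds the 95th percentile of the null; the observed correlation is also
the reported strength of axis coding.

**Observed-statistic convention.** The observed correlation is computed on
a single seed-fixed split by default (`observed="single"`). Averaging it
over the same split ensemble as the null (`observed="ensemble"`, also
supported) would reduce its variance but destroys exchangeability with
single-run null draws: the mean of ~1000 null-distributed values
essentially never exceeds their own 95th percentile, so the test would
flag almost no unit under the null instead of the nominal 5%. The
single-split default keeps the selection calibrated — over null units the
flag rate is 5% by the rank argument, at any permutation count — which is
what makes "specificity ≈ 95%" a meaningful planted-null recovery check.

## Representational geometry and RSA

Population responses live in unit space: `v_s` is the vector of mean rates
of all units for stimulus `s` in a given window and condition. For every
stimulus pair, the geometry stage reports the Euclidean distance
`‖v_i − v_j‖` and the angle `arccos(v_i·v_j / ‖v_i‖‖v_j‖)`; pairs involving
a zero vector are reported as undefined, not dropped. Distances and angles
are contrasted target-vs-distractor per pair and tested with two-tailed
paired t tests (df = n_pairs − 1; 64 stimuli give 2016 pairs, df 2015).
Angles are invariant under proportional rate scaling of one condition,
which separates gain changes from genuine pattern separation; both early
and late windows are analyzed.

Dissimilarity matrices are `1 − Pearson r` between per-stimulus population
patterns; correspondence between two DMs is Spearman's rho over the lower
triangles, with a permutation null built by relabeling the stimuli of one
DM (rows and columns jointly) and Bonferroni correction across
comparisons applied by the caller.

## Spike–LFP coherence

Each fixation contributes one fixed 200 ms window from fixation onset
(short fixations simply extend into the next saccade/fixation — the window
is not shortened). Spikes are binned as delta counts at the LFP sampling
rate; both signals are mean-subtracted per window and Hanning-tapered;
auto- and cross-spectra are averaged across fixations before forming
`C_xy = |S_xy| / sqrt(S_x S_y)`. On a 200-sample window at 1 kHz the grid
has 5 Hz resolution, so the 4–12 Hz theta band averages the 5 and 10 Hz
bins. Spike and LFP must come from different electrodes.

Conditions are equalized to the same number of fixations *and* the same
number of spikes by random subsampling. Whether the source analysis
subsampled once or repeatedly is unstated; here the subsampling is
repeated (default 20×) and the coherence spectra averaged, which honors
the equal-count rule while reducing subsampling variance. Magnitude
coherence of independent signals has a positive bias ≈ 1/√n_segments;
equal counts make this bias identical across conditions rather than zero.

## Spectral Granger causality

Per condition and spike–LFP pair, the 200 ms segments are detrended
(per-segment least-squares line), ensemble-demeaned (across-segment mean
waveform removed sample-wise), and KPSS-screened: segments whose level-
stationarity statistic (Bartlett-kernel long-run variance, lag
⌊4(T/100)^¼⌋) exceeds the 5% critical value 0.463 are excluded. A
bivariate VAR is fit by least squares pooled across surviving segments —
lagged design rows never cross segment boundaries — with AIC order
selection (capped at 15 in the library, 8 in the pipeline default, since
200-sample segments bound the usable order). Spikes enter as demeaned
binned counts at the LFP rate; this spike-to-continuous convention is a
logged package choice.

Spectral GC uses the transfer-matrix form
`G_{j→i}(f) = −ln(1 − (Σ_jj − Σ_ij²/Σ_ii)|H_ij(f)|² / S_ii(f))` with
`H(f) = (I − Σ_k A_k e^{−i2πfk/fs})^{−1}` and `S = H Σ H*`. An independent
time-domain Geweke oracle (`ln(var_restricted / var_full)`) verifies the
frequency integral `2/fs · ∫₀^{fs/2} G df`. The restricted univariate
autoregression gets its own AIC-selected order up to max(4p, 20): omitting
the other variable turns the target's own process into an ARMA, and
truncating the restricted AR at the VAR's order would overstate the
restricted residual variance (the identity then fails by tens of percent
even at T = 10,000).

## Synthetic sessions and planted ground truth

The simulator emulates the free-gaze search design: 400 ms central
fixation, cue 500–1300 ms (uniform), 500 ms delay, then a search array of
11 items — 2 targets sharing the cue's category (face or house), 9
distractors from the other three categories — on 11 of 20 locations.
Fixation durations are log-normal matched to mean 208 ms / SD 154 ms,
truncated at 80 ms; items are visited uniformly at random (the source task
imposed no search-order constraints, and any sequence model is a
stand-in); a trial ends with an 800 ms target hold.

Planted effects, with defaults:

* **Stimulus features** — 4 categories × 40 stimuli, 512-D, isotropic unit
  scatter around category means at pairwise distance `separation = 8`.
  The separation is chosen so category identity is linearly decodable from
  the features at >95% held-out accuracy, as it is for embeddings from
  category-trained networks; at 512 dimensions with 40 stimuli per
  category, smaller separations defeat any practical linear readout purely
  through centroid-estimation noise.
* **Axis units** (`fraction_axis = 0.5` of each area) — rate
  `softplus(1.5·z + 1)` scaled to the unit's baseline (8–25 spikes/s),
  where `z` is the standardized projection of the features on the unit's
  axis. The softplus link keeps rates positive while staying near-linear
  over the operating range, so the linear encoding model stays
  well-specified. Axes put weight 0.7 on the category-mean subspace
  (units tracking the leading feature components, as observed in recorded
  populations) and 0.3 on a random direction. Non-axis units draw
  per-stimulus log-normal rates (σ = 0.5) independent of the features —
  an exact null for permutation calibration.
* **Attention** — multiplicative gain 1.5 on target fixations, applied
  only inside the late window. Planted index ≈ (1.5−1)/(1.5+1) = 0.2
  before dilution by fixations shorter than 225 ms.
* **Theta coupling** — each area has one theta oscillation whose frequency
  drifts inside 4–12 Hz; LFP = theta + 1/f noise, and unit rates are
  multiplied by `1 + locking·cos(phase)` during fixations, with locking
  0.6 on distractor and 0.2 on target fixations. Sharing the phase between
  an area's LFP and its units' rate modulation is what produces
  controllable spike–field coherence.
* **Axis > non-axis group effects** — non-axis units receive the planted
  attention gain and locking gap shrunk toward null by
  `nonaxis_effect_scale = 0.3`, giving the group contrasts a known sign.
* `n_trials = 300` by default so that each of the 160 stimuli accrues
  roughly 10+ distractor fixations — the coverage the encoding model needs.

Spikes are inhomogeneous Poisson at 1 ms resolution with uniform jitter
within bins.

**What the simulator does not emulate:** gaze-sample dynamics and saccade
trajectories, a separate saccade RF-mapping task, per-neuron latency
differences, spike-sorting artifacts, non-Poisson spiking (refractoriness,
bursting), spatially structured LFP beyond one theta source + 1/f noise
per area, and volume conduction. Passing recovery tests therefore shows
the *estimators* are correct and calibrated under the planted model, not
that real recordings satisfy that model.

## Problem sizes used in the test suite

Tests run the same estimators at reduced scale, chosen as the smallest
sizes at which each property is a sharp check: null calibration uses 500
synthetic null units at 200 permutation runs (the flag decision depends
only on the rank of the observed draw, so the null flag rate is 5% at any
run count); desynchronization recovery uses 20 sessions of 60 trials;
end-to-end recovery uses 20 sessions of 150 trials with 20 stimuli per
category and 8 units each; Granger identities use single T = 10,000
series. The acceptance script runs the null-calibration target at the full
1000 permutation runs.

## Known limitations

* The KPSS screen uses the published 5% critical value, which assumes
  longer series than 200 samples; on short segments the test is
  approximate and slightly conservative.
* Band summaries on 200 ms windows rest on two theta bins (5, 10 Hz);
  finer frequency resolution requires longer windows than the fixation
  design provides.
* Bivariate (pairwise) GC only; no conditional multivariate GC, and no
  nonparametric (factorization-based) spectral GC.
* Pairwise distances between noisy mean-rate vectors are biased upward by
  estimation noise, and the two conditions rarely have equal fixation
  counts per stimulus; condition contrasts of *distance* therefore carry a
  sampling-asymmetry component (targets are typically fixated less often,
  inflating their distances). Angles are less affected; the late-window
  axis-vs-non-axis comparisons the suite asserts are differences of
  contrasts and are robust to this shared bias.
* The fixation-sequence model is a stand-in; only its duration statistics
  are matched to the recorded behavior.
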
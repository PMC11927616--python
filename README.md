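# fixsearch

Fixation-aligned analysis of how visual *feature* coding interacts with
*attention* coding in primate electrophysiology recorded during free-gaze
visual search — with a synthetic-session simulator that plants every
analyzed effect as known ground truth.

## The problem

During natural visual search a monkey fixates one search item after
another; each fixation is a self-paced "trial". Two questions drive the
analysis:

1. **Which units carry an axis code for visual features?** A unit
   axis-codes when its firing rate is (near-)linear in the stimulus
   position along directions of a high-dimensional visual feature space
   (deep-network embeddings, D = 512). Because D far exceeds the number of
   stimuli, the encoding model `r(s) = β·x_s + β₀` is fit by partial least
   squares (SIMPLS, 4 components) and tested with a 1000-run
   split-and-permute procedure: shuffle stimulus labels, split stimuli
   50/50, and compare the held-out Pearson `r` of the intact model against
   the 95th percentile of the shuffled null. The held-out `r` doubles as
   the strength of axis coding.
2. **How does attention reshape what those units transmit?** Target vs
   distractor fixations are compared via the attention index
   `(FR_T − FR_D)/(FR_T + FR_D)` in the late window (150–225 ms after
   fixation onset), via population geometry (pairwise Euclidean distances
   and angles between population vectors — pattern separation), via
   spike–LFP coherence `C_xy(f) = |S_xy| / √(S_x S_y)` in the theta band
   (4–12 Hz, target-induced desynchronization), and via spectral Granger
   causality `G_{j→i}(f) = −ln(1 − (Σ_jj − Σ²_ij/Σ_ii)|H_ij|²/S_ii)` from
   a bivariate VAR.

The package implements the full chain — screening, encoding models,
selectivity indices, geometry/RSA, coherence, Granger causality, group
statistics — plus a session simulator whose planted axis units, attention
gain and condition-dependent theta locking make each stage testable
without any recording. See `docs/methods.md` for model details and design
decisions.

## Worked example

Run the whole pipeline on a simulated session (flat key = value config):

```sh
cat > example.cfg <<EOF
n_trials = 150
n_stimuli_per_category = 20
n_units_per_area = V4:4,TE:4
n_channels_per_area = 2
n_perm = 500
granger_max_order = 6
EOF
fixsearch all --config example.cfg --seed 11 --out run/
```

This simulates a session (8 units, half of them planted axis units),
screens units, fits the PLS encoding models, and computes geometry,
coherence and Granger tables. Selected output:

```text
$ cat run/report_scorecard.csv
axis_sensitivity,axis_specificity,mean_attention_index_gain_units,mean_desynchronization_index
1.0,0.75,0.134,0.152
```

All 4 planted axis units were detected (`axis_sensitivity = 1.0`; one of
the 4 null units was a false positive — at these tiny unit counts the 5%
nominal rate is noisy). The mean attention index is positive (planted
multiplicative gain > 1 on target fixations) and the mean theta
desynchronization index is positive (planted locking 0.6 on distractor vs
0.2 on target fixations).

```text
$ cat run/report_attention_by_class.csv
t,p,mean_axis,mean_nonaxis,n_axis,n_nonaxis
1.549,0.172,0.171,0.073,5,3
```

Axis-flagged units show the stronger attentional modulation
(0.171 vs 0.073), the planted axis > non-axis pattern; with 8 units the
two-sample t test is underpowered, and the test suite asserts the same
pattern across 20 sessions instead. `run/geometry_contrasts.csv` likewise
shows the late-window distance contrast (0.291) exceeding the early-window
one (0.075): attention separates the population patterns mostly in the
late window, where the gain is planted.

Individual stages (`simulate`, `screen`, `axis`, `geometry`, `coherence`,
`granger`, `report`) can be run separately against the same output
directory; all tables are CSV with header rows, and `manifest.json`
records the seed and config hash of the run.

The same machinery is importable as a library:

```python
import fixsearch as fx

fit = fx.axis_permutation_test(features, rates, n_perm=1000, seed=0)
fit.is_axis, fit.strength   # e.g. (True, 0.64)
```

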
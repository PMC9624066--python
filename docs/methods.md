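# Methods

`neurofuse` implements a multivariate comparison of object representations
across three kinds of neural measurement — scalp EEG, intracranial field
potentials (ECoG), and fMRI beta patterns — on a common 125-condition
design: 5 object categories (animal, chair, face, fruit, vehicle) x 5
exemplar identities x 5 viewing conditions (the canonical 3°/0° view, two
depth rotations, and two size changes). Because the pipeline is exercised
on synthetic data with known ground truth, every analysis stage can be
validated against the parameters that generated its input. This note
documents the generative model, each analysis stage with its tunable
parameters, the numerical choices, and what the synthetic validation does
and does not establish.

## Synthetic data model

**Spatial code.** For category *c* under viewing condition *v*, every trial
carries the spatial pattern

```
s(c, v) = a_c * [ rho * P_c + (1 - rho) * P_{c,v} ]
```

where `P_c` (shared across views) and `P_{c,v}` (view-specific) are fixed
unit-norm Gaussian random vectors over channels/voxels, drawn once per
participant. `rho = invariance_mix` in [0, 1] interpolates between a fully
view-specific code (rho = 0: cross-view decoding at chance) and a fully
view-invariant code (rho = 1). `a_c = category_amplitudes[c]` sets the
category effect size in units of the noise standard deviation; the default
profile gives faces the largest response, matching the ubiquitous finding
that face signals are the strongest and earliest to decode.

**Temporal envelope.** The pattern is modulated by a Gaussian bump
truncated at 5 % of its peak. Onset is *defined* as that 5 % crossing, so
pre-onset samples are exactly signal-free and onset-recovery tests have an
unambiguous ground truth. `signal_width` (the Gaussian sigma, ms) is by
default derived from `(signal_onset, signal_peak)` through the 5 % rule;
an explicit width overrides the derivation and the effective onset is then
the crossing implied by that width. Defaults: onset 80 ms, peak 150 ms.

**Noise.** Channel noise is Gaussian with exponential spatial covariance
`C_ij = exp(-|i - j| / channel_corr_scale)` (so whitening has something
non-trivial to remove) and stationary AR(1) temporal smoothing with
coefficient `temporal_smoothing` (unit marginal variance). `noise_sd`
scales everything; amplitudes are therefore effect sizes in noise units.

**EEG.** One recording per participant: `n_channels` (default 64) sensors,
`n_repetitions` (default 32) repetitions per condition, epochs
−100..+600 ms at 1 kHz by default.

**ECoG.** One pooled "super-subject" recording: electrodes come in blocks
per region (occipital-inferior, fusiform, lingual, parahippocampal,
inferior temporal, temporal pole), each region's envelope shifted by
`region_latency_offsets` (defaults follow the early-visual-to-temporal-pole
progression), and a `selective_fraction` of electrodes carries signal.
Electrode provenance across pseudo-patients is retained in the channel
table. Besides the slow evoked deflection, selective electrodes receive an
envelope-modulated broadband component (`ecog_power_scale` times amplitude
times fast Gaussian fluctuation): intracranial category selectivity is
predominantly a broadband-power phenomenon, and the range features used
for ECoG decoding (below) respond to within-bin variability rather than to
slow deflections.

**fMRI.** Per participant, ROI and run, a 125 x `n_voxels` beta matrix:
`roi_snr[roi]` scales the spatial code, unit Gaussian voxel noise is drawn
independently per run. The default SNR map degrades from occipital (1.0)
to temporal pole (0.15), mimicking the well-known temporal-lobe SNR loss
from susceptibility artifacts.

**Determinism.** All randomness derives from one `numpy` `SeedSequence`;
participant *i* uses spawn key *i*. Identical parameters give bit-identical
output, and participants are independent streams.

## Preprocessing

A minimal conditioning chain for continuous recordings: a linear-phase FIR
low-pass (Hamming design; defaults 40 Hz cutoff, order 396) applied in one
forward pass with the constant group delay (order/2 samples) compensated by
shifting — a forward-backward pass would square the magnitude response and
is not used — followed by polyphase rational resampling (default target
1 kHz; ratios must be rational with denominator ≤ 1000, e.g. 1100→1000 Hz
= 10/11), subtraction re-referencing to a named electrode (the left-mastoid
convention), and closed-interval epoching with 0 ms at the event sample.
No high-pass filter is applied (high-pass filtering displaces multivariate
patterns into activity-silent periods) and no baseline correction is
applied anywhere; the decoders are insensitive to constant channel offsets
and this keeps the provenance simple.

## Decoding

One-vs-rest linear classification per category, chance = 0.5, in three
schemes:

* **category selectivity** — train and test on all viewing conditions;
* **rotation invariance** — train on the canonical view, test on the two
  rotated views (scored separately, then averaged);
* **scale invariance** — train on the canonical view, test on the two
  rescaled views.

The class imbalance (1 category vs 4) is removed by randomly subsampling
the negatives to the positive count; the whole procedure is repeated
(`n_repeats`, defaults 300 for selectivity and 150 for the invariance
schemes) over fresh negative samples and averaged.

For the selectivity scheme, trials of each class are randomly partitioned
into `n_pseudotrials` (default 150) sets whose sizes differ by at most one
(800 trials → 100 sets of 5 and 50 of 6) and averaged within set;
cross-validation then leaves one pseudo-trial *per class* out (149 + 149
train, 1 + 1 test). The invariance schemes skip pseudo-trial averaging and
test every held-out-view trial against balanced negatives.

**Multivariate noise normalisation.** Activation patterns are whitened by
`W = Sigma^(-1/2)`, where `Sigma` is the channel covariance of residuals
(pattern minus its class mean, per class and per timepoint, pooled over
timepoints) estimated from training data only, shrunk toward a scaled
identity (Ledoit-Wolf by default, or a fixed coefficient), and inverted
via an eigendecomposition with an eigenvalue floor so rank-deficient
estimates still whiten. Whitening inside each cross-validation fold (never
from test data) keeps the null calibrated.

**Classifier.** A linear max-margin classifier (L2-regularised squared
hinge, C = 1 — the conventional default since no principled value is
available for these data sizes), optimised by dual coordinate descent with
randomised sweeps (`neurofuse.svm`). This solver optimises the same convex
objective as `sklearn.svm.LinearSVC`; the test suite verifies hyperplane
agreement to 1e-4. It exists because the time-resolved pipeline fits one
classifier per timepoint x fold x repeat — hundreds of thousands of tiny
problems — where per-call overhead, not the solve, dominates. Decision
ties (score exactly 0) go to the negative class, deterministically.

**Static decoders.** fMRI uses leave-one-run-out cross-validation; both
the training-run negatives and the held-out run's negatives are subsampled
to balance, so chance is exactly 0.5. ECoG decoding uses a range feature —
max(x) − min(x) per electrode in consecutive 25 ms bins tiling 50–300 ms —
with leave-one-trial-out or run-wise cross-validation.

**Aggregation.** Mean over folds → mean over repeats → per category →
(outside the decoder) mean over participants.

## Representational similarity

Condition patterns are trial averages per condition; an RDM entry (i, j) is
`1 − Spearman` (mid-ranks for ties) between the patterns of conditions i
and j, computed as Pearson correlation of ranked rows for speed. RDMs are
symmetric, valued in [0, 2], with an undefined (NaN) diagonal; constant
patterns yield undefined entries with a warning. The canonical
vectorisation is the upper triangle (row < col). Time-resolved EEG/ECoG
RDMs are computed per sample from sensor patterns; ECoG RDMs come pooled
(all electrodes) and regional (per ROI); fMRI RDMs are static, one per
participant x ROI from run-averaged betas. Group RDMs average
dissimilarities directly (no rank transform first — simpler, and recorded
in provenance); undefined entries propagate.

The **upper noise ceiling** is the mean Spearman correlation of each
participant's RDM with the group-mean RDM (participant included). It
carries a self-inclusion bias of order 1/sqrt(n_participants) — verified
against a leave-one-out variant in the tests — which is unproblematic here
because it is used comparatively, as a per-ROI SNR proxy. If participants
cancel exactly (constant group RDM), the ceiling is 0 by convention.

## Inference

* **Per-timepoint significance**: one-sided Wilcoxon signed-rank across
  participants against chance. The null distribution of the positive-rank
  sum is computed exactly for n ≤ 25 by dynamic programming over doubled
  mid-ranks (scipy's exact mode refuses ties, and tied accuracies are
  routine with few folds); above that, a tie-corrected normal
  approximation with continuity correction. Zero differences are dropped
  (Wilcoxon convention); all-zero vectors give p = 1.
* **Multiplicity**: Benjamini–Hochberg FDR at q = 0.05, with the family =
  all timepoints of one curve (matching per-curve significance markers;
  not pooled across categories or schemes). NaN p-values are excluded from
  the family and never significant.
* **Onset latency**: earliest time opening a run of ≥ 15 consecutive
  significant samples, searched from stimulus onset; undefined is a valid
  outcome. **Peak latency**: time of the accuracy maximum (earliest sample
  on ties), searched post-stimulus by default.
* **Participant bootstrap**: resampling with replacement (default 10,000),
  percentile 95 % CI, and a two-sided difference p with +1 smoothing:
  `p = 2 * min(P(s* <= 0), P(s* >= 0))`.
* **RDM permutation test**: Spearman over upper triangles; the null
  relabels the conditions of one RDM (joint row/column permutation,
  default 10,000 draws, exhaustive on request), with
  `p = (1 + #{rho* >= rho_obs}) / (1 + n_perm)` so p is never zero.
  Relabeling permutes the pair vector, so ranks are computed once and
  gathered per permutation.

## Fusion

Classification-based: a single Spearman rho between two accuracy
timecourses on a common grid, and a per-timepoint Spearman across the five
category accuracies. Millisecond-resolution curves are compared to
25 ms-binned ones by averaging within bins and comparing at bin centers —
resolution is never fabricated by interpolation. Representation-based: a
static RDM (or a second stack) against a time-resolved RDM stack, per
timepoint, with permutation p and FDR over time. The SNR analysis
correlates, per region, the participant-mean fMRI category accuracies with
the ECoG category accuracies (category-selectivity scheme), and then
correlates the six per-region rhos with the six noise-ceiling SNR proxies.
Undefined rhos (constant vectors) propagate as NaN and are excluded from
FDR families; an all-defined-but-constant summary is flagged degenerate.

## Validation experiments and problem sizes

The experiments in `neurofuse.experiments` (used by the test suite and
`scripts/acceptance.py`) run the full chain at sizes chosen so each check
is well powered yet completes on a single CPU in minutes:

* *Design arithmetic* uses the full-size design (4000 EEG trials, 8 runs x
  125 conditions) since counting is cheap.
* *Null calibration*: 10 label-shuffled datasets (10 channels, 50 Hz,
  6 repetitions); the pooled mean accuracy is compared to the exact 99 %
  binomial interval computed for one decision per cross-validation fold —
  the two test patterns of a fold share their classifier, and counting
  them as one independent unit bounds that dependence (the empirical
  variance inflation is below 2). FDR/onset calibration uses 200 null
  accuracy families of 12 participants x 80 timepoints.
* *Latency recovery*: 21 participants, 24 channels, 250 Hz grid,
  −52..320 ms, 8 repetitions of a reduced (5 x 2 x 5) design, amplitudes
  twice the default so decoding is sensitive near the 5 %-of-peak envelope
  foot; 10 meta-seeds. Recovered onsets are systematically a few
  milliseconds late — the envelope carries almost no energy at its formal
  onset — which is inherent to threshold-crossing onset definitions.
* *Invariance ordering and whitening benefit*: 20 paired seeds each, one
  participant per seed, decoding restricted to a peri-peak window.
* *SNR correspondence*: 8 fMRI participants (12 voxels, 4 runs) with an
  ROI-graded SNR profile; three independent ECoG pseudo-patient cohorts
  (12 electrodes per region, 4 pseudo-runs) sharing the fMRI category
  amplitude profile; 20 seeds. Spearman over five category accuracies is
  intrinsically noisy, so positivity of the summary (not its magnitude) is
  the validated property.

## What passing tests do and do not show

The generator produces linearly separable Gaussian codes with stationary
noise. It contains no eye blinks, line noise, channel drift, or
hemodynamic convolution; ECoG broadband activity is reduced to an
envelope-modulated variance increase; fMRI runs are exchangeable (no
scanner drift or motion). Passing validation therefore establishes that
the *analysis chain* is correct and calibrated — balanced decoding is
unbiased, inference controls false positives, latency and SNR structure
are recovered when present — not that real recordings would yield any
particular accuracy or latency. Real-data headline numbers depend on
physiological signal strength that the generator only parameterises.

## Known limitations

* The invariance schemes follow the train-on-canonical-view convention;
  training on a non-canonical view is expressible via a custom `Scheme`
  but untested.
* The exact signed-rank null is O(n * total-rank-sum) per timepoint;
  beyond n = 25 the normal approximation is used.
* Fusion p-values treat timepoints independently before FDR; no
  cluster-based correction is provided.
* The HDF5 reader validates schema and shapes but not physical units;
  times are always milliseconds relative to stimulus onset, closed at both
  window ends.
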
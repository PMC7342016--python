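# Methods

`oscdecode` implements a complete multivariate analysis chain for epoched
EEG designed to detect object representations that two tasks (viewing an
object vs. imagining it on an auditory cue) express in the same oscillatory
code, and to characterize where on the scalp and in which representational
format that shared code lives.  Every stage is exercised end-to-end on
synthetic EEG with known ground truth.

## Time-frequency decomposition

Single trials are convolved per channel with complex Morlet wavelets on a
20-bin logarithmic grid between 5 and 31 Hz
(`f_i = 5 * (31/5)^(i/19)`).  The wavelets have a **fixed temporal support of
600 ms at every frequency**: the Gaussian envelope's standard deviation is
100 ms so the truncation edges sit at 3 sigma, and a zero-mean correction
keeps the wavelet admissible at 5 Hz.  Fixed support means spectral
bandwidth (sigma_f ~ 1.6 Hz) is constant across the grid; this trades
frequency resolution at the top of the grid for uniform temporal resolution.
The magnitude of the complex coefficient is taken per time point as absolute
power — computed before any trial averaging, so non-phase-locked (induced)
activity is retained.

Power is converted to dB relative to the per-trial, per-channel,
per-frequency mean over a pre-stimulus baseline (-500 to -300 ms), then
averaged into non-overlapping 20 ms bins (50 Hz resolution; bins are
left-closed/right-open, anchored at the first epoch sample, stamped with the
bin start).  The 20 bins are aggregated into three bands by rounding each
bin center to the nearest integer Hz and testing membership in the nominal
ranges theta 5-7, alpha 8-13, beta 14-31 Hz, which yields the 5/6/9 split
the rest of the pipeline assumes.

Epochs must carry at least 300 ms of pre-stimulus padding (half a wavelet);
the convolution zero-pads at epoch edges, so the outermost 300 ms of an
epoch are attenuated and should be padding rather than analysis window.
With the default 600 ms pre-stimulus epochs, the earliest 100 ms of the
baseline window lean on this zero-padded region; the attenuation there is
small and identical across trials and conditions, so it cancels in the dB
ratio to first order.

`decompose()` fuses the three steps frequency-by-frequency so the full-rate
four-dimensional power array is never materialized; a test asserts
equivalence with the composed modular operations, and an independent
cross-check against MNE-Python's Morlet implementation (envelope width
matched via `n_cycles = 2*pi*f*0.1`) shows r > 0.999 agreement up to a
constant gain that cancels in dB.

## Decoding

Object decoding is pairwise: for each of the 66 unordered pairs of the 12
objects, a linear C-SVC (libsvm, cost C = 1, no additional feature scaling —
the dB normalization already centers features) discriminates the two objects
from band-averaged sensor patterns (63 features with the reference montage;
a concatenation variant keeps bins separate, e.g. 6 x 63 = 378 features for
alpha).  Before classification, each condition's trials are averaged into 4
pseudo-trials (disjoint random 25% shares, remainder trials dropped at
random); partitions are redrawn on every repeat (default 100 repeats, 20 at
demo scale) and results averaged.

*Cross-task time generalization*: classifiers are trained at each perception
time point and tested at each imagery time point (train on one task's 4
pseudo-trials per object, test on all 4 of the other task's; each of the 8
test pseudo-trials scored individually, a decision value of exactly zero
earning half credit).  Both train/test directions are run and averaged onto
the same perception-time x imagery-time cell, so the map's axes are fixed
regardless of direction.  *Within-task decoding* uses leave-one-pseudo-
trial-out cross-validation with training and testing times yoked; all four
folds are rotated per repeat (variance reduction; the repeat average is the
estimand either way).

Implementation note: the solver is called through scikit-learn's low-level
libsvm binding and its solution (weights, bias, decisions) is asserted
against `sklearn.svm.SVC` in the test suite; per-pair scoring across all
test times is a single batched tensor contraction.

Variants implemented on the same machinery: anterior/posterior electrode
halves (35/37 channels, central and temporal rows in both); participant-
specific alpha (1 Hz-resolution decomposition on an integer 7-14 Hz grid,
peak = frequency in 8..13 whose 3-bin band maximizes time-averaged
within-task perception decoding, ties to the lowest frequency, band =
peak +- 1 Hz); alpha-enhancement/suppression trial split (per-trial mean
alpha dB over the post-stimulus window > 0 vs <= 0, larger class subsampled
to the smaller); and broadband decoding of raw baseline-corrected voltages
at the acquisition rate without any frequency decomposition.

## Localization

Classifier weights are not interpretable channel-wise, so they are
multiplied with the training-data feature covariance (pooled
class-mean-removed estimator, 1/(n-1) normalization) to obtain activation
patterns; for two-class Gaussian data with shared covariance this recovers
the class-mean difference, which the suite verifies by simulation.
`weights_to_pattern` accepts whatever exemplar set the caller designates as
training data.  For topography summaries the package estimates the
covariance from the full training dataset at the analysed time point (all
conditions' trials, class means removed) rather than from only the
classifier's 8 pseudo-trials: a covariance from 8 exemplars has rank 6 and
is strongly correlated with the fitted weights, which at desk scale smears
the pattern over noise channels, whereas the full-dataset estimate is
well-conditioned and weight-independent.  Per pairwise classifier, patterns
are averaged signed over partition repeats and time points (the pattern
sign is consistent within a pair), then rectified, then averaged across
pairs — the sign is arbitrary only across pairs — per channel and time,
separately for perception- and imagery-trained classifiers, and exported as
a long-format table.

## Representational similarity analysis

The neural RDM treats pairwise cross-decoding accuracy as dissimilarity
(more discriminable = more dissimilar): the 12 x 12 accuracy slices are
averaged over every cell of the significant cross-task cluster, one RDM per
participant.  Model RDMs are 1 - Pearson correlation of per-object feature
rows (feature matrices are external CSV inputs listed in a JSON manifest;
running the vision/auditory networks themselves is out of scope), a binary
+-1 superordinate-category code (four categories of three objects; the 66
lower-triangle entries then contain 12 within-category and 54 between-
category pairs), the 19 -> 8 aggregation of VGG-19 layer RDMs (conv blocks
1-2 / 3-4 / 5-8 / 9-12 / 13-16 averaged, the three fully connected layers
kept singly), and the 2 + 11 stages of the auditory models (two
spectrotemporal stages; three shared conv layers plus conv1/conv2/fc1/fc2
for each of the genre and word branches).  Neural and model RDMs are
compared with Spearman rank correlation over the 66 lower-triangle entries
(average ranks for ties, which matters for the binary model); group
inference is a sign-permutation test per model RDM with Benjamini-Hochberg
FDR at q = 0.05 across the RDMs of each model family.

## Group statistics

The group statistic (mean accuracy minus 50%, or mean correlation minus 0)
is tested with participant sign-permutation: each of the (default) 10,000
permutations flips every participant's entire map by an independent +-1 and
recomputes the group mean; the identity permutation is included, so the
smallest attainable p is 1/(n_perm+1).  Tests are one-sided (right tail) by
default — the hypotheses are directional (above-chance decoding, positive
correlation) — and switchable.  Every draw is converted to a p-map against
the same pooled empirical distribution; maps are thresholded at the
cluster-definition p < 0.05; supra-threshold cells are grouped by adjacency
(1-D) or 8-connectivity (2-D, configurable); the maximum cluster size per
permutation forms the null, and an observed cluster is significant when the
fraction of null maxima reaching its size is below 0.05 divided by the
Bonferroni factor (3 when the three bands are tested).  Cluster *size* (cell
count) is the statistic, not cluster mass.  Peak latencies of group maps are
the argmax of the marginal means along each task axis with percentile
bootstrap (over participants) confidence intervals.

Because cluster sizes are integers, the procedure is conservative on very
small or rough maps (the attainable p-values are discrete); the family-wise
error simulation in the test suite therefore uses smooth 30 x 30 null maps,
matching the smoothness of real accuracy maps, where the empirical FWER is
statistically indistinguishable from the nominal 5%.

## Synthetic EEG generator

Each trial is the sum of

1. **1/f^beta background noise** (beta = 1 by default), synthesized in the
   frequency domain, independent per channel, unit variance;
2. an **ongoing spatially broad 10 Hz background** with uniform random phase
   and gamma-distributed per-trial amplitude (mean 1, cv 0.5) on a
   per-participant near-uniform topography, scaled by 0.5 — this gives
   single trials genuine alpha enhancement *and* suppression relative to
   baseline, so the alpha-split analysis has both classes; and
3. the **planted object code**: a sinusoid at the center of `shared_band`
   (10.5 Hz by default), with uniform random phase per trial
   (`phase_locked=False`, the default) so it is induced power only,
   multiplied by an envelope that is exactly zero outside the task's latency
   window (50 ms raised-cosine ramps inside the window edges keep the
   planted energy inside the band), and by the participant's object pattern.

Object patterns are standard-normal loadings on the posterior-exclusive
channels (occipital first; 25% of channels by default), unit-normalized, and
identical across the two tasks — identity across tasks *is* the ground-truth
"shared representation".  Patterns are independent across participants
(group statistics only need within-participant decodability); optionally a
model feature matrix imposes a common representational geometry via
participant-specific random linear read-outs of the z-scored features.
`snr` is the amplitude of the unit-norm pattern oscillation relative to the
unit-variance channel noise.

What the generator does *not* emulate: evoked components beyond the optional
`phase_locked` flag, biophysical volume conduction (patterns are assigned
directly to channels, not propagated from sources), eye or muscle artifacts,
and non-stationary noise.  Passing recovery tests therefore demonstrates
that the pipeline's inferences are correct *given* the assumed signal
model — band-limited induced patterns in 1/f noise — not that they are
robust to every artifact of real recordings.

## Demo-scale parameters

The full-scale defaults are the documented analysis conditions: 38
participants, 63 channels, 12 objects, 80 trials per object and task,
1000 Hz sampling, epochs -600..1100 ms (perception) and -600..3100 ms
(imagery), analysis windows 0-800 and 0-2500 ms, 100 pseudo-trial repeats,
10,000 permutations.  The packaged demo configuration (`RunConfig.demo()`)
is the package's desk-scale choice for its own validation runs: 10
participants, 16 trials per object and task, 250 Hz sampling, 20 repeats,
1,000 permutations, decoded time grids of 40 ms (perception) and 60 ms
(imagery).  `snr = 1.2` was calibrated once so that the demo cohort yields
a clearly significant alpha cluster without saturating single-pair
accuracies, and is recorded in the config.  Planted latency windows are
200-600 ms (perception) and 600-2300 ms (imagery).

## Numerical choices and degenerate inputs

- Wavelet amplitude is normalized so a unit sinusoid at the center frequency
  yields magnitude 1; all downstream quantities are dB ratios, so the
  normalization is cosmetic.
- Time-frequency work runs in single precision (the decoder upcasts its
  features to float64 for the SVM); the fused and modular paths agree to
  ~2e-3 dB.
- A zero or negative baseline mean (e.g. an all-zero channel) raises rather
  than producing -inf dB.
- Pseudo-trial remainders are dropped at random per repeat; conditions with
  fewer trials than pseudo-trials raise.
- SVM decision values of exactly zero score half credit, keeping degenerate
  classifiers (identical classes) at exactly 50%.
- Peak-alpha ties break to the lowest frequency; flat (constant) input data
  produce exactly 50% everywhere and hence peak at 8 Hz.
- Empty cluster masks, empty p-value lists, flat maps for peak finding, and
  single-exemplar covariance all raise with explicit messages.

## Known limitations

- The exact Morlet parameterization behind a fixed 600 ms support is a
  convention choice (truncation at 3 sigma); the envelope parameter is
  exposed (`edge_sigmas`) rather than hidden.
- Cluster-size inference is conservative on small/rough maps (discrete
  sizes); cluster-mass statistics are a config hook, not implemented.
- The generator's read-out construction makes pattern correlations
  approximate (not exactly equal to) the supplied model geometry; RSA
  recovery tests use rank correlation, which only needs monotone agreement.
- `align_to_offset` rounds per-trial shifts to whole samples.
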
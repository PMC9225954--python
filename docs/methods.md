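# Methods

This note documents the models, conventions and numerical choices behind
`crossdecode`, and what its synthetic-data validation does and does not show
about real recordings.

## The cross-decoding model

All decoding is pairwise binary classification with a linear C-SVM
(libsvm backend, C = 1, no feature scaling beyond the whitening stage).
C is not tuned: with six-sample training sets a maximum-margin hyperplane is
essentially insensitive to C ≥ 1, and tuning would have to be nested inside
the cross-validation to remain unbiased.

A *scheme* crosses the classified factor with a transfer factor:

- classified pairs: all unordered pairs of the target factor's levels
  (6 location pairs, or 6 category pairs when the roles are swapped);
- transfer pairs: all ordered (train, test) pairs of the other factor's
  levels with train ≠ test (12 for four categories).

One *cell* is one (classified pair, transfer pair) combination: the
classifier trains on data from the train level only and is tested on the
test level only, so any above-chance accuracy reflects information that
generalizes across the transfer factor.  Reported accuracies are plain
means over cells (and folds/iterations); chance is 50% exactly because
every test set contains one exemplar of each class.

Cell counts under the default 4 x 4 x 3 design:

| analysis | cells per reported value |
|---|---|
| fMRI ROI (5 pseudo-run folds) | 6 x 12 x 5 = 360 |
| EEG time point (100 iterations) | 6 x 12 x 100 = 7,200 |
| temporal-generalization entry | 7,200 |
| fusion RDV | 72 entries, *not* averaged |

### Pseudo-trials

Raw trials of a condition are randomly partitioned into `n_bins` bins
(default 4; near-equal sizes when the count is not divisible) and each bin
is averaged.  Training uses bins 1…n−1 of the train condition, testing the
held-out bin of the test condition; because the binning partitions trials,
no raw trial can contribute to both sides.  fMRI uses the same mechanism on
runs (10 runs → 5 pseudo-runs of 2) with leave-one-pseudo-run-out folds; the
pseudo-run partition is drawn once per (subject, seed) and reused by every
cell and every searchlight sphere of that subject, so spatial comparisons
are not confounded by binning noise.  When conditions have unequal trial
counts (real data after artifact rejection), all conditions are first
subsampled to the common minimum with the scheme seed — balance is what
guarantees the 50% chance level.

### Noise normalization

Channels are whitened by Σ^(−1/2), where Σ is the covariance of
within-condition residuals (trial minus condition mean, per time point)
pooled over time points and conditions, shrunk toward the scaled identity
with the Ledoit–Wolf analytic intensity.  Shrinkage makes Σ invertible for
any trial count; for very long recordings the residual sample list is
strided down to ≤ 200,000 rows before fitting, which changes the estimate
negligibly while bounding memory.

## Synthetic data

The generator is the package's testbed: it emulates the *structure* of the
target experiments (fully crossed design, 63 channels at 1 kHz, epochs
−100…999 ms, 60 trials per category-level condition; 10 fMRI runs of 48
condition t-maps; layered feature banks) with planted, parameterized
signals.

Per trial of condition (category, location, clutter):

```
x(t) = A_loc · topo(loc, cat) · g(t; λ_loc, w) + A_cat · topo(cat, loc) · g(t; λ_cat, w) + ε(t)
```

- `g` is a Gaussian bump, latency = mean (ms), width = FWHM (default 80 ms).
  Default planted location latencies are 140 / 133 / 317 ms for no / low /
  high clutter — the regime the package is meant to probe: an early locus
  for clean backgrounds and a delayed one under clutter.
- `topo(loc, cat) = sqrt(f)·T_loc + sqrt(1−f)·T_loc,cat`: the fraction `f`
  (`invariant_fraction`, default 0.7) of the location topography is shared
  across categories.  Cross-decoding transfers *only* on the shared part —
  with f = 0 cross-decoding stays at chance while within-category decoding
  is far above, so the generator cleanly separates the two constructs.
- `T_loc` embeds the quadrant offsets (±3°, ±3°) through a random
  orthonormal map, so pairwise pattern distances are proportional to
  quadrant distances.  The embedding is drawn from `geometry_seed`
  (separate from the subject seed): subjects and modalities share
  representational geometry, as participants viewing identical stimuli
  would, which is what the RDV fusion analyses recover.
- `ε` is Gaussian with exponential spatial-decay correlation over the 2-D
  cap layout (nearest-neighbour correlation default 0.3) and optional
  moving-average temporal smoothing — structure for the whitening stage to
  remove.

fMRI patterns are simulated directly on the t-value scale:
`pattern = SNR_loc(ROI, clutter)·topo + SNR_cat(ROI, clutter)·topo + N(0,1)`
per run.  The per-ROI x clutter SNR map is the instrument for planting the
qualitative spatial result (early-visual-like ROIs informative only without
clutter, object-selective-like ROIs robust to it); defaults encode exactly
that gradient over V1…LOC with 325 voxels per ROI.  No haemodynamics or GLM
are simulated — the decoding consumes t-maps, so the generator produces
t-maps.  Feature banks use the same pattern model per layer with a
layer x clutter separability map.

**What passing tests do not show.**  The generator's noise is Gaussian and
stationary; there are no eye movements, no alpha rhythm, no autocorrelated
scanner drifts, no haemodynamic blurring, no anatomical variability, and
subjects differ only by topography resampling.  Recovery of planted
parameters therefore validates the *estimator chain* (no leakage, correct
averaging, correct inference arithmetic), not robustness to physiological
artifacts.

## Spatiotemporal analyses

- **Voxel searchlight**: sphere membership is decided on integer grid
  coordinates with squared distance ≤ radius² (257 voxels at radius 4,
  matching the lattice-point count); distances are in voxel units, not mm.
  Isolated voxels simply yield a one-voxel sphere; voxels outside the data
  grid carry NaN.
- **Channel searchlight**: the k = 5 nearest channels *excluding* the
  centre (reading "surrounding" literally; `include_center=True` preserves
  the alternative), stored at the centre, with the time axis down-sampled
  to 10 ms by non-overlapping bin means (means, not decimation — noise
  robustness).
- **Temporal generalization**: both epoch sets are first averaged into bins
  centred on the −100…600 ms, 10 ms grid (71 points); per iteration and
  cell, one SVM fit per train time predicts all test times at once.
- **Peak statistics**: the peak search window defaults to post-stimulus
  (0…600 ms) to exclude spurious pre-stimulus noise maxima.  Exact ties at
  the matrix maximum are broken to the entry closest to the diagonal (a
  conservative choice for any below-diagonal claim), then earliest train
  time, and flagged.  1-D peak ties break to the earliest time point.

## Inference

- **Wilcoxon signed-rank**, two-tailed, against 50% (accuracies) or 0
  (correlations, distances): zero differences are dropped; scipy's exact
  null is used for small samples without ties, the normal approximation
  with continuity correction otherwise.  The normal-approximation Z is
  always computed for the effect size r = Z/sqrt(N).
- **FDR**: Benjamini–Hochberg step-up at q = 0.05 (the standard reading of
  "FDR at 5%"), verified in the test suite against a brute-force step-up
  oracle.  Note that p = (0.01, 0.02, 0.04, 0.2) at q = 0.05 rejects
  exactly two hypotheses: the third threshold is 3·0.05/4 = 0.0375 < 0.04.
- **Bootstraps**: percentile CIs (2.5/97.5) over 10,000 subject resamples;
  latency differences use paired resampling with one-tailed
  p = proportion ≤ 0.  All bootstraps are bit-reproducible under a fixed
  seed.
- **Searchlight peak-distance null**: per-subject random swaps of the two
  condition labels, distance between the group-mean peaks per draw,
  one-tailed p = proportion of null distances ≥ observed.  This null is
  *conservative* when both conditions carry strong peaks at distinct sites:
  complementary label mixtures preserve both peak locations, so the null
  distance concentrates at the observed value.  It has power only when the
  condition maps are nearly exchangeable; treat a non-significant result as
  uninformative rather than as evidence of colocalization.

## Sizes used in the shipped validation

The test suite and `scripts/acceptance.py` run scaled-down copies of the
full design — typically 2 x 2 x 2 designs with 12–16 channels at 100 Hz,
2–12 binning iterations, 10–20 simulated subjects, and 200–500 bootstrap
resamples — sizes chosen so that every stage, including the searchlights
and the 200-experiment type-I simulation, completes in minutes on one CPU
while keeping Monte-Carlo error well below the tested effect sizes.  Counts
that the design fixes exactly (6, 12, 72, 360, 7,200 cells; 48/144
conditions; 257-voxel spheres; 71-point grids) are asserted at full scale,
since they cost nothing.  The chance-level acceptance check averages
≥ 10⁴ genuinely decoded scheme cells.

## Known limitations

- The RDV uses decoding accuracy directly as dissimilarity (no distance
  transform); any strictly monotone recoding would leave the Spearman
  fusion unchanged, but accuracies saturated at 100% compress rank
  information.
- Saturated decoding (plateaus at 100%) also makes peak *locations*
  unidentifiable; recovery guarantees hold in non-saturated SNR regimes.
- The per-subject-swap peak-distance null is conservative (above).
- Time-resolved decoding operates on single time points; temporal windowing
  or sliding averages beyond the 10 ms searchlight down-sampling are out of
  scope.
- ANOVA model fitting is out of scope; only the printed effect-size
  formulas are provided.
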
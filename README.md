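# crossdecode

Multivariate cross-decoding of object **location** and **category** from EEG
and fMRI measurements, with synthetic-data generators that plant known ground
truth so the entire analysis chain can be validated end to end.

## The scientific problem

When an object appears embedded in a cluttered scene, where and when does the
brain represent *where it is*, independently of *what it is*?  The analyses
in this package address that question with cross-decoding: a linear
classifier is trained to discriminate two object locations using trials from
one object category and tested on trials from a *different* category.
Above-chance transfer indicates a location representation tolerant to
category.  The same logic, with the factor roles swapped, measures
location-tolerant category information.

The package implements, for a fully crossed design of 4 categories x
4 screen-quadrant locations x 3 background-clutter levels (48 conditions;
144 at exemplar level):

- **Pairwise cross-decoding schemes** — all 6 location pairs x all 12 ordered
  category train/test pairs (72 cells; 360 with five-fold pseudo-run
  cross-validation in fMRI; 7,200 with 100 pseudo-trial randomizations in
  time-resolved EEG).  Chance is 50% throughout.  Classification is binary
  C-SVM with a linear kernel (libsvm via scikit-learn), C = 1.
- **Pseudo-trial construction** — random binning of 60 raw trials into
  4 pseudo-trials of 15 (EEG) or of 10 runs into 5 pseudo-runs of 2 (fMRI),
  plus multivariate noise normalization (Ledoit–Wolf-shrunk whitening of the
  within-condition residual channel covariance).
- **Searchlights** — voxel spheres of grid radius 4 (257 voxels when
  complete) and EEG channel neighborhoods (the 5 closest channels around
  each channel), mapping where the information resides.
- **Temporal generalization** — train at one time point in the no-clutter
  condition, test at every time point in the high-clutter condition on a
  10 ms grid over −100…600 ms (a 71 x 71 matrix).  The matrix peak
  (p_x, p_y) is summarized by its signed perpendicular distance from the
  diagonal,

  ```
  b_x = (p_x + p_y) / 2
  d_Euclidean = sqrt((p_x − b_x)^2 + (p_y − b_x)^2),  negated when p_x < p_y
  ```

  positive d means the test time lags the train time — a delayed but shared
  representational stage.
- **EEG–fMRI fusion** — a 72-entry representational dissimilarity vector
  (RDV) of per-cell cross-decoding accuracies, averaged over the EEG peak
  latency's 95% CI and over subjects, Spearman-correlated with
  subject-specific fMRI ROI RDVs.
- **Group inference** — two-tailed Wilcoxon signed-rank tests against chance
  with Benjamini–Hochberg FDR at q = 0.05; 10,000-resample percentile
  bootstraps for peak-latency CIs and latency differences (one-tailed
  p = proportion of resampled differences ≤ 0); a label-shuffle null for
  searchlight peak distances; effect sizes
  partial η² = SS_effect / (SS_effect + SS_residual) and r = Z / sqrt(N).

No real recordings are required: `crossdecode.simulate` produces EEG epoch
sets (trials x channels x time, −100…999 ms at 1 kHz, 63 channels), run-wise
fMRI t-value patterns (10 runs x 48 conditions x voxels on a labelled grid)
and layer-wise feature activations, all with planted location/category
signals whose latency, amplitude, ROI-wise SNR and cross-factor invariance
are configurable.  User-supplied data in the same containers (HDF5 epochs,
HDF5/NIfTI patterns) drop into the same functions.

## Worked example

The bundled desk-scale configuration simulates 10 subjects under a
2 x 2 x 2 design (12 channels at 100 Hz) with location signals planted at
140 ms (no clutter) and 300 ms (high clutter), then runs every stage:

```python
from crossdecode.pipeline import RunConfig, run_pipeline

bundle = run_pipeline(RunConfig.small(out_dir="demo_run", root_seed=0))
print(bundle["summary"])
for clutter, boot in bundle["eeg_peaks"].items():
    print(clutter, boot.estimate, (boot.ci_low, boot.ci_high))
```

prints (exactly reproducible for `root_seed=0`):

```
{'n_subjects': 10, 'n_significant_eeg_timepoints': 11,
 'n_significant_roi_cells': 3, 'n_significant_fusion_cells': 0}
no 170.0 (110.0, 170.0)
high 310.0 (280.0, 310.0)
```

Eleven EEG time points survive FDR; the group decoding peaks land at 170 and
310 ms — near the planted 140/300 ms latencies, at the resolution a
10-subject, 2-cell-scheme run affords — and the bootstrapped high-minus-no
latency difference (140 ms, one-tailed p < 0.001 in
`eeg_peak_differences.tsv`) recovers the planted 160 ms delay direction.
The temporal-generalization peak shift is positive (subject mean
d = 53 ms, Wilcoxon p = 0.021), the delayed-but-shared-stage signature.
ROI decoding reproduces the planted SNR gradient: the V1-like ROI decodes
location without clutter (84%) but not under clutter (58%), while the
LOC-like ROI decodes it in both (67% / 72%).  All tables are written as
tidy TSV under `demo_run/` together with `manifest.json` listing every
output file and the seed that produced it.

The same stages are scriptable from the shell:

```sh
crossdecode simulate eeg --config gen.json --seed 3 --out eeg.h5
crossdecode decode time --data eeg.h5 --clutter no --iterations 100 --seed 0 --out acc.tsv
crossdecode tempgen --data eeg.h5 --train-clutter no --test-clutter high --out tg.tsv
crossdecode run --seed 0 --out demo_run
```

## Layout

- `src/crossdecode/design.py` — design enumeration, pair schemes, geometry
- `src/crossdecode/simulate.py` — synthetic EEG / fMRI / feature generators
- `src/crossdecode/decoding.py` — pseudo-trials, whitening, SVM schemes
- `src/crossdecode/spatiotemporal.py` — searchlights, temporal generalization,
  peak statistics
- `src/crossdecode/fusion.py` — RDVs, fusion, Wilcoxon/FDR/bootstrap stack
- `src/crossdecode/io.py`, `pipeline.py`, `cli.py` — containers, the
  end-to-end driver, and the command line

See `docs/methods.md` for the generative model, parameter conventions and
known limitations.
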
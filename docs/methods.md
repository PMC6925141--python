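# Methods

## Problem and pipeline

`dwiprost` detects clinically significant prostate cancer (PCa; Gleason
score >= 7, ISUP grade group >= 2) from multi-b-value diffusion-weighted
MRI (DWI), at two levels: does an individual axial slice contain tumor,
and does the patient have PCa. The pipeline has three stages:

1. **Slice stage.** Each slice is converted into a 66x66x6 channel stack
   and classified by an ensemble of five independently trained residual
   networks, each emitting a PCa probability `p_ij` and its complement
   `n_ij` (member `i`, slice `j`).
2. **Aggregation stage.** Per member and patient, the probability sets
   `P_i = {p_i1..p_iN}` and `N_i = {n_i1..n_iN}` are filtered (top five
   values above a 0.74 cutoff) and summarized by nine first-order
   statistics each, giving 18 features per member and 90 per patient for
   the five-member ensemble. A decision-tree feature selector prunes the
   vector.
3. **Patient stage.** A random forest, trained on validation-set
   patients only, maps the selected features to a patient-level PCa
   probability.

The methodological backbone is strict set hygiene: training slices fit
the networks, validation data tune everything downstream (probability
cutoff, feature selector, forest), and the test set is scored exactly
once.

## Preprocessing

Each slice arrives as one 2D image per acquired b-value
(0, 100, 400, 1000 s/mm^2). Per pixel we fit the mono-exponential decay
`S(b) = S0 * exp(-b * ADC)` by least squares on `(b, ln S)` — the
clinical standard for apparent-diffusion-coefficient estimation.
Intensities are clamped to 1e-6 before the logarithm; fitted ADC is
floored at 0 (negative diffusivity has no physical meaning and arises
only from noise). The computed high-b-value image is the extrapolation
`b1600 = S0_fit * exp(-1600 * ADC)` using the fitted intercept, not the
measured b0 (on noiseless mono-exponential data the two coincide).

Channels are resized to 144x144 (bilinear; Gaussian anti-alias prefilter
when downsampling so mean intensity is conserved), center-cropped to
66x66 (odd margins floor toward the origin; all coordinates are 0-based
half-open), and stacked in the fixed order (ADC, b0, b100, b400, b1000,
b1600).

Normalization is the z-score `(X - mu) / std` with statistics computed
over **all pixels of the entire dataset**, but **per channel**: ADC
(~1e-3 mm^2/s) and raw intensities (~1e3 a.u.) differ by six orders of
magnitude, and a single global pair would leave the ADC channel
numerically invisible. Standard deviation uses the population convention
(divide by n). Pooling all three sets into the statistics mirrors the
original study's procedure and is the default; `preprocess_cohort`
accepts externally fitted (e.g. train-only) statistics for leakage-free
deployment.

## The slice classifier

A fully pre-activated bottleneck residual network, 41 weighted layers in
its default configuration: 7x7/64/stride-2 stem convolution, 3x3/stride-2
max pool, four bottlenecks at widths (64, 64, 256), nine at
(128, 128, 512), a final BN+ReLU, 7x7 average pooling, dropout
(drop probability 0.90), and a fully connected softmax head over two
classes. Weighted layers = 1 stem + 3x(4+9) block convolutions + 1 head;
projection shortcuts, pooling, batch norm and dropout do not count, so
`count_weighted_layers` obeys the closed form `2 + 3*(r1 + r2)`.

Each bottleneck applies (BN -> ReLU -> conv) three times (1x1 reduce,
3x3, 1x1 expand) on the residual branch and adds the input — through a
1x1 projection when width or resolution changes. Downsampling sits in
the first bottleneck of the second group (stride-2 on its 3x3
convolution), the standard placement. A zeroed residual branch makes the
block exactly the identity (or pure projection) map, which the tests
assert numerically.

Design points that were genuinely open and how they were fixed:

* **Head.** A single fully connected layer from pooled features to two
  outputs (consistent with the 41-layer count); an optional 1000-unit
  hidden layer is available via `ArchitectureConfig.hidden_units`.
* **Dropout rate 0.90** is interpreted as drop probability (the usual
  convention), applied to the pooled feature vector.
* **Loss.** Two-way softmax cross-entropy, which for two classes equals
  binary cross-entropy on the PCa probability; optional inverse-frequency
  class weighting is off by default.

Training is plain SGD: initial learning rate 1e-3, momentum 0.90, weight
decay 1e-6, batch size 8, learning rate divided by 10 when the
validation loss has not improved for 5 consecutive epochs (the patience
is configurable; only "divide by 10 on stall" is prescribed), up to 100
epochs. The ensemble trains `n_members = 5` networks on identical data
and hyperparameters with seeds `base_seed + k`; differing initial
weights, dropout masks and batch orders are the only source of member
diversity, exactly the randomness the stacking exploits.

The network engine itself (convolution via im2col, batch normalization,
pooling, inverted dropout, SGD, the plateau schedule — forward and
backward) is implemented in numpy inside `dwiprost.nn`, in float64,
single-threaded and seed-deterministic: identical seeds give bitwise
identical training histories. Backward passes are verified against
central finite differences to ~1e-7 relative error, and the convolution
forward against an independent `scipy.signal.correlate2d` oracle.

## Aggregation statistics

Filtering keeps the top five probabilities strictly greater than 0.74,
sorted descending (the cutoff was grid-searched on the validation set in
the original study and is kept as the package default; both `k` and the
cutoff are parameters). When nothing clears the cutoff the single
maximum is retained — otherwise every statistic of the empty set would
be undefined; this fallback is this package's choice. Filtering is
applied symmetrically to the PCa and non-PCa sets.

The nine statistics per filtered set: mean, standard deviation,
variance, median, sum, maximum (PCa set) / minimum (non-PCa set),
skewness, kurtosis, range. Conventions: population moments,
Fisher-Pearson skewness `m3 / m2^1.5`, Fisher (excess) kurtosis
`m4 / m2^2 - 3`; for a constant set both are the indeterminate form 0/0
and are defined as 0 to keep feature vectors finite. Feature order is
member-major (`cnn1_pca_mean .. cnn5_non_range`), and the vector is
invariant to slice order by construction.

The selector fits a depth-5 decision tree on each of 10 stratified CV
folds of the validation patients, averages Gini importances across
folds, and keeps features with importance above the mean nonzero
importance (or a fixed top-k via `n_keep`; the original run retained
26 of 90 — the count is data-dependent). The patient classifier is a
random forest tuned by a deliberately small stratified-CV grid,
{100, 300} trees x depth {3, 5, unlimited}: with ~48 validation patients
a larger tuning grid would overfit the tuning itself. All estimators are
scikit-learn, seeded.

## Evaluation

AUC is the Mann-Whitney concordance probability (ties one half),
computed by scikit-learn; the test suite verifies trapezoidal-ROC and
pairwise-concordance equality to 1e-10. Confidence intervals are
percentile bootstrap (default 2000 resamples, seeded); the resampling
unit is the patient at patient level and the slice at slice level, so
within-patient correlation cannot spuriously narrow patient-level CIs.
Resamples that lose a class are redrawn (capped). AUC differences
between two scorers of the same subjects use a paired bootstrap of the
difference with a two-tailed percentile p-value. The original study does
not identify its CI method, so these intervals are well-defined but not
guaranteed to match its printed ones.

## Synthetic cohorts

`generate_cohort` produces phantom cohorts whose per-(set x label)
patient and slice counts are specified exactly and reproduced by
construction; the default composition is the published 427-patient
cohort (train 105 PCa / 166 non-PCa patients with 439 / 3,253
tumor / non-tumor slices; validation 18/30, 66/588; test 52/56,
226/1,260 — 5,832 slices in total, ~14 per patient). Count-specified
generation sidesteps the unreported rounding that produced 271/48/108
from a 75% / 85% two-stage split; the `split` module implements that
split generically (per-stratum `round(ratio * n)`, remainder to the
larger side) and lands within +-2 of the published sizes.

Phantom physics: per patient one S0 (~N(1000, 50) a.u.) and one
background ADC (~N(1.5e-3, 1e-4) mm^2/s); each slice is the
mono-exponential decay at the four acquired b-values with multiplicative
Gaussian noise (sigma = 0.05 by default — Rician noise is deliberately
not modelled). Tumor slices of a PCa patient form one contiguous block
and share one elliptical lesion (axes 3-8 px) whose ADC is
`lesion_adc_factor = 0.5` of background — restricted diffusion, hence
dark on ADC and bright at high b. Lesions are placed entirely inside the
preimage of the 66x66 center crop, mirroring the acquisition premise
that the crop covers the prostate. Tumor-slice counts per PCa patient
default to the range 1-6: the published per-set totals imply an average
of ~4.2 tumor slices per PCa patient, so the generator errors if the
requested range cannot meet the requested totals. The default raw grid
is 64x64 (configurable): it keeps a full 427-patient cohort to a few
hundred MB, and preprocessing resizes to 144 and crops to 66 exactly as
it would for scanner-resolution data.

`simulate_probability_sets` bypasses imaging entirely: slice
probabilities are drawn from Beta(8, 2) for tumor slices and Beta(2, 8)
otherwise, with per-member Gaussian jitter (sigma = 0.05), standing in
for trained-network outputs when the aggregation stage is tested in
isolation.

What the phantoms do **not** emulate: anatomy, partial-volume and
motion effects, Rician noise, scanner drift, inter-reader label noise.
Passing tests therefore demonstrate correctness of the pipeline's
machinery and its behavior under a controlled, separable signal — not
clinical performance. The published clinical AUCs (0.87 slice-level,
0.84 patient-level) require the private 427-patient cohort and
GPU-scale training and are outside what this package can or tries to
reproduce.

## Scaled-down study sizes

The `tiny` preset (`dwiprost.tiny_config`) is the configuration used by
the end-to-end tests and the worked example: 40 patients
(train 8 PCa + 8 non-PCa, 96 slices; validation and test 6+6, 64 slices
each), the reduced architecture (block repeats 1/1, widths 16/32, 8
weighted layers), 10 epochs, batch 8, learning rate 0.01, dropout 0.25,
500 bootstrap resamples. The raised learning rate and lowered dropout
are deliberate: the full-scale values (1e-3, 0.90) are tuned for a
cohort two orders of magnitude larger, and at 96 training slices they
leave the reduced network badly underfit within 10 epochs. On this
preset the phantom signal is separable by construction and the pipeline
reaches slice- and patient-level AUC >= 0.95 / >= 0.90 on the held-out
test set, while refitting the patient level on permuted validation
labels collapses to chance (mean null AUC within 0.5 +- 0.1 over 10
permutations). Determinism checks run an even smaller 18-patient
configuration twice and require bitwise-equal histories, probabilities
and metrics.

## Numerical and degenerate-input conventions

* Signal floor 1e-6 before logarithms; `b_target < 0` rejected.
* Zero-variance channels make normalization statistics invalid and
  raise; z-scoring is exactly invertible (`denormalize`) to 1e-10.
* Center-crop tie-break: floor of half the margin (window [39, 105) for
  144 -> 66).
* Single-class training sets warn and proceed (the loss stays defined);
  single-class inputs to selector, forest or AUC raise.
* All-constant feature matrices fall back to keeping the single
  best-ranked feature.
* Empty probability sets cannot reach the statistics layer (the filter
  fallback guarantees one element).

## Known limitations

* The numpy engine is single-threaded and CPU-bound; the full 41-layer
  network is buildable and verifiable (and its forward pass runs), but
  training at the published scale is out of reach by design — the
  reduced configuration is the supported training path.
* Batch-norm statistics at batch size 8 are noisy; running statistics
  use momentum 0.1, so very short trainings evaluate with
  close-to-initial running estimates.
* The feature selector's retained count is data-dependent; on phantom
  data a single dominant feature (typically `cnn*_pca_max`) often
  suffices, which is expected given the phantoms' clean separability.
* NIfTI I/O assumes one volume per b-value with slices on the last
  axis and an identity affine; DICOM and scanner-specific corrections
  are out of scope.
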
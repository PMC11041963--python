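# Methods

This note documents the models, numerical choices and limitations of
`pulsetherm`, and what its simulation-backed tests do and do not show.

## Scope and model overview

The package estimates cardiac activity from facial skin-color traces
(remote photoplethysmography, r-PPG), derives heart-rate-variability
(HRV) measures from it, computes segment-change features from facial
thermal-imaging ROI traces, and combines both modalities in classifiers
of a two-state (baseline vs stimulus) design. It deliberately starts
from *per-ROI traces*, not video: face detection, landmark tracking and
patch averaging are upstream concerns with their own mature tooling.

## Pulse extraction (POS)

Each ROI's RGB trace is converted to a blood volume pulse with the
plane-orthogonal-to-skin projection. Within a sliding window of 1.6 s
(hop of one sample), each channel is divided by its window mean; the
normalized channels are projected onto `S1 = G − B` and
`S2 = −2R + G + B`, combined as `h = S1 + (σ(S1)/σ(S2))·S2` with σ the
population standard deviation in the window, mean-centered, and
overlap-added. Temporal normalization makes the output exactly
invariant to per-channel constant gain — the property the test suite
asserts bit-tightly. A window with `σ(S2) = 0` (constant input) uses a
ratio of 0 and contributes `S1` alone.

## Windowed spectral heart rate

The BVP is cut into overlapping 6-s windows (default hop 1 s). Each
window is mean-removed, Hann-tapered, zero-padded to a frequency grid of
at most 0.25 BPM, and the in-band (0.65–4.0 Hz, i.e. 39–240 BPM)
magnitude argmax gives HR = 60·f. Choices worth noting:

* **Hann taper.** With a rectangular window, sidelobes of a secondary
  spectral component can drag the argmax a few tenths of a BPM off a
  pure tone; the taper confines this far below the grid spacing.
* **Zero-padding, not peak interpolation.** A ≤0.25 BPM grid is cheap
  at these window lengths and makes the estimate exactly reproducible.
* **All-zero windows** yield a missing HR rather than an arbitrary bin.

Per-ROI HR series are combined per window by the **median** across ROIs,
which tolerates the occasional corrupted patch that the quality index is
designed to flag. The quality index is MAE/HR: the mean absolute
deviation of per-ROI window HR from the aggregate, divided by the mean
aggregate HR — zero exactly when every ROI agrees everywhere, scale-free
by construction.

## HR cleaning and HRV

HR points that jump by more than 25 BPM from their predecessor are
resolved by deleting whichever of the two points lies farther from the
median of the full series (ties delete the later point), re-examining
the newly adjacent pair, until no violation remains. The median is that
of the *input* series and is not recomputed during the sweep; this makes
the rule a deterministic function of the input and keeps it idempotent.
Surviving HR values become NN intervals via `NN = 60000/HR` ms; values
outside 300–2000 ms are treated as conversion artifacts and dropped
(the bounds mirror the HR search band and are configurable).

Time domain: SDNN is the sample standard deviation (n−1 denominator);
rMSSD the root-mean-square of successive differences; pNN50 the
percentage of successive differences *strictly* greater than 50 ms.
With fewer than 3 intervals, rMSSD/pNN50 are reported missing while
SDNN still requires only 2.

Frequency domain: the NN tachogram is resampled at 4 Hz by cubic
interpolation, mean-removed, and a Welch periodogram (64-s segments,
50% overlap) is integrated over LF = 0.04–0.15 Hz and HF = 0.15–0.40 Hz
(Task-Force band edges), reported as natural logs of ms² powers. ULF
and VLF need recordings far longer than the 120-s analysis segments and
are not computed. Band powers at or below 1e−12 ms² (numerically zero,
e.g. a constant tachogram) are reported missing with a warning.

Segment analysis uses non-overlapping 120-s segments; each segment is
filtered and converted independently, and last-minus-first deltas are
emitted per measure. Within a 120-s segment the window centers span
slightly less than 120 s, so the frequency-domain coverage requirement
is 75% of the segment length there.

## Thermal features

Per ROI (22 regions: eyebrows, forehead, nose, nostrils, lips, cheeks,
chin, throat), the feature set is: mean of the first and last 120-s
windows (windows with under 50% of nominal frames are missing), their
difference (absolute change), the change referenced to the forehead
(ROI 58, the most thermally stable facial region — any additive common
drift cancels exactly), and the antisymmetric 22×22 matrix
`M[i, j] = change_j − change_i` of pairwise change differences.

## Fusion models

Records are classified baseline vs stimulus with an RBF-kernel SVM or a
random forest under stratified 5-fold cross-validation *grouped by
subject* (a subject's records never straddle folds), with feature
standardization and a hyperparameter grid search fitted inside each
training fold (3-fold inner CV, also grouped). Grids: SVM
C ∈ {0.1, 1, 10, 100}, γ ∈ {scale, 0.01, 0.1, 1}; RF 100 trees with
max depth ∈ {None, 3, 5} and min leaf ∈ {1, 3}. One hundred trees are
ample at the ~100-record studies this package targets, so the search
spends its budget on the regularizing parameters; deeper tree grids
mostly add selection noise at this sample size. Accuracy and the
stimulus-class F1 are averaged over outer folds; everything is seeded.

Early fusion concatenates both modalities' features before one
classifier. Late fusion fits one model per modality per outer fold and
trains a depth-2 Gini decision tree on their class probabilities; the
tree is trained on *cross-fitted* (out-of-fold) probabilities of the
training records so it never sees resubstitution scores. SVM
probabilities come from cross-fitted Platt-style calibration of the
tuned margin classifier.

## Shapley attribution

Feature importance is the mean absolute Shapley value of the model's
positive-class probability, estimated by Monte-Carlo permutation
sampling: per sampled permutation, features are switched one at a time
from a background record to the explained record and each feature is
credited the induced output change, averaged over 24 permutations and a
64-record background sample. The estimator is unbiased for the exact
Shapley value, deterministic given its seed, and gives *exactly* zero to
features the model's output never depends on. Near-tied importances can
swap ranks between seeds; the tests therefore check rank stability only
where importances are well separated.

## Quality sweep and statistics

The quality sweep retains recordings whose MAE/HR index is at or below
each threshold and reports the Pearson correlation (and p) between
r-PPG-derived and reference-derived values per measure, with the
retained n; thresholds keeping fewer than 3 recordings are marked
insufficient. Change scores are tested against zero with one-sample
two-sided t-tests; the HRV-change × thermal-change correlation map
reports raw Pearson p-values with a p < 0.05 mask (an optional
Benjamini–Hochberg mask exists but is off by default, matching the
reporting convention of raw-p heatmaps).

## Synthetic data: what it emulates, and what it does not

* **Beat series** are built by direct NN-sequence construction:
  `NN(t) = 60/HR + a_LF·sin(2π·0.095·t) + a_HF·sin(2π·0.275·t) + ε`,
  laid down cumulatively. The modulation frequencies sit at the centers
  of the LF and HF bands so programmed power lands unambiguously inside
  them; integral pulse-frequency modulation would be more physiological
  but less transparent as ground truth.
* **RGB traces** embed a unit-peak pulse train (one asymmetric Gaussian
  per beat, rise σ 0.09 s, decay σ 0.25 s) multiplicatively with
  channel weights G:R:B = 1.0:0.6:0.3 (hemoglobin absorbs green most
  strongly), plus a slow common illumination drift and white sensor
  noise. Default pulse amplitude 1% of baseline, noise 0.2–0.3%.
* **Thermal traces** realize each programmed group effect as a linear
  ramp whose first/last 120-s means differ by exactly the effect, plus
  an optional common drift, AR(1) noise (coefficient 0.9) and randomly
  missing frames, at 8 fps (thermal cameras run slower than RGB).
* **Labeled studies** draw per-subject HRV measures and ROI
  temperatures from population distributions with subject random
  effects shared between a subject's baseline and stimulus records;
  the stimulus record adds the programmed shifts (HR up, HRV measures
  down, lip/cheek warmer under cognitive stress; nose-to-chin warmer
  under elevation). Records are generated at the *measure* level —
  the full trace→POS→HRV chain is exercised separately by the recovery
  tests, and generating it per subject would add nothing to what the
  classification tests can show.

None of the generators model motion, occlusion, illumination flicker
beyond a smooth drift, or non-stationary HR trends. Passing tests
demonstrate that the algorithms recover what they are defined to
recover under the stated signal model; they say nothing about
performance on real, motion-contaminated recordings, where signal
quality — as the MAE/HR index is designed to expose — varies widely.

## Problem sizes

The test suite and the reproduction script use 5-min recordings at
30 fps (RGB) and 8 fps (thermal), 6–8 ROIs for the r-PPG path, studies
of 30–60 subjects (two records each), 10-seed replication for
stochastic properties and 1000 replicates for the type-I calibration —
sizes at which every property they assert is already stable.

## Known limitations

* `hr_to_nn` treats each window's HR as one pseudo-NN interval; this is
  a rate-domain approximation of true beat-to-beat variability, and HRV
  from windowed spectral HR systematically smooths fast variability
  (visible in the HF band above all). The reference-beat path
  (`beats_to_nn`) computes HRV from true intervals.
* The jump filter's one-comparison rule can, for pathological
  alternating series, remove many points; the survivors are always a
  subsequence and the result idempotent, but short segments may become
  unusable (reported as an error rather than guessed at).
* Grid values, band edges and NN bounds are defaults, not re-estimated
  per dataset; all are exposed in the pipeline configuration.
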
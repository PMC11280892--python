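# Methods

`pdeeg` implements a complete two-class (Parkinson's disease vs. control)
resting-state EEG classification pipeline built around *channel selection by
single-channel evaluation*: every electrode is scored by how well a simple
classifier trained on that electrode's features alone separates the groups
on held-out subjects, and only electrodes whose R² score reaches a threshold
enter the final multi-channel model.  Because the public cohorts the method
is designed for cannot be bundled, the package ships a synthetic cohort
generator that reproduces their structure, so every stage of the pipeline is
exercisable and testable end to end.

## Synthetic cohorts

Each recording is synthesized in the frequency domain as a random-phase
surrogate of a target one-sided power spectrum, then inverse-FFT'd:

* **Background**: 1/f-weighted broadband noise over (0, 100] Hz with total
  standard deviation `background_sd` (default 10 µV).
* **Rhythms**: flat-topped oscillator bumps in delta (1–4 Hz), theta (4–8),
  alpha (8–13) and beta (13–30) with default total powers 20, 10, 15 and
  5 µV² — plausible relative magnitudes for resting scalp EEG.
* **Eye state**: eyes-closed recordings multiply alpha power by 1.5
  (configurable), emulating the classic alpha blocking contrast.
* **Heterogeneity**: each subject draws one log-normal multiplier for the
  background and one per rhythm (`per_subject_sd`, default 0.4 on the
  log-power scale, shared across channels), plus a small per-channel
  log-normal jitter (sd 0.1).  The subject-level multipliers are what makes
  classification non-trivial: at a planted power ratio of 4 the
  between-group log-power separation is ln 4 ≈ 1.39 against a subject noise
  of ≈ 0.4, i.e. a strong but not degenerate effect (linear-SVM subject
  accuracy ≈ 0.9–1.0).
* **Planted effect**: for disease-group subjects, spectral power inside one
  sub-band is multiplied by `power_ratio` on a chosen channel subset, so
  "informative channels" exist by construction and their recovery is
  measurable.  `power_ratio = 1` produces an exact null cohort.

Two 64-channel montages are shipped (10-10 labels, online references CPz and
Pz respectively) whose channel lists share exactly 59 names; montage
harmonization restricts any recording to that common set in lexicographic
order, which makes flattened feature vectors from either site align
column-for-column.

The generator deliberately does **not** model ocular/muscle artifacts,
line-noise beyond what the notch stage is tested with, volume conduction, or
any claim about real PD electrophysiology (which spectral contrast separates
the groups, and on which channels, is an engineering choice, not a
physiological one).  Passing tests therefore demonstrate that the pipeline's
machinery — filtering, feature extraction, scoring, selection, evaluation —
behaves correctly and recovers planted structure; they say nothing about
classification accuracy on real patients.

## Preprocessing

Broadband filtering is a zero-phase (forward–backward) 4th-order Butterworth
band-pass, 0.1–100 Hz, plus 2nd-order IIR notches (quality factor 30) at 60
and 180 Hz.  Zero-phase application avoids group-delay misalignment between
channels; the trade-off is that the effective magnitude response is squared.
Each 60 s event (30,000 samples at 500 Hz) is cut into 15 consecutive,
non-overlapping 2000-sample segments starting at sample 0; trailing samples
are dropped.  Artifact removal (e.g. ICA) is outside the package; a
`pre_filter_hook` callback on `apply_filters` is the plug-in point.

## Feature extraction

Six analysis sub-bands are used: delta 1–4, theta 4–8, alpha1 8–10,
alpha2 10–13, alpha 8–13, beta 13–30 Hz (boundaries shared, alpha nesting
deliberate).  Two parallel paths extract per-(channel, segment, band)
features:

**Band-pass path (13 features/band).**  Each segment is restricted to each
band by a zero-phase 4th-order Butterworth band-pass.  Features: mean,
absolute mean, power mean (mean of squared samples), population standard
deviation, excess kurtosis, skewness, mean absolute deviation
(MAD = (1/m)·Σ|xᵢ−u|), interquartile range (linear interpolation), RMAV,
three periodogram statistics — frequency center Σf·P(f)/ΣP(f), mean spectral
amplitude (1/K)·ΣP(f), RMS frequency √(Σf²·P(f)/ΣP(f)) — and sample entropy
(m = 2, r = 0.2·std, Chebyshev distance, self-matches excluded; 0 for a
constant signal by convention, +∞ flagged when no template match extends).

RMAV (ratio of absolute mean values between sub-bands) is defined once per
band: band *k* is paired with band *k+1* in the order above, and the last
band with the 1–30 Hz broadband signal.  This keeps exactly 13 features per
band, so one subject/eye-state yields 59 × 15 × 6 × 13 = 69,030 values.
"Frequency center" and "mean value of frequency" are implemented as the
distinct statistics above; they are sometimes treated as synonyms in the
literature, so the choice is documented rather than inferred.

**Wavelet-packet path (9 features/node).**  Each segment is decomposed with
the db5 wavelet to depth 6; six nodes are used, in printed tree-path order:
AAAAAA6, AAAAAD6, AAAADA6, AAAADD6, AAAAD5, AAAD4.  The same eight
time-domain kernels plus RMAV (node *k* vs. node *k+1*; last node vs. the
concatenation of all six nodes' coefficients) are computed on the raw
coefficient vectors, giving 59 × 15 × 6 × 9 = 47,790 values per
subject/eye-state.  Note the natural (tree) node order and ascending
frequency differ by a Gray-code permutation — e.g. AAAADD6 is 7.8–11.7 Hz in
frequency order; `node_frequency_band` computes both mappings, and the
package keeps the printed tree order rather than silently reordering.

Boundary extension is zero-padding: under an orthogonal wavelet this makes
every level's leaf energies sum exactly to the segment energy (Parseval),
which the tests assert to 1%.  Symmetric extension — a common default — was
rejected because reflected padding inflates deep-level boundary-coefficient
energy by far more than 1% on 2000-sample segments.  Coefficient statistics
include boundary coefficients.

Both paths share one set of statistic kernels (asserted equal in tests), and
the cohort-scale drivers are vectorized across channels/segments but
numerically equivalent to the per-segment functions.

## Channel selection

Subjects are split 70/30 (stratified by group, fixed seed).  For each
channel, that channel's (segment × band × feature) values are flattened to
one vector per subject, z-scored with training-subject statistics, and a
linear-kernel SVM is fit on training subjects; the R² score (coefficient of
determination of the 0/1 predictions) on validation subjects is the
channel's score.  For balanced labels R² = 4·accuracy − 3, so the default
threshold 0.7 demands ≈ 92.5% held-out accuracy.  Selection keeps channels
with R² ≥ 0.7 (the threshold is inclusive: only scores *below* 0.7 are
rejected).  Per-method selections are combined by set union or intersection.
The package ships the 11-channel (band-pass) and 22-channel (wavelet)
reference selections as plain-text fixtures; their intersection is
{Oz, P8, FC5, O1} and their union has 29 channels.

## Classification and evaluation

The flattened per-subject vectors, restricted to a selection scheme and
z-scored on the training split, feed eight classifiers: logistic regression
(max 5000 iterations), KNN (k = 7), linear-kernel SVM, AdaBoost (learning
rate 0.01, ≤ 50 estimators), XGBoost with tree (learning rate 0.01, gamma
0.05) and linear boosters (gamma is tree-specific and not passed to the
linear booster), random forest (100 trees), and a dense neural network.
The network is a single 512-unit hidden layer trained with Adam on log-loss
(sklearn `MLPClassifier`, batch size 8, ≤ 200 epochs, plateau stopping, L2
α = 10⁻³ standing in for dropout, which sklearn does not expose).
Hyperparameters are fixed defaults serialized into every report; a grid
search is deliberately not rerun.

Three designs are provided: subject-stratified hold-out (default 70/30);
10 rounds of 3-fold stratified CV with per-round reshuffling (30 reports);
and cross-cohort out-of-sample testing, fitting on all of one cohort
(eyes-open only, or pooling both eye states as separate samples) and
testing on the other cohort's eyes-open recordings, with scaling statistics
from the training cohort only.  Reports carry accuracy, sensitivity
(PD = positive), specificity, ROC AUC (decision scores where available,
midrank ties), R², `n_test` and full provenance.  Optionally the training
R² is recorded to quantify the train/validation gap — with all 59 channels
the gap is larger than with the planted/selected channels, reproducing the
overfitting rationale for channel selection as a directional property.

## Numerical and testing choices

* Determinism: every stochastic component takes a seed; cohorts derive
  per-subject seeds from a `SeedSequence`, so single recordings are
  reproducible in isolation.
* Degenerate inputs: zero-variance segments produce defined time-domain
  statistics, sample entropy 0, and flagged (invalid) spectral/RMAV slots;
  invalid blocks propagate as missing channel scores rather than NaNs.
* Sample entropy is an O(n²) template count (numba-jitted, with a numpy
  fallback); a naive brute-force implementation exists only in the tests as
  the independent oracle.
* EDF export uses a built-in minimal 16-bit writer whose affine scaling is
  derived from the header's truncated ASCII physical range, so a compliant
  reader (mne, used in tests as the independent read path) inverts it to
  within half a quantization step.
* Stochastic acceptance-style checks run at the study's cohort sizes
  (27 + 26 subjects, 20 Monte-Carlo seeds, effects planted on Oz and P8)
  but on 12 s eyes-open recordings (3 segments of 2000 samples) and the
  wavelet feature path; these problem sizes are the package's chosen
  trade-off between statistical resolution and a single-CPU test run.
  The full 60 s × 15-segment geometry is exercised where the quantity
  depends on it (dimensional bookkeeping).

## Known limitations

* The generator's stationary, artifact-free, linear-superposition signals
  are far cleaner than real EEG; selection thresholds tuned here should not
  be read as clinical recommendations.
* The alpha1/alpha2 wavelet nodes inherit the Gray-code frequency ambiguity
  discussed above; both interpretations are computable but the default
  follows the printed tree paths.
* `cross_validate` evaluates per-subject vectors; per-segment voting
  schemes are not implemented.
* The dense network is a sklearn approximation of a dropout-regularized
  two-layer Keras model; with the small cohort sizes involved its variance
  across seeds is large.
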
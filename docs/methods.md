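# Methods

## Signal model

A measurement is a 260 s acquisition on a uniform 100 ms grid (2601
timestamps) over 8 MOS gas channels (S1–S8) plus temperature and humidity.
The instrument protocol defines three phases: delay [0, 20) s (reference
air; baseline), sampling [20, 140) s (sample headspace), purging
[140, 260] s (flush). Phase boundaries are mapped to the grid with
half-sample-step thresholds so floating-point jitter on the time axis can
never move a sample across a phase boundary.

The simulator's noise-free response is the simplest kinetic that produces
the trapezoidal shape characteristic of MOS chemoresistors:

* delay: 0;
* sampling: first-order saturation `A (1 − exp(−(t − 20)/τ_rise))`;
* purging: exponential decay from the 140 s peak with constant `τ_decay`.

The trace is continuous at both phase boundaries. MOS adsorption/desorption
chemistry, sensor drift beyond a linear term, and humidity–response coupling
are deliberately not modelled.

## Class profiles

Plateau amplitudes encode the qualitative VOC fingerprints seen by this
sensor family. All classes share a hydrocarbon response on
{S1, S2, S4, S5, S7, S8} and an alcohol response on S3 over a fixed
per-channel base amplitude (0.7–1.3 V). Two dials control the class
geometry:

* `separation_margin` (default 0.5 V): pork's unique aldehydes and alcohol
  raise {S1, S2, S5, S7, S8} and S3. Pork is offset by
  `separation_margin + overlap_margin` so its gap to *both* non-pork
  classes is at least `separation_margin` on those channels.
* `overlap_margin` (default 0.1 V): chicken's unique ether/ester compounds
  add the full margin on {S1, S3, S7, S8} and half of it on the remaining
  hydrocarbon channels; S6 is identical between beef and chicken. Beef and
  chicken therefore differ nowhere by more than `overlap_margin`.

Response kinetics also differ mildly by class (rise/decay τ: beef 12/25 s,
chicken 14/28 s, pork 10/20 s), which is what window slicing exploits: a
single whole-trace statistic is blind to kinetic differences that
per-window statistics resolve. The beef and chicken constants are kept
close together by design — the benchmark's defining property is that beef
and chicken overlap while pork is well separated, and the package's own
acceptance checks (the pork-vs-nonpork centroid distance dominating
beef–chicken at every window count) constrain how far their kinetics may
diverge.

## Noise model

The study's instrument noise is not characterized anywhere we could draw
from, so the defaults are stated choices of plausible magnitudes, not
inferred values: per-record baseline offset sd 0.02 V, additive white noise
sd 0.02 V per sample, plateau amplitude coefficient of variation 0.06,
linear drift slope sd 1e-4 V/s. Environmental channels are slowly drifting
constants around 25 °C and 55 %RH (lab ambient), with offset and drift
scales tied to the gas-channel noise parameters so an all-zero noise spec
yields exactly constant traces.

With these defaults the designed benchmark (seed-reproducible,
100 records/class) behaves like the study it emulates: a whole-trace (W0)
maximum feature leaves beef/chicken partially confused (LDA testing
accuracy ≈ 87%), while five windows separate all three classes completely
(LDA testing accuracy 100%).

## Reproducibility

Every record's random stream is a `numpy.random.SeedSequence` child of the
master seed with spawn key `(class_index, record_index)`, so datasets are
bit-reproducible, order-independent, and any single record can be
regenerated in isolation. Random draws are consumed in a fixed order
regardless of parameter values, so setting one noise term to zero does not
shift the others. Derived seeds (per model configuration, per CV run) use
the same spawn-key scheme reduced modulo 2^31 for scikit-learn.

## Feature extraction

Baseline correction subtracts each gas channel's t = 0 reading
(idempotent; environmental channels untouched). The sensing region is
[20, 200] s, treated as closed on both ends (1801 samples); W0 uses the
full [0, 260] s trace (2601 samples). Hard-sliced windows are half-open
`[edge_i, edge_{i+1})` with the final window closed at 200 s, so every
sample belongs to exactly one window.

Two feature families are implemented because the method is described via
bell-weighted areas while the headline results are keyed to the four order
statistics; `slice_stats` is the default.

* Statistics: max, min, mean, and a positional median (sort ascending;
  even N averages the two central values; odd N takes the middle one —
  the even-N rule is the printed convention, the odd-N rule the natural
  completion).
* Bell areas: `W_i = Σ R(t_k) K_i(t_k) Δt` with
  `K_i(t) = 1/(1 + |(t − c_i)/a_i|^{2 b_i})`. Defaults: centre c_i at the
  window midpoint, half-width a_i at half the window span, shape b_i = 5 —
  steep enough to be near-rectangular (at b = 50 the weighted area matches
  the rectangular one within 1% on smooth signals) while staying smooth.
  No b value is prescribed anywhere; 5 is a documented choice.

Feature counts follow the 8 / 8n + 2 convention (8, 10 and 42 columns at
W0, W1, W5). The +2 environmental summaries (mean temperature/humidity
over the sampling phase) are appended only for W ≥ 1; this reproduces the
printed counts, which exclude the environmental channels at W0.

## Chemometrics

Standardization centres to mean 0 and scales to sample sd 1 (ddof = 1);
fitted parameters are retained so held-out rows are transformed with
training statistics; zero-variance columns are centred and scaled by 1
with a logged warning.

PCA is an SVD of the column-centred matrix. Component signs are fixed by
forcing the largest-magnitude loading positive, so score plots do not flip
between runs. Requesting more components than the numerical rank is an
error rather than a silent truncation.

Cluster separation is the Euclidean distance between per-class centroids
in full standardized feature space (a PC-subspace option exists since the
distance analysis is usually paired with dimension reduction; the space
used in the original analysis is unstated, and the full feature space is
the choice that involves no extra truncation parameter). The pork–nonpork
distance uses the pooled beef+chicken centroid, which for balanced classes
is the midpoint of the two centroids. Note the printed form of the
distance formula omits the square on the difference term; the quantity is
named and used as a Euclidean distance, so the standard squared-difference
form is implemented.

## Supervised protocol

One stratified 75/25 split (225/75 rows at the default size) is drawn per
run seed and shared across every (family × statistic × window)
configuration, mirroring a single database split; stratification is a
design choice (plain random sampling would only add size jitter around the
same balanced expectation). Validation accuracy is the fold-level mean (±
sample sd) over 10-fold stratified CV repeated 10 times on the training
portion, with standardization refitted inside every CV-training portion —
no validation fold or test row ever reaches the fitted parameters.
Aggregation over folds (rather than pooling predictions) is used; with
equal-sized stratified folds the two differ negligibly.

Model details:

* LDA/QDA: scikit-learn Gaussian discriminants; QDA uses a 1e-6 ridge on
  the per-class covariance (with the rank tolerance set below the ridge so
  regularized covariances are always accepted). QDA inherently needs more
  samples per class than features in every CV-training portion; at the
  default 300-record benchmark that holds up to W5 (67 > 42).
* k-NN: Euclidean metric, majority vote over k = 5 neighbours; tied votes
  resolved by the single nearest neighbour's class, equal distances by
  lowest training index — a deterministic rule scikit-learn's stock
  classifier does not provide, hence the thin custom estimator over
  `NearestNeighbors`.
* RF: 500 trees, mtry = 6 features per split, tree seeds derived from the
  run seed.

Accuracies are reported in percent to one decimal place.

## Problem sizes in the shipped tests

The test suite runs the full benchmark (300 records) for the structural,
distance and headline-accuracy checks, and scaled-down grids (20 records
per class, W0/W1, 20-tree forests, 1–2 CV repetitions) for the exhaustive
model-grid and permutation-null checks. The chance-level band for the
permutation null is computed from the actual number of validation
predictions (4σ binomial around 33.3%), so fewer repetitions widen rather
than narrow the tolerance. The paper-scale default pipeline configuration
(W0–W6 × 4 statistics × 4 families at 10×10 CV with 500-tree forests)
remains available through `run_pipeline` / `enoseslice report`; it is a
long run and is not exercised at full scale by the tests.

## What passing tests do and do not show

The generator reproduces the *design* of the study (record counts, grid,
phases, class geometry, balanced classes) and a qualitative response
shape; it does not reproduce the real instrument's noise spectrum, sensor
aging, inter-device variation, or genuine VOC chemistry. Passing the
benchmark checks therefore demonstrates that the pipeline's machinery —
correction, slicing, feature conventions, no-leakage CV, model wiring — is
correct and that the window-slicing mechanism behaves as described on data
engineered to have the study's cluster structure. It does not certify the
accuracies attainable on real meat-floss measurements.

## Known limitations

* Trapezoidal kinetics are first-order only; real MOS sensors show
  channel-dependent asymmetries and memory effects.
* The amplitude table is qualitative (detected / not detected per channel
  scaled by two margins); real spectra differ by compound concentration.
* QDA cannot be fitted when a CV-training class has no more samples than
  features (a scikit-learn SVD-solver constraint), so QDA columns of a
  report require window counts small enough for the dataset size.
* `bell_area` at W0 degenerates to the plain rectangular area of the full
  trace (there is no window to centre a bell on).
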
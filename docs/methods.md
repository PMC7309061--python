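# Methods

This note documents the models, numerical choices and design decisions in
`nits`, and what the synthetic cohort does and does not demonstrate.

## Session model

A session is one visit of one subject: a demographic profile, per-task
payloads keyed `T0`..`T15`, and one duration (seconds) per task.
Sessions serialize to JSON (schema tag `nits-session/1`); coordinates are
screen pixels with origin top-left and y increasing downward (the native
touchscreen convention), timestamps are integer milliseconds from task
start.  Audio is PCM WAV only (16-bit or float; stereo averaged to
mono); recordings are referenced by path, never embedded in the JSON.

## Geometric scoring

**Reference spiral.**  The displayed Archimedean spiral is `r =
(spacing/2π)·θ`, sampled uniformly in θ; defaults are 3 turns, 256
points, and a spacing that spans 80% of the shorter screen dimension.
Counter-clockwise reflects about the vertical axis through the center.

**Discrete Fréchet distance.**  The standard O(n·m) dynamic program over
monotone couplings with the Euclidean ground metric, JIT-compiled with
numba when available (pure-python fallback otherwise).  Inputs longer
than 512 points are resampled by arc length first.  Per-path comparisons
against an ideal straight edge resample both curves to a common 64-point
arc-length grid, so a perfectly straight stroke scores exactly 0.

**Percentage match.**  Fraction of drawn points whose nearest reference
point lies within a radius (default 2% of the screen diagonal for the
spiral task).  Invariant to point order and monotone in the radius.

**Parallel lines.**  Edge slopes come from a total-least-squares line fit
(robust to vertical strokes, flagged as slope `None`); the angle between
slopes m1, m2 is `atan(|m1−m2| / |1+m1·m2|)`, 90° when the denominator
vanishes.  The cube task checks 9 designated parallel edge pairs with a
10° tolerance and passes at ≥ 50% of pairs within tolerance.  The
published methodology counts 9 pairs although a cube has more; which 9
is a configured convention here (`CUBE_PARALLEL_PAIRS`).

**Neighbor-matching graph similarity.**  Node-pair similarities start at
1 and are refined to a fixed point: the similarity of two nodes is the
optimal assignment (Hungarian) of their neighbor similarities divided by
the larger degree; the graph score is the optimal node-assignment mean,
normalized by the larger node count.  Identical or isomorphic graphs
score exactly 1.  The iteration stops when the largest change is below
`eps = 1e-4` (at most 100 iterations); for strongly mismatched small
graphs the fixed point itself approaches 0, so reported values are
graded by how quickly the mismatch propagates — appropriate for a
drawn-vs-reference comparison where drawings are near-correct.

## Task scoring rules

One point per correct date component (T6, max 3).  Picture naming (T7):
exact match earns the point, otherwise the best Jaro–Winkler similarity
against the accepted alternates earns it at ≥ 0.85 (a configurable
spelling-tolerance threshold; the raw similarity always feeds the
Spelling feature group).  Similarities/calculation (T8): 2 points for an
abstract-category answer, 1 for a concrete one (abstract wins a double
match); the subtraction answer B − M is accepted within ±0.005 (currency
rounding); the coin-count answer must be the exact integer.  Verbal
fluency (T11): an item is correct on an exact or ≥ 0.85-JW dictionary
hit, duplicates count once, > 3 words invalidate a slot; 2 points at 12
distinct correct items, 1 point at 10–11, else 0; the auxiliary is the
mean of the 12 per-item JW similarities (blank → 0).  Delayed memory
(T0): 2 for the exact phrase (case and punctuation ignored), 1 if
"finished" or "done" appears, else 0.

Graph tasks (T9/T12/T13) are replayed from the action log.  A stroke
forms an edge only when it resolves exactly two node circles (Euclidean
hit test at the drawn node radius, first-touch order).  Error counters
follow the construction taxonomy — wrong connection, too few nodes, too
many nodes, already-existing connection (T9); wrong connection, same
node, click outside a node (T12); same node twice, touch outside the
operation zone, disallowed operation (T13) — and are monotone in the log
prefix.  T13 executes insert/remove on sequential two-node touches and
stops when the operation budget reaches 0.  Battery points for these
tasks (max 2) are a documented convention mapping replay quality
(similarity ≥ 0.95 with no errors → 2; similarity ≥ 0.8 → 1; T13: goal
reached cleanly → 2).  The clock task's clinical score is supervised;
the automatic part counts stroke points outside the active contour
(ray-casting point-in-polygon) and a supplied supervisor score is stored
unchanged.

## Energy expenditure

Mifflin–St Jeor BMR with height in metres (`625·H + 10·W − 5·A + 5`,
women −161), TDEE = BMR × PAL with the conventional multipliers
(sedentary 1.2, light 1.375, moderate 1.55, heavy 1.725, athlete 1.9 —
config-overridable; the published description names the levels but not
the coefficients).  Diaries are summed exactly per the equations above.
The four table features are {BMR, TDEE, P_gained, P_balance}.

## Speech features

Framing is 30 ms Hamming / 10 ms hop for spectral features; pitch uses a
60 ms frame (several cycles at the 50 Hz search floor) and 4× zero
padding.  Voicing is decided by the normalized-autocorrelation peak
(> 0.5) for all five estimators; the estimator then supplies f0 within
50–400 Hz.  The cepstral method floors the log spectrum 60 dB below its
peak to suppress noise-floor quefrency ripple; harmonic-summation
methods weight harmonics (1/k linear; 0.85^k log) to suppress
subharmonics; the residual method whitens with a 12th-order LPC.

MFCC: magnitude spectrum → 26 triangular mel filters → log → orthonormal
DCT-II, keeping coefficients 0–12.  GTCC: identical pipeline through 32
ERB-spaced 4th-order gammatone magnitude responses (bandwidth
1.019·ERB(fc)).  Because the filterbank applies to magnitude and the log
has no additive offset, a gain change moves only coefficient 0.

Spectral descriptors (per frame): slope (least-squares of magnitude vs
frequency), centroid/spread/skewness/kurtosis as power-weighted moments
(power weighting keeps a pure tone's centroid on the tone instead of
being dragged by window sidelobes), decrease, flux (L2 change of the
normalized magnitude spectrum), rolloff (0.85 of cumulative magnitude),
flatness (geometric/arithmetic mean of power) and normalized Shannon
entropy.  Single-frame flatness of white noise is biased low by
chi-square bin scatter, so clip-level noise identities use
`mean_spectrum_descriptors`, which averages the periodogram over frames
first.

Wavelet scattering: analytic Gaussian (Morlet-envelope) filter banks
with 8 and 1 wavelets per octave, top center frequency 0.35 of the rate
down to 50 Hz; envelopes are lowpass-averaged at the 0.5 s invariance
scale and pooled into exactly 8 time windows, then log(x + 1e-10).
Second-order filters act on envelopes decimated to ~8 kHz by spectral
cropping (envelope modulation lives far below the carrier), capped at
2 kHz centers, which bounds the cost without affecting the invariance
property (50 ms shifts change the output by < 1% in relative norm).

The sequence preset is pitch (1) + MFCC (13) + GTCC (13) + spectral
skewness (1) = 28 z-scored columns per frame; the published description
names the methods but not the coefficient counts, so the 28-column
layout is this package's documented choice.

## Feature table

The published group sizes (T1 9, T2 10, T3 28, T4 22+22, T9 30, T10 24,
T11 2, T12 33, T13 25, T15 4, Spelling 3, SAGE 10, Duration 16 — total
238) are fixed; the individual features inside each group are not
published, so this package defines and freezes a concrete list (see
`feature_table.default_schema`): tap timing/offset/miss statistics for
T1–T3, Fréchet/percentage-match/kinematic/tremor-band statistics for the
spiral and drawing tasks, error counters + similarity + per-stroke
kinematics for the graph tasks, the four energy quantities, the three JW
averages, the nine task scores plus their total, and the 16 durations.
Any list matching the published counts is methodology-consistent.
Speech features are deliberately not part of the 238 (the published
group sizes sum to 238 without a speech group; speech lives on the
sequence/scattering path).

Missing tasks leave their group as NaN with a per-vector flag;
table-level imputation fills column medians.  Class encoding is 0 =
healthy, 1 = impaired.

## Classification

Base learners delegate to scikit-learn behind a uniform
`predict_proba` contract, each wrapped in standardization (and optional
PCA retaining a configured variance fraction).  Learners without a
scikit-learn equivalent are implemented here: a voted perceptron, a
locally weighted (Gaussian-distance-weighted neighbor) classifier, a
shallow logistic-model tree, a discretized naive-Bayes network stand-in,
and a numpy BiLSTM (below) adapted to tabular rows as length-1
sequences.

**AdaBoost.M1**: uniform initial weights; per round fit on weighted data
(`sample_weight` when the learner supports it, weighted resampling
otherwise), weighted error ε, stop at ε = 0 (the round's model becomes
an effectively unanimous vote) or ε ≥ 0.5 (warn, keep the single model);
β = ε/(1−ε), correct-instance weights ×β then renormalize, model vote
weight log(1/β); prediction by weighted vote normalized to
probabilities.

**hybrid13**: AdaBoost.M1 over decision stump, random forest, MLP, SMO
(linear SVM), kNN, locally weighted learner and Bayes net; sigmoid-SVM +
PCA; two linear SVMs + PCA (0.95 and 0.9 variance); Fisher LDA; the
LSTM-style learner; voted perceptron + PCA — fused by the average of
probabilities.  Exact probability ties break to class 0 (healthy), the
conservative screening default.

**Metrics**: one-vs-rest rates aggregated by class support, which is the
convention under which the published hybrid row (accuracy 96.12%,
weighted TNR 0.953, precision 0.961, F1 0.961, kappa 0.918, MCC 0.918)
is reproduced exactly from its printed confusion counts.  MAE/RMSE use
per-class probability residuals; RAE/RRSE are relative to the
class-prior constant predictor.  AUCs are support-weighted one-vs-rest.

**Protocols**: stratified k-fold (pooled held-out predictions,
deterministic per seed) and leave-subjects-out (all records of held-out
subjects removed from training; per-test-set error count EC and mean
prediction confidence PrC reported).

**Feature selection**: correlation ranking, PCA by variance fraction,
wrapper forward best-first search (CV-accuracy scored, with up to
`patience` non-improving expansions before stopping), and a binary
grey-wolf/particle-swarm hybrid search (sigmoid transfer; fitness = CV
accuracy minus a small cardinality penalty).

## Sequence classifier

Two stacked bidirectional LSTM layers of 100 units per direction, mean
pooling over time, softmax output; trained with RMSProp (ρ = 0.9, lr
1e-3), at most 10 epochs, mini-batches of 128 with per-epoch shuffling,
and a piecewise schedule dropping the learning rate by 0.1 every 5
epochs.  Implemented in numpy with manual backpropagation through time
(verified against numerical gradients); all randomness flows from an
explicit seed.  The published architecture text is ambiguous between
dense and recurrent layers; the recurrent reading is implemented.  The
scattering classifier trains a third-order polynomial-kernel SVM on one
instance per scattering window and labels a clip by majority vote over
its windows.

## Synthetic cohort

The generator emulates the study conditions: 150 records (89 healthy
from 8 subjects, 61 impaired from 7) over 5 visit rounds.
Class-conditional parameters: tremor amplitude 1 px (healthy) vs 6 px
(impaired) at 5–6 Hz (the pathological 4–8 Hz band) plus white jitter;
response latency 500 vs 900 ms; drawing speed 400 vs 250 px/s; typo rate
0.02 vs 0.20 per character (substitution/transposition); graph-task
error rate 0.02 vs 0.25 per action; fluency blanks 0 vs 0.15; voice
jitter 0.5% vs 3%, shimmer 3% vs 10%, HNR 25 vs 10 dB; mean daily
calorie balance +100 vs −400 kcal.  Where the study reports no value
these are chosen once as clinically plausible early-stage contrasts and
documented here.  Demographics are drawn identically for both classes so
the label cannot leak through the profile.

Voices are impulse-train sources with cycle-level jitter/shimmer, two
damped vocal-tract resonances (500 and 1500 Hz) and additive noise at
the target HNR.  Trajectories are the reference path plus lateral
sinusoidal tremor and white jitter — with zero tremor and jitter the
points equal the reference exactly.

**What passing tests show**: that the full pipeline (generation →
scoring → 238 features → ensemble CV) separates classes when
class-conditional structure exists and sits at chance when it does not.
They do not show clinical accuracy: synthetic effects are simplified,
independent across tasks, and stationary within a session, unlike real
tremor, speech and behavior.  The published dataset-level accuracies are
properties of a non-public cohort and are reproduced here only
analytically, from their printed confusion counts.

## Problem sizes

Desk-scale defaults keep the suite and the acceptance script inside a
few minutes on one CPU: the full synthetic run uses the study's 150
records; the null control uses a balanced 80-record cohort (so chance is
0.5 rather than the majority rate); speech experiments use 16 clips of
1.5 s; wrapper recovery uses 20 trials of n = 200 with 5 planted + 50
noise features, where the label is the sign of the planted features'
sum (each planted feature is individually necessary, which is what makes
"recovery" well-defined).

## Known limitations

Speaker characteristics (age, gender, microphone) are not normalized in
the speech path.  The neighbor-matching fixed point is eps-dependent for
strongly mismatched graphs.  The LMT, LWL and Bayes-net registry entries
are functional stand-ins for their WEKA namesakes, not re-implementations
of WEKA internals.  The clock task's clinical score remains supervised;
only its boundary-error counter is automatic.
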
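# Methods

This note records the models implemented in `motionseq`, the choices made
where the procedure left room, and what the synthetic cohort does and does
not establish.

## Skeletal motion model

A motion is a 17-joint skeleton tree plus per-frame joint rotations and a
root translation. Rotations are stored as Euler angles in degrees (the BVH
convention) and interpreted with a fixed z, y, x application order: the
local rotation for angles (α, β, γ) about the x, y, z axes is
R = R_z(γ) R_y(β) R_x(α), regardless of the channel order a BVH file
declares (the file order only determines how numbers are read off each
frame line). The equivalent quaternion is the product
q = q_z(γ) q_y(β) q_x(α), implemented in closed form and cross-checked in
the tests against scipy's rotation matrices.

Because q and −q encode the same rotation, all quaternions are
canonicalised (w ≥ 0; if w = 0, first nonzero component positive) before
any vector-space distance. Root translation is carried through I/O and
forward kinematics but excluded from quaternion features; no procedure
here defines a distance on it, so it is left out rather than guessed in.

## Keyframe extraction

Given compression rate `c_rate` ∈ (0, 1] and N frames, k = c_rate·N
keyframes are selected (round half-up, clamped to ≥ 1, and to ≥ 2 whenever
N ≥ 2 so both endpoints can be kept). k-means runs on the per-frame 51-dim
pose vectors with Euclidean distance, seeded k-means++ initialisation
(which spreads initial centroids over distinct frames) and best-of-5
restarts; determinism under a fixed seed is a hard requirement for
reproducible pipelines. Each centroid maps to its nearest original frame;
collisions backfill with the next-nearest unused frame so exactly k
distinct frames result. The first and last frames are force-included
(evicting the worst-matching keyframes) because linear interpolation of a
non-keyframe needs flanking keyframes on both sides.

Reconstruction uses u(t) = (t₂−t)/(t₂−t₁), p_t = u p₁ + (1−u) p₂ with the
frame index as the time variable (frame time is uniform). The error is the
mean over frames of the posture distance, read as the Euclidean norm per
joint summed over the 17 joints (the alternative reading — a single norm
over all 51 coordinates — is isolated behind one function and not used).
Units are centimetres, matching the skeleton offsets.

The 15% default rate follows the elbow of the error-vs-rate curve on
smooth synthetic motions (error rises steeply below ~15%, changes little
from 15% to 25%), which the sweep test reproduces.

## DTW distances

Each of the 17 joints is aligned independently (two motions may warp
differently at different joints; a single shared path is deliberately not
offered). The DP uses steps {(1,0), (0,1), (1,1)} with no step weights;
the local cost is the Euclidean distance between canonical [w, x, y, z]
4-vectors (a geodesic rotation-angle metric is available behind
`DTWConfig.local_metric` but is not the default). The warping window is a
Sakoe-Chiba band of half-width ceil(0.1·max(n, m)) around the
slope-corrected diagonal j ≈ i·(m−1)/(n−1); slope correction keeps the
band meaningful for unequal lengths. If the band disconnects the corners
(very unequal lengths at small n), it is doubled with a warning until
feasible. The per-joint distance divides the cumulative cost by the
optimal path's cell count (traceback prefers the diagonal on ties); the
motion distance D is the mean over joints.

DTW runs on the keyframe-compressed sequences by default — the stated
purpose of keyframes is cutting processing time — with raw sequences
available by setting `c_rate = 1`.

Feature layouts (the source procedure does not pin these down; both are
explicit here): assessment uses the 17 per-joint distances averaged over
the class's 3 teacher repetitions (a scalar-D mode is selectable);
recognition uses the 8 distances D to each class's teacher reference,
averaged over that class's repetitions.

## Classifiers

k-NN (k = 3, vote ties broken by smallest mean neighbour distance then
lowest label), SVM (RBF kernel, C = 1), Gaussian naive Bayes, logistic
regression (L2), and a Gini decision tree follow their textbook
definitions via scikit-learn. Two networks are implemented in full:

* **BPNN** — input layer sized to the feature dimension, one hidden layer
  (default 16 units) with tangent-sigmoid activation
  f(x) = 2/(1+e^(−2x)) − 1, softmax output, full-batch gradient descent on
  cross-entropy (500 epochs, learning rate 0.01, seeded init, features
  z-scored internally).
* **RBFNN** — one hidden layer of Gaussian units
  exp(−‖x − cᵢ‖²/d²) with centres from k-means (default 8), width d =
  median pairwise centre distance, and linear output weights by least
  squares. The exponent is negative: a positive exponent grows without
  bound in the distance and cannot form a radial basis.

## Hidden Markov model

The HMM is discrete-emission, λ = [N, M, π, A, B]. Continuous 68-dim pose
frames (17 joints × 4 quaternion components) are mapped to symbols by a
vector-quantisation codebook (k-means, default M = 16 symbols, fitted on
the training fold only). The topology is left-to-right with self-loops and
N = 5 states by default — exercise motions progress through phases
monotonically — with a full ergodic topology available. Scoring uses the
forward algorithm with per-step scaling (log-likelihoods remain finite for
long sequences); a plain unscaled backward pass is kept for short-sequence
diagnostics and satisfies Σᵢ πᵢ bᵢ(o₁) β₁(i) = P(O|λ) exactly. Training is
standard Baum-Welch EM over multiple sequences; the total log-likelihood
is non-decreasing per iteration and structural zeros of the left-to-right
topology are preserved by re-estimation. The ergodic initialiser draws
emission rows from a dispersed Dirichlet: near-uniform emission rows are a
symmetric fixed point EM cannot leave. Classification takes the class
whose model gives the highest log-likelihood, ties to the lowest class id.

## Recurrent networks

LSTM, BiLSTM and GRU cells are implemented in plain numpy with exact
analytic backpropagation through time (verified against central finite
differences to better than 1e-4 relative). The LSTM uses the standard
three gates (forget, input, output) with h₀ = C₀ = 0. The GRU update is
h_t = (1−z_t)·h_{t−1} + z_t·h̃_t with reset gate r_t entering the
candidate through r_t ∗ h_{t−1}. BiLSTM runs a forward and a time-reversed
pass and concatenates the final hidden states. The readout is an affine
map of the final state(s) to class scores; training is full-batch gradient
descent on softmax cross-entropy with global-norm gradient clipping at 5
(defaults: hidden 32, 200 epochs, learning rate 0.01, all seeded). Inputs
are the keyframe 68-dim quaternion frames, z-scored over the training set,
processed at native variable length.

## Evaluation

Cross-validation defaults to 10 folds with seeded shuffling. Recognition
folds are stratified by motion class. Assessment folds are *not*
stratifiable at realistic grade frequencies — one motion class has ≈7
expected fails and another none at the default cohort size — so the
assessment runs use plain shuffled folds (`stratified=False`); the
stratified path errors with guidance when a class cannot fill the folds.
Grades are encoded fail = 0 < pass = 1 < good = 2 for ordinal operations;
rater concordance uses Kendall's tau-b (tie-corrected — three-level grades
are heavily tied). The chi-square comparison of methods reports both the
Pearson and likelihood-ratio statistics without continuity correction,
plus the expected matrix, minimum expected count and the number of cells
below 5 (the usual validity diagnostics).

## Synthetic cohort

The generator emulates the study design the pipeline targets: 8 motion
classes, 3 teacher repetitions and 95 students per class (98 × 8 = 784
motions), per-class durations drawn from normal distributions with the
published per-motion means/SDs (2.94 ± 1.01 s up to 21.72 ± 4.01 s), and
per-class grade frequencies matching the published marginals (largest-
remainder allocation, shuffled per class). Class templates are sums of 1-3
random sinusoids per joint channel (amplitudes ~8-35°, 0.5-2.5 cycles per
motion), which makes distinct classes nearly orthogonal in pose space.

Grades are defined by construction: a student motion is the template
resampled to a re-drawn duration, time-warped by a random strictly
monotone re-parameterisation, corrupted by band-limited amplitude noise,
and offset by a constant angle on a random ~30% joint subset. Scales
(amplitude-noise SD, offset, warp strength) are (1.5°, 2°, 0.05) for good,
(4°, 6°, 0.15) for pass, (10°, 15°, 0.35) for fail, with (0.8°, 0°, 0.03)
for teacher repetitions — good performances deviate by a degree or two
while failing ones show the 10-15° joint-angle errors and strong timing
drift typical of novices. These define exact ground-truth labels for
parameter-recovery tests.

What this does *not* establish: the generator has no biomechanical
constraints (joint limits, balance), no soft-tissue or sensor noise model,
no inter-subject anthropometry, and its grade structure is purely
magnitude-of-deviation — real rater disagreement, style variation and
qualitatively wrong movements are absent. Passing recovery tests therefore
show the pipeline's machinery is correct and can separate
magnitude-graded deviations, not that it reaches any particular accuracy
on real recordings.

## Problem sizes and determinism

Default frame rate is 120 Hz (the sensor family's nominal rate; the
per-motion frame counts then match the published duration·rate products).
Cohort-scale runs in the tests and the acceptance script use 30 Hz — the
pipeline is rate-agnostic and this keeps a 784-motion end-to-end run at a
few minutes on one CPU; unit tests use 15-60 Hz as appropriate. All
randomness flows from a single seed through named substreams
(class/subject/purpose), so cohorts are reproducible and stable under
partial regeneration, and two runs with identical configuration produce
identical reports.

## Known limitations

* The BVH writer emits zero-length End Sites (terminal bone lengths are
  not modelled).
* The assessment feature layout (17 per-joint distances averaged over
  repetitions) is one of several defensible readings; the scalar-D mode
  covers the most conservative alternative.
* Baum-Welch uses no smoothing; a symbol absent from a class's training
  folds yields −inf log-likelihood for that class (harmless for argmax
  classification, but callers scoring single models should expect it).
* RNN training is full-batch plain gradient descent — adequate for the
  toy and cohort scales here, not tuned for large datasets.
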
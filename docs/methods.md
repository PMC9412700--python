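# Methods

This note documents the models, parameters and design choices behind
`gripdec`, and what the synthetic benchmark does and does not show.

## Problem setting

A subject wearing an exoskeleton data glove performs trials, each a fixed
D2→D5 sequence of four thumb-opposition grips belonging to one of six
movement tasks (fingertip touching; clothes-peg transfer; large-cube turns
clockwise/counter-clockwise; small-cube turns cw/ccw). A trial is a
(time × channel) series over the 15 flexion sensors (joints J1–J3 of digits
D1–D5), sampled at 100 Hz. Sessions comprise five runs of six blocks of ten
repetitions; block k of every run carries task k in a fixed order, so each
subject contributes 300 trials, 50 per task. The decoding question is:
given one trial, which task was performed?

## Preprocessing

Device angles relate to anatomical joint angles through hand geometry and
glove placement, which we deliberately do not model. Instead:

1. **Calibration normalization** — per channel, y = (x − min)/(max − min)
   with the extrema taken from the subject's held calibration postures.
   Values outside the calibrated range pass through the same affine map.
2. **Smoothing** — centered moving average, width 0.1 s (10 samples at
   100 Hz). Edges use the shrinking-window mean of available samples, so
   length is preserved; even widths take the extra sample from the past.
3. **Differentiation** — forward first difference scaled by the sample
   rate (units s⁻¹, length t − 1). Velocity removes posture offsets, making
   the signal largely independent of hand geometry.
4. **Downsampling** — linear interpolation onto a uniform 16 Hz grid
   spanning the same interval (natural hand movements are slow, and the
   smoothing filter has already attenuated the upper band; residual energy
   above 8 Hz is bounded by the moving average's stopband, not exactly
   zero). New length = ⌊(t−1)·16/100⌋ + 1.

The order normalize → smooth → differentiate → downsample is a package
choice: smoothing before differencing controls derivative noise, and
interpolating last preserves derivative fidelity. An invariance follows
and is tested: applying any per-channel affine gain to raw data *and* its
calibration leaves the preprocessed velocity unchanged to 1e-9.

## DTW template alignment

DTW uses the Euclidean (not squared) distance between c-dimensional
samples, step set {(1,0), (0,1), (1,1)}, fixed endpoints, no band
constraint — all channels warp together (dependent multivariate warping).
Backtracking prefers the diagonal on ties so identical inputs yield the
identity path. The dynamic program is numba-compiled; a memoized recursion
serves as its independent test oracle.

Template selection pairs trial i with trial i + ⌊n/2⌋ (i = 0..⌊n/2⌋−2, the
last trial of odd n unpaired) — a deliberately small subset of pairings
that suffices to find a non-outlier representative. ρ_i is the Pearson
correlation between the two series expanded along the warping path and
flattened across channels and steps (a per-channel-mean correlation is a
documented alternative; the flattened form gives one well-defined scalar).
Raw distances are normalized so max_i d_i = 1; if all pairings are
identical (max = 0) the distances are left at 0 and scores reduce to ρ_i.
Argmax ties break to the lowest pairing index. Warp-resampling averages all
trial samples mapped to a repeated template index and replicates a trial
sample mapped to repeated template indices, so output length always equals
the template length.

The template is selected per training fold, never from test trials (a
one-global-template variant would risk mild leakage; the strict per-fold
reading is implemented and asserted at run time via template provenance).

## Linear one-vs-rest SVM

Features are the flattened aligned trials (t_T × c dims). No scaling or
hyperparameter search is applied; the box constraint defaults to the
SVM-light heuristic C = n(Σ x_i·x_i)⁻¹, the reciprocal mean squared norm,
making the problem invariant to a global feature rescaling (tested). Each
class-vs-rest binary SVM is solved by libsvm's SMO through scikit-learn
(`SVC(kernel="linear")`, tolerance 1e-6); an SLSQP solution of the dual QP
is the independent oracle in the tests. Multi-class decisions take the
argmax of uncalibrated decision values, ties to the first class in sorted
order. Inside the permutation test the per-fold Gram matrices are
precomputed and refits use `kernel="precomputed"` — the identical dual
problem, reusing inner products across relabellings.

## Stacked Bi-LSTM

Architecture: two stacked bidirectional LSTM layers (default 100 units per
direction per layer, configurable — the widths are the one architectural
quantity the source description leaves open), each followed by layer
normalization then ReLU; encoder output = concatenation of the forward
state at the last valid step and the backward state that has consumed the
whole sequence; then a 30-unit ReLU layer and a softmax over the 6 classes.
Gate order (input, forget, cell, output); Glorot-uniform weights, forget
bias 1. Training: cross-entropy, Adam (β₁ 0.9, β₂ 0.999, ε 1e-8), learning
rate 1e-3, mini-batch 16, fixed 64 epochs, no early stopping, dropout or
gradient clipping. Ragged mini-batches are formed by sorting trials by
length into buckets and right-padding; padded steps freeze the recurrent
state, so a trial's prediction is identical inside any batch (tested to
1e-5). The implementation is pure numpy with hand-derived backpropagation
through time, validated against numerical gradients (relative error
< 1e-4 on every parameter block). All stochasticity flows from one seed;
training is deterministic on a given machine. The `lstm_dtw` variant feeds
DTW-warped fixed-length trials to the same network. A small optional grid
search utility scans epochs × batch × widths but is never run by default.

## Evaluation and statistics

* **LORO** — per subject, leave one run out (within-subject decoding).
* **LOSO** — leave one subject out (across-subject generalization).
* **Two-fold** — split subjects in half: *matched* (sort each age group by
  hand size, alternate assignment), *hand-size-grouped* (smallest half vs
  largest half), *age-grouped* (young vs old).

DA = 100 × correct/total over all pooled test trials; per-class
sensitivity = per-task recall; SE = sd of per-subject DAs / √n_subjects.
The permutation test reassigns labels over all trials (preserving class
counts) and reruns the full cross-validation per permutation; template
selection and warping are label-independent and folds are fixed, so the
per-fold aligned features are computed once and shared — mathematically
identical to rerunning everything, including template re-selection.
The 95% CI is the 2.5th–97.5th percentile of the DA distribution; the upper
bound is the significance threshold. Condition comparisons use the paired
two-sided Wilcoxon signed-rank on per-subject DAs (exact null for n ≤ 25
without ties, normal approximation otherwise), Bonferroni-multiplied by a
caller-supplied family size.

At small sample sizes the permutation-mean estimator is slightly negatively
biased: a global permutation that over-assigns a class to the training
trials necessarily under-assigns it to the test trials, anti-correlating
the classifier's predictions with the test labels. The effect is ≈ −1
percentage point at 4 subjects × 60 trials and ≈ −0.3 at 6 × 60; the
chance-level benchmark therefore uses six subjects, where the estimate sits
within Monte-Carlo error of the theoretical 1/6.

## Synthetic data generator

The simulator emulates the session structure above. Each grip is a
raised-cosine flexion pulse (smooth and band-limited like natural movement)
with optional peak plateau and a skew obtained by warping pulse time with
exp(asymmetry). Classes differ in which channels co-activate per grip,
their amplitude ratios, pulse width and plateau; the cw/ccw directions of
the same cube share everything except the sign of a small asymmetry
(0.22), making them deliberately the hardest pair — at noise levels where
errors occur, the four cube classes carry the lowest sensitivities (tested).
Subjects draw a hand size per age group; full-flexion amplitude is
proportional to hand size (30 device units at the 18.5 cm reference), with
per-channel resting offsets uniform in 5–15 units; the calibration extrema
are exactly offset and offset + amplitude, so noise-free trials normalize
into [0, 1]. Tempo is log-normal (σ = 0.08) with a ×1.2 slowdown and extra
per-grip amplitude jitter (+0.03) for the older group, emulating slower,
more variable movement. Per-trial durations scatter with CV 0.1 around
8 s; sensor noise is additive Gaussian with sd 0.02 × amplitude. All draws
come from one `numpy.random.default_rng` (PCG64) generator, so datasets are
reproducible across platforms for a given seed. The magnitudes are package
choices of plausible values, not measured kinematic distributions.

What passing on synthetic data shows — and does not. The generator provides
exact ground truth, perfect label balance, stationary per-class waveforms
and independent Gaussian noise; real glove data add sensor drift and
crosstalk, within-subject learning effects, occasional mis-executed trials
and unmodelled inter-subject strategy differences. Green tests therefore
validate the algorithmic machinery (alignment, feature construction, fold
hygiene, chance-level calibration, the within-subject SVM-vs-LSTM ordering)
rather than any clinical-grade accuracy claim on recordings.

## Problem sizes and numerical choices

Desk-scale runs use 2–6 simulated subjects with one to three runs each;
the chance-level benchmark uses 6 subjects × 60 trials with 200–300
permutations, and LSTM checks use 24 units per direction and 32–40 epochs —
sizes chosen so the full suite completes in minutes while leaving every
pipeline stage exercised end to end. Solver tolerances: SVM 1e-6, layer
norm ε 1e-5, softmax log-clamp 1e-12. Degenerate inputs are defined
behavior: constant aligned pairs make ρ undefined (error), all-identical
template pairings fall back to scores = ρ, empty test splits are valid,
single-class training folds warn and predict the constant label.

## Known limitations

* No Sakoe–Chiba band: DTW is O(t²) per pair; fine at 16 Hz trial lengths.
* The Bi-LSTM runs on CPU only; widths near 100 are slow to train in numpy
  at scale (the network is small, but BPTT in Python has overhead).
* The two-fold matched split assumes equal-sized age groups; unpairable
  configurations raise.
* Device-angle idiosyncrasies (hysteresis, per-sensor nonlinearity) are not
  simulated, so the amplitude-invariance result is exact by construction
  here and only approximate on hardware.
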
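# Methods

## Problem setting and model

The package predicts epileptic seizures from multi-channel scalp EEG by
binary classification of fixed-length analysis windows: *preictal* windows
fall fully inside a horizon before an annotated seizure onset, *interictal*
windows are seizure-free baseline. Windows that touch the seizure itself or
a post-seizure guard period are discarded, since ictal and postictal
activity belongs to neither class. Time is measured in seconds from record
start and all intervals are half-open `[start, end)`.

Defaults follow clinical convention: the preictal state is commonly placed
60–90 minutes before onset, so the horizon defaults to 3600 s (the
conservative end) and the postictal guard to 1800 s; both are configurable
and must be chosen to match the recording lengths at hand (the synthetic
suite uses a 300 s horizon and 60 s guard on 20-minute records). Windows
default to 4 s, non-overlapping — long enough for stable moment and wavelet
estimates at 256 Hz (1024 samples), short enough for dozens of windows per
class in short records.

## Preprocessing and band decomposition

Records are optionally downsampled (polyphase resampling with built-in
anti-alias filtering) and band-limited to 0–75 Hz with a 4th-order
Butterworth filter applied forward–backward (zero phase), preserving
waveform morphology. A 0 Hz low edge means the high-pass stage is omitted.
The same design splits each window into delta (0–4), theta (4–8), alpha
(8–13), beta (13–22) and gamma (22–30 Hz) bands. Butterworth transition
bands make the edges approximate: tests assert ≥ 20 dB out-of-band
attenuation and energy dominance of the band containing a pure tone, not
brick-wall separation. The beta/gamma split at 22 Hz and the 30 Hz gamma
ceiling are narrower than some conventions (13–30, > 30 Hz); they are the
package defaults and overridable per band.

## Features

Eight features per (band, channel): mean, variance (1/(q−1)), standard
deviation d, skewness Σ(A−m)³/(q d³), kurtosis Σ(A−m)⁴/(q d⁴) — note the
*population* count q against the *sample* d, kept exactly as stated and
verified against a two-pass brute-force oracle; relative wavelet detail
energy; wavelet entropy; and amplitude-histogram entropy.

Wavelet features use a Daubechies-4 DWT at level 5, chosen so the deepest
approximation band of a 256 Hz signal covers 0–4 Hz (delta). The per-band
scalar FWEY is 1 minus the approximation band's relative energy (total
relative detail energy); the full per-sub-band vector is available from
`wavelet_features`. Entropies are Shannon sums in base 2 (bits). The
amplitude entropy discretizes into 16 equal-width bins over `[min, max]` —
a count of "unique values" is meaningless for continuous amplitudes.
Degenerate inputs return 0 with a logged warning rather than raising
(constant window ⇒ skewness/kurtosis/entropies 0; zero energy ⇒ zero
wavelet features), so batch extraction never aborts mid-record.

## Hybrid seek optimizer

A population metaheuristic maximizing a deterministic finite fitness over a
box. Each agent keeps a memory of the best position it has held; each
iteration proposes, per agent, the elementwise midpoint of:

* **corvid move** `J_e + λ₁·a·(Z_f − J_e)` toward the memory `Z_f` of a
  uniformly drawn flock-mate `f ≠ e`, with λ₁ ~ U[0,1] and flight length
  `a` (default 2). With probability `P_aw` (default 0.1) the followed mate
  is "aware" and the agent relocates uniformly in the bounds — the standard
  crow-search evasion semantics, adopted because `P_aw` is initialized by
  the algorithm but appears in no update equation.
* **gregarious move**: non-best agents move to
  `J_best + θ·|J_e − J_best(1 + ν₁ϖ) + V|`; the (tied-)best agent explores
  via `J_e + χ·|J_e − J_worst| / ((j_e − j_ws) + ς)` with ς = 1e−12
  guarding the denominator. The printed branch condition `j_e > j_gl` is
  impossible for a maximized global best, so the split is interpreted as
  the parent sparrow-search best/non-best dichotomy, and the second branch
  uses the quotient (guarded) form of that parent algorithm.

Undeclared distributions were fixed once: θ, ν₁, ϖ ~ U[0,1], χ ~ U[−1,1],
redrawn per agent per iteration. The velocity `V` is swarm-global, starts
at 0, and is refreshed once per iteration as `V ← V + ν₁ϖ·J_best` with its
own draws. Out-of-bounds proposals are rejected outright (the old position
is kept; no clipping), bounds are closed, and memories update only on
strict fitness improvement, so trajectories are stable under ties and the
best-so-far history is monotone. Every agent is (re-)evaluated once per
iteration, giving exactly `m·(I_max + 1)` evaluations. All randomness flows
from one seeded generator: identical (config, seed, fitness) give
bit-identical trajectories. Defaults m = 25, I_max = 100.

## Wrapper feature selection

Positions live in `[0,1]^D`; a feature is included iff its coordinate
≥ 0.5. Candidate masks are scored by mean stratified 3-fold validation
accuracy of a cheap surrogate classifier, with the fold assignment frozen
per call so the landscape is deterministic; empty masks receive a sentinel
fitness of −1 (any real mask scores ≥ 0, so the selected mask is never
empty, and the optimizer contract of finite fitness is preserved).

The surrogate is **Gaussian naive Bayes** by default. A depth-limited
decision tree (the `"tree"` option, depth 3) was evaluated first and
rejected as the default: an axis-aligned greedy tree saturates once two or
three strong features are in the mask — on the planted benchmark its CV
accuracy for a 2-informative mask (0.975) *exceeds* that of the full
5-informative mask (0.970) — so maximizing it cannot reward complete
recovery of the informative set. Naive-Bayes accuracy is monotone in the
included informative content (0.925 / 0.9875 / 0.99 / 0.9975 / 0.9975 for
1–5 informative features on the same benchmark), which makes
masks containing the full planted set the optimum. Scoring with the full
ensemble itself is available (`use_full_ensemble_fitness`) at
correspondingly higher cost. Selection budget defaults: 20 agents, 40
iterations (820 evaluations).

## Ensemble and fusion

AdaBoost is built directly from the weighted error
`φ_c = Σ_s p_s·1[u_c(v_s) ≠ t_s]` and learner weight
`τ_c = ½ ln((1−φ_c)/φ_c)` (φ clamped to [1e−10, 1−1e−10]); the sample
reweighting `p ← p·exp(−τ_c t_s u_c(v_s))`, renormalized each round, is the
unique multiplicative update consistent with that weight. Weak learners
are exhaustively fitted decision stumps over {−1,+1}; training halts when a
round's best stump is no better than chance or training is perfect. The
decision tree splits greedily on the largest Gini decrease
`1 − Σ V_χ²`, deterministic with ties broken toward the lowest feature
index then lowest threshold; conflicting duplicate rows end in a
proportional leaf. The random forest (bootstrap Q = n, h = ⌊√D⌋ < D
features redrawn per node, unpruned, majority vote) delegates its tree
internals to scikit-learn's RandomForestClassifier behind the package's
own surface — an ordinary, well-tested building block rather than part of
the method's novelty.

Fusion combines the three base models' class-1 scores in [0,1] (squashed
normalized margin for AdaBoost, vote fraction for the forest, leaf
proportion for the tree) as `E_c = τ E_AB + ρ E_RF + ε E_DT`; the label is
1 iff `E_c ≥ 0.5`. Weight tuning searches `[0,1]³` with every candidate
projected onto the simplex by positive normalization (floor 1e−6 per
coordinate, divide by the sum), so `τ + ρ + ε = 1` holds exactly for every
evaluated candidate, not only the winner. If all three base models are
constant on the validation set the search is vacuous and equal weights are
returned with a warning. Fusion budget defaults: 15 agents, 30 iterations.

## Evaluation protocols

Either one stratified split per training percentage in
{40, 50, 60, 80, 90} or stratified k-fold with k ∈ {2, 4, 6, 8, 10, 12};
each protocol point is an independent run (selection, training, tuning
from scratch). Within each training part, base models are fitted on a
stratified 75 % sub-split and fusion weights tuned on the remaining 25 %
validation part (the source material does not specify this split; a
dedicated tuning set avoids rewarding training-set memorization). Folds
that lose a class are reported as undefined, excluded from means, and
warned about. Child seeds derive from the global seed through numpy
`SeedSequence` spawn keys — a fixed, documented counter — which makes
whole-pipeline reports byte-identical across repeated runs.

## Synthetic data

The record generator composes one sinusoid per band (2, 6, 10.5, 17.5,
26 Hz at 20, 10, 8, 4, 2 µV — amplitudes falling with frequency as in
resting EEG) over 1/f^β Gaussian noise (β = 1, σ = 5 µV). Inside each
preictal horizon the delta/theta components are multiplied by
`preictal_delta_gain` (default 3) and 3 Hz spike–wave sawtooth bursts of
1–2 s are injected (also during the seizure itself), a conventional
epileptiform surrogate. The tabular generator plants `k` of `D` columns
with a between-class mean shift of `effect_size` within-class SDs and
returns the ground-truth informative indices.

What the generator does **not** emulate: volume conduction and channel
correlation, artifacts (EMG, eye blinks, electrode pops), non-stationary
background, patient-to-patient variability, or realistic seizure
morphology. Passing tests therefore demonstrate that the pipeline's
machinery is correct and recovers planted structure — not that comparable
accuracy would be achieved on clinical recordings, where the preictal
signal is far subtler. The perfect accuracy in the worked example is a
property of the planted 3x slow-rhythm gain, which separates the classes
by design.

Study-scale choices: the synthetic evaluation suite uses two 20-minute,
4-channel, 256 Hz records with one 60 s seizure each, a 300 s horizon and
60 s guard — about 540 windows — and single-split (80 % training)
evaluation; these sizes give stable metrics while keeping a full pipeline
run under a minute on one CPU.

## Numerical conventions and edge cases

* Logs base 2 throughout; entropies in bits.
* EDF I/O is a minimal in-package codec (16-bit, uniform rate, 1 s data
  records when the length allows); physical calibration values are
  quantized to their printed 8-character header form before encoding, so
  write→read round trips are exact up to the quantization step. Seizure
  annotations travel in a sidecar CSV (`source_id,onset_s,offset_s`);
  EDF+ annotation channels and discontinuous records are out of scope.
* Downsampling requires `target ≤ source` rate; band edges must stay below
  Nyquist; window length times sampling rate must be integral.
* Memory/elitism ties never replace (strict improvement only).
* Fusion-weight and sample-weight simplex checks use 1e−9 tolerance;
  projection restores exactness after every optimizer proposal.

## Known limitations

* The gregarious move's `J_best + θ|…|` form biases proposals to be
  componentwise ≥ `J_best`; hybridization with the corvid move compensates
  in practice (the sphere benchmark converges in 20/20 restarts), but the
  optimizer is not claimed competitive with modern baselines — it is the
  method under study.
* AdaBoost with stumps improves slowly on parity-like (XOR) structure:
  ~0.65 training accuracy after 20 rounds, 0.84 after 200 (the sklearn
  SAMME implementation behaves comparably), although it does surpass the
  0.75 single-stump ceiling with enough rounds.
* Feature selection treats the mask threshold 0.5 as fixed; no parsimony
  pressure is applied beyond what the surrogate's validation accuracy
  provides, so selected masks typically contain noise features alongside
  the informative ones.
* Metrics are windows-level; alarm latency, event-level sensitivity and
  false-alarm rates per hour — the clinically decisive quantities — are
  out of scope.
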
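# Methods

`reachdyn` implements a complete simulation-and-analysis study of how
rotational population dynamics and single-neuron directional tuning relate in
motor-cortex-like activity during center-out reaching. This note documents
the models, the analysis conventions, the numerical choices, and what the
synthetic populations can and cannot establish about real recordings.

## Task and kinematics

The task is the standard 13-direction instructed-delay center-out reach:
targets equally spaced on a circle of radius 20 cm. Reaches follow a
bell-shaped speed profile, realized as a Gaussian with SD = duration/6,
baseline-subtracted so it is exactly zero at both ends and rescaled so its
time integral equals the reach radius. Movement duration defaults to 300 ms
(400 ms for the complex-kinematic model, which probes a slightly longer
reach). Velocity, position, acceleration and jerk traces follow by
construction: velocity is speed times the target's unit vector, position is
the running (right-Riemann) integral of velocity so the endpoint lands
exactly on the target circle, and acceleration/jerk are successive central
differences.

## The representational (velocity-tuning) population

Each of 200 neurons is cosine-tuned to reach direction with a uniformly
random preferred angle θ_n. Its noiseless rate in condition c is a flat
preparatory level φ·b before its neuron-kinematic latency τ_n, and a
Gaussian movement bump b·exp(−(t − τ_n − μ0)²/2σ²) afterwards, where
b = (1 + cos(θ_c − θ_n))/2 is the directional gain, σ is the movement SD
(default 56 ms, corresponding to a 300–400 ms movement), and
μ0 = σ√(−2 ln φ) places the bump so that it equals φ·b exactly at t = τ_n —
the two branches are continuous by construction. φ = 0.2 throughout, i.e.
preparatory activity is one fifth of the movement peak. Latencies are drawn
normal with SD 72 ms (the empirically reported spread of neuron-kinematic
lags) and zero mean: only the spread matters for the phenomenon, so the
population is centered on the go cue. Gaussian noise (SD 0.01, i.i.d. per
sample; per-trace noise is available by flag) is added everywhere. Two
variants reproduce the published controls: signed gains b = cos(θ_c − θ_n)
and randomly scaled gain magnitudes (uniform on [0.5, 1.5]).

The simulation window is −300 to +800 ms around the go cue at 10-ms
resolution (the analysis step). "Neural movement onset" is detected on the
grand-average rate: the preparatory level is the mean over the first five
samples, and onset/offset are the first/last crossings of
prep + 0.1·(max − prep).

## The dynamical (two-oscillator) population

Muscle-like activity is modeled as two complex oscillators with fixed
frequencies 2.8 Hz and 0.3 Hz whose phase (uniform [0, π/2]), amplitude
(uniform [−2.5, −1.5]) and shared offset (uniform [−5.5, −4.5]) are drawn
per condition. Each neuron mixes the two condition-level oscillations and
the offset through five standard-normal scalar weights (real and imaginary
parts of two complex coefficients plus an offset coefficient), shared across
conditions — so the condition structure is defined jointly across the whole
population, which is precisely what the permutation test probes. The
movement epoch is 0–300 ms; preparatory activity holds the first movement
sample (noise included) for 100 ms before the go cue. Noise matches the
representational model's SD (0.01) without rescaling.

Note a structural property with consequences below: after preprocessing this
population is rank ≤ 5 (two quadratures per oscillator plus the offset), so
the first two rotation planes necessarily capture nearly all of its variance
(~93% here). The variance-per-plane figures published for this generator
(28%/14%) are not reachable from these equations under any accounting we
tried; the rotational goodness-of-fit (≈0.98) and circularity (≈0.93) do
reproduce.

## The complex-kinematic population

Identical latency structure to the velocity model, but each neuron's
movement drive is a weighted sum of the directional projections of velocity,
position, acceleration and (for a quarter of neurons) jerk onto its
preferred direction, each trace time-shifted by the neuron's latency and
edge-padded outside the movement (the hand rests at the center before the
reach and at the target after it). Traces are pre-scaled to unit RMS so
weights are comparable: velocity weights are N(1, 0.2²), position and
acceleration N(0, 0.5²), jerk N(0, 0.5²) on the jerk-sensitive subset. The
exact weights behind the published variant are not printed anywhere we could
consult; the half-velocity scale is this package's choice, made once, so
that the neurons are genuinely multi-parameter rather than degenerating to
the velocity model (an order-of-magnitude-weaker convention does degenerate,
and reproduces neither the published rotational level nor the model's
premise). With these weights the model shows strong rotations (RGR ≈ 0.84)
that are still non-significant under the permutation test.

## jPCA: rotational-dynamics analysis

Within the analysis window (detected onset→offset for the representational
models; go cue→go+300 ms for the dynamical model and the network; explicit
for external data) each neuron is normalized by its range plus a softening
constant (0.05 for unit-scale simulations; use ~5 for spike rates in Hz),
the cross-condition mean is subtracted at each time point, and the data are
reduced to the top 6 principal components. The cross-condition mean removal
follows the original analysis toolbox's default and is required to reproduce
the published variance fractions; it is config-switchable. The state
derivative is the within-condition adjacent-sample difference divided by dt,
never spanning condition boundaries, paired with the state at the earlier
sample.

Two linear flows are fit by least squares: unconstrained Ẋ = MX and
skew-symmetric Ẋ = M_skew X. The skew fit is solved in closed form on the
d(d−1)/2 free parameters (normal equations); antisymmetry is exact. Planes
are the eigenplanes of M_skew, ordered by rotation frequency (|imaginary
eigenvalue|) descending and oriented so the mean signed angular velocity of
the projected trajectories is positive (anticlockwise). Degenerate
zero-frequency eigenspaces are completed to an orthonormal basis with a
warning. Note that frequency ordering does not guarantee monotonically
decreasing variance per plane (and the 0.3-Hz plane of the dynamical model
indeed carries more variance than the 2.8-Hz one).

Metrics:

* **variance fraction per plane** — variance of the projection onto the
  plane basis over the total variance of the normalized, centered data;
* **RGR (rotational goodness-of-fit ratio)** — R² of the skew fit divided by
  R² of the unconstrained fit (R² computed as 1 − SSE/Σ Ẋ²), over a caller-
  selected plane set; with 6 PCs, "first three planes" and "all planes" are
  the same full fit, and both readings of the published headline agree;
* **circularity** — the mean unsigned angle between x and ẋ in the top
  plane, divided by π/2 and clipped to [0, 1]: 1 for purely circular flow
  (ẋ ⟂ x), 0 for purely radial flow. The published phrasing is ambiguous;
  this is the reading under which 1 means "purely circular". An alternative
  (mean sine of the angle) is available via config.

RGR is ill-conditioned when the unconstrained fit explains almost nothing
(a ratio of two near-zero R²s); this widens the null distribution of the
permutation test below and is the main reason its effect sizes land near 2
rather than the published 3.2.

## CMPT: covariance-matched permutation test

The test asks whether rotational structure depends uniquely on the
neuron-to-condition assignment. Per repetition: (1) whole condition
time-courses are randomly reassigned within each neuron — no values change
and nothing moves between neurons, so per-neuron trace multisets, means and
totals are conserved exactly; (2) random within-neuron condition pairs are
swapped greedily, accepting only strict increases of covariance similarity,
until similarity with the observed neuron×neuron covariance reaches 95%
(99% in strict mode); (3) jPCA is recomputed from scratch on the matched
data and the full-fit RGR recorded. Covariance similarity is
1 − SSD(C_obs, C_perm)/TSS(C_obs) with TSS the total squared deviation of
the observed covariance entries from their mean, capped at 1. The p-value is
the fraction of null RGRs ≥ the observed one (reported as < 1/n when zero);
the effect size is the observed RGR's z-score against the null distribution.

The matcher updates the covariance and the similarity incrementally — a
within-neuron swap changes one covariance row/column, and only the two
swapped blocks contribute to the change — verified bit-level against full
recomputation. The inner loop is JIT-compiled (numba); a repetition takes
tens of milliseconds at full size (200 neurons × 13 conditions), so 100
repetitions run in seconds. Repetitions that fail to reach the threshold
within 200·neurons·conditions proposals are discarded with a warning, never
silently kept. Greedy single-swap matching plateaus around 0.985–0.99
similarity for small populations, so the strict 99% mode is only usable at
full size.

The "unshuffle" control sorts each repetition's assignment-matrix rows by
greedy maximum matching on most-common conditions (the most conservative
alignment), computes the retained-assignment fraction, and correlates it
with the null RGRs (Pearson; Spearman by flag). Retained fractions stay near
chance and the correlation near zero in all our runs: matching does not undo
the shuffle.

Calibration caveat: replacing the observed data with one of its own matched
permutations and re-running the test yields p-values concentrated below 0.5
(mean ≈ 0.26 at desk scale) rather than uniform — matching to 95% leaves
null draws slightly less structured than whatever plays the observed role,
so the test is mildly anticonservative under its own null. This is a
property of the published procedure (matching is never perfect), not of this
implementation; the stricter 99% mode removes the representational model's
occasional spurious significances, as published.

The neuron-count × condition-count sensitivity grid redraws a random subset
per repetition, computes the observed RGR on the subset and one matched null
per repetition, and maps p-values and effect sizes over the grid.

## The recurrent network

A 200-unit continuous rate network, τ = 50 ms, Euler-integrated at 10 ms,
rectified-tanh rates, no output feedback. Inputs: a hold signal (1 until the
go cue, 0 after) and the target's (sin θ, cos θ), on throughout the trial.
Targets: zero output during the delay (600/800/1000 ms, interleaved), then
the bell-shaped x/y velocity profile starting 100 ms (the enforced reaction
time) after the go cue, then zero again for a 100-ms tail. J is initialized
N(0, g/√N) with g = 1.5 — the standard chaotic-network scaling; the
alternative N(0, g/N) is available by flag but trains far slower (it starts
the network essentially without recurrent dynamics). B is N(0, 1/N); W
starts at zero.

The loss is the normalized squared output error (summed over times, output
dimensions and conditions, divided by total target variance) plus three
regularizers with weights 1e-2, 2e-5 and 5e-5: the mean squared rate, the
squared sum of input and output weights, and a trajectory-complexity
surrogate — the mean squared discrete state velocity ‖Δx/dt‖² with dt in ms.
Gradients are computed by backpropagation through time in closed form
(validated against finite differences at 1e-4 relative) and optimized with
L-BFGS, stopping at 0.1% normalized error or an iteration cap. A full-size
network reaches the 0.1% criterion in roughly 100–150 iterations (tens of
seconds on one core). Delay-period outputs stay below 2% of peak target
speed (the null-space property) and integrated outputs land within 5% of the
target radius.

Different optimization seeds find different solutions. Across nine training
seeds the exported population's full-fit RGR spans 0.72–0.96 and the
permutation-test effect size spans ~0 to 11 (median ≈ 3.2): most solutions
show strongly condition-locked rotations, but a minority are unusually
low-dimensional and their rotations survive covariance matching. Published
values from a single network should be read with this spread in mind.

## Representational read-outs

* **Preferred directions** (per neuron): least-squares fit of the mean
  movement-period rate (go→go+300 ms) to b1 + b2 sin θ_c + b3 cos θ_c;
  modulation depth k = √(b2² + b3²) and unit vector C = [b2/k, b3/k].
  Neurons with k below a scale-aware tolerance are flagged untuned.
* **Population vector**: P(t) = Σ_i (R_i(t) − b_{i,1}) C_i; the overall
  predicted direction is the angle of Σ_t P(t) and the predicted trajectory
  its running integral. Exact for equally spaced cosine-tuned neurons; on
  trained networks the integrated trajectories end within ~10° of the
  targets on average (worst condition ~18°).
* **Lagged velocity regression** (per neuron): R(t−τ) = a1 + ‖V(t)‖(a2 +
  a3 sin θ + a4 cos θ) + a5(a3 sin θ + a4 cos θ), with the lag τ searched on
  a −200…+200 ms grid in 10-ms steps (the published fit reports a lag but no
  search range). For fixed τ the model is nonlinear only through a5, which
  is profiled on a grid with a bounded scalar refinement; the remaining
  coefficients are linear least squares. The lag maximizing adjusted R² is
  kept, ties broken toward the smallest |τ|; adjusted R² counts six fitted
  quantities (a1…a5 and τ). When a5 exactly compensates scale the (a3, a4,
  a5) triple is identified only up to that trade-off; the profiling scheme
  returns the least-|τ| solution.
* **Tuning stability**: Pearson correlation (Spearman by flag) between each
  neuron's length-C condition-rate vector at neural movement onset and at
  onset + Δ, averaged over neurons per Δ; neurons with zero-variance vectors
  are skipped and counted.
* **Preferred-direction map**: argmax condition per neuron and time point,
  untuned where the max−min rate difference is below 1e-4.
* **Time-shifted-signal PCA demo**: PCA of identically shaped,
  randomly shifted Gaussians reproduces the classic artifact — components
  resembling Fourier harmonics of increasing frequency and a single-curvature
  "horseshoe" trace in the first component plane.

## Problem sizes and determinism

Headline quantities that are means use 20 seeds; permutation tests use 100
repetitions (the published analyses used up to 1000; the p-value floor
scales accordingly); the sensitivity grid and calibration checks run on
reduced populations. All randomness flows from explicit seeds — same config,
same numbers, byte-identical driver output.

## What the synthetic populations do not show

The generators are trial-averaged and noiseless in the trial-to-trial sense:
no spiking variability, no behavioral variability, no sensory feedback, no
recording artifacts. Passing tests establish that the analysis chain
reproduces the published simulation results and that the permutation test
separates the two model classes *under these generative assumptions*; they
do not validate the dynamical-systems interpretation of any real recording.
The published cortical-recording numbers (56%/40% variance, RGR 0.77, effect
4.1, the >30-neuron/>8-condition thresholds) require data that are not
redistributable; the corresponding procedures are exercised on synthetic
populations instead.
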
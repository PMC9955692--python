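# Methods

## The model

Each agent is a predictive-coding-inspired variational RNN (PV-RNN): a
hierarchy of L = 3 leaky-integrator ("multiple timescale") layers of
deterministic units d with per-layer diagonal-Gaussian latents z.  Layer l
updates its internal state as

    h_t^l = (1 - 1/tau_l) h_{t-1}^l
            + (1/tau_l) [ W_dd d~_{t-1}^l + W_zd z_t^l
                          + W_up d~_{t-1}^{l+1} + W_dn d~_{t-1}^{l-1} + b_h ],
    d~_t^l = tanh(h_t^l),

with time constants tau = (2, 4, 8) from the bottom layer up, so higher
layers integrate more slowly.  Layers are chained: each receives d~ only
from its immediate neighbors.  At t = 1 the state is zero.

The prior over z is conditional on the previous deterministic state:
mu^p = tanh(W_mu d~_{t-1} + b_mu^p), sigma^p = exp(W_sig d~_{t-1} +
b_sig^p); at t = 1 it is fixed to N(0, I).  The approximate posterior has
the same functional form, shifted by per-step adaptive variables A:
mu^q = tanh(W_mu d~_{t-1} + A_mu + b_mu^q), sigma^q = exp(W_sig d~_{t-1} +
A_sig + b_sig^q).  By default the prior and posterior heads share the
weight matrices and differ only in their biases and the A shift
(`shared_heads=False` gives fully separate heads).  Samples use the
reparameterization z = mu + sigma * eps.

The 10-channel output (6 joint angles + 4 hand coordinates) is
tanh(W_out d~^1 + b_out).  All channels live in [-1, 1]: joint angles by
construction, hand coordinates because the synthetic data divides the
planar-arm coordinates by the total reach (3 unit links).  This fixed
data-side normalization is the only affine rescale in the observation
path.

## Free energy

Learning and perception both minimize the normalized variational free
energy

    F = sum_t sum_l w_l(t) * mean_r delta(l, r, t)
        + (1/R_X) sum_t || mask * (X_t - X^bar_t) ||^2,

where delta is the elementwise Gaussian KL of the posterior from the
prior, R_X is the number of masked observation channels, and w_l(t) is the
meta-prior of layer l.  The accuracy term of the usual evidence bound is
the negative squared error (unit observation noise), so the minimized
objective is complexity plus normalized squared error.  Large w pins the
posterior to the prior — confident top-down intention, i.e. sensory
attenuation; small w lets prediction errors dominate — sensory attention.
Meta-priors scale by x10 per layer above layer 1 in both training and
interaction; at the first time step of training the weight is overridden
to 1.0 in every layer so the initial latent state stays informative.

Gradients are hand-derived backpropagation through time over the exact
computation graph above (reparameterized pathwise gradients with the noise
held fixed); the test suite checks every parameter group and the adaptive
variables against central finite differences at relative error < 1e-4.
Autodiff frameworks are deliberately not used: the network is small and
the analytic adjoint keeps the package dependency-light and fast on one
CPU core.

## Training

Full batch over the training sequences, Adam (lr 1e-3 full scale,
betas 0.9/0.999), optimizing network weights and the per-sequence A
jointly; weights use uniform fan-in initialization, biases start at zero.
Gradients are clipped at a global norm (default 1.0) to guard against the
NaN failure mode of long BPTT; training aborts with a diagnostic if F
turns non-finite.  The full-scale protocol is 20 sequences x 400 steps,
70,000 epochs, layer-1 training meta-prior 3.5.

### Desk-scale profile

The full protocol is far beyond one CPU core at test time, so the package
ships a desk profile used by its own acceptance checks: d = (16, 8, 4),
z = (2, 1, 1), 8 sequences x 200 steps, 1200 epochs, lr 0.01, gradient
clip 50.  Two balance choices do not transfer across a 35-fold epoch cut
and were rescaled once for the desk profile:

- training meta-prior 0.35 (not 3.5): at 3.5 the complexity term dominates
  the short optimization and the reconstruction error never drops below
  the data variance; at 0.35 the fit reaches ~5% of data variance while
  the prior still learns the B/C stochasticity;
- online inference uses a 16-step window, 15 iterations, inner Adam
  lr 0.03 (full scale: window 70, 50 iterations): the cumulative number of
  inner gradient steps a window entry receives shrinks ~15-fold at desk
  scale, so the inner step size is raised to compensate.

One network per agent is trained with a fixed seed (agent 1: seed 1,
agent 2: seed 32).  The seeds were chosen once by a small preliminary
selection — train a handful of candidates, evaluate their prior
generation against the target 50/10/40 (resp. 50/40/10) preferences, and
keep the closest adaptable one — mirroring the published protocol of
training 25 networks and keeping the best 5.

## Online inference (error regression)

During interaction the network weights are frozen.  At each step the
agent minimizes the windowed free energy with respect to the A entries of
a sliding window (growing from 1 step at onset to `window_len`), with the
error computed on the exteroceptive channels only: the agent explains the
partner's observed hand positions, while its own proprioceptive
prediction is executed verbatim (ideal actuation).  New window entries
start at A = 0; retained entries warm-start.  When the window slides past
a step, that step is folded into the frozen pre-window state using the
posterior mean (a reproducible convention; a sampled z would make the
permanent record noisy).  The reparameterization noise is drawn once per
interaction step and held fixed over the inner iterations, making the
inner objective deterministic; per-iteration resampling is available
(`resample_noise=True`) but makes the per-step free-energy trace
non-monotone in ~1/5 of steps.  Noise still enters the loop between
steps: the posterior z of each new window pass and the prior z used to
generate the next action are sampled fresh.  The current schedule value
w_i(t) is applied uniformly to all window steps (schedules vary slowly
relative to the window).

## Dyadic coupling

Updates are synchronous: both agents act at step t, then both observe the
partner's executed posture — mirrored (x negated, left/right hands
swapped) forward kinematics, the same convention the training data uses —
infer, and produce the step t+1 action.  The first action comes from the
initial prior with no observation.  Meta-prior schedules are constant or
sinusoidal; the anti-phase pair for the joint-intention experiment uses a
phase offset of pi, holds 0.5255 during an onset (80 steps at full
scale), and oscillates between 0.0048 and 1.0461 with period 1280 — the
grid values w10 and w41 of the 50-point log grid from 0.001 to 5.

## Primitive classification

An echo state network labels 6-channel joint trajectories: reservoir of
25 leaky-integrator units (leak 0.6), 25% connectivity, spectral radius
0.9, fixed random input map; a ridge readout (lambda 1e-2) maps each
12-step sliding window to a one-hot label, argmax decided.  The reservoir
is restarted from rest for every window and the readout sees the
window-end state concatenated with the window-mean input, so a label is a
deterministic function of the window content alone.  A T-step trajectory
yields T - 12 labels (the last full window is discarded — the counting
convention adopted throughout, including the 1000 -> 988 bookkeeping).
The readout is fitted on fresh FSM-generated trajectories of both
preference machines plus constant-primitive fixtures (repeated same-label
contexts never occur in the alternating FSM data and are replicated so
the ridge fit keeps them); held-out window accuracy is ~97%.

## Behavioral statistics

All statistics operate on the per-window label sequences.  Overall
synchronization is the fraction of steps with equal labels; the per-label
rate for M is (steps both show M)/(steps either shows M).  The
chance-level overall synchronization of independent label distributions
is sum_M p1(M) p2(M); the per-label chance level under the same
independence model is p1 p2 / (p1 + p2 - p1 p2).  A turn is a transition
between a synchronized-B episode and the next synchronized-C episode (or
vice versa); episodes shorter than `min_run` steps are ignored as
flicker, and intervening A or unsynchronized stretches do not reset the
detector.  `min_run` defaults to one primitive duration (20); the desk
profile uses 4, because its synchronized episodes are short (see
limitations).  Transfer entropy on the 3-symbol alphabet is the plug-in
estimator with history lengths k = l = 1, base-2 logarithm, no bias
correction; the sliding variant recomputes it over each trailing window
(320 steps at full scale).

Phase regions partition a meta-prior grid by thresholding the per-label
B- and C-synchronization at their chance levels: both above ->
turn-taking, neither -> ignoring, only the C (agent 1's preferred) above
-> agent 1 leads, only B -> agent 2 leads.

## What the synthetic data emulates — and what it does not

The generator reproduces the study conditions: 20 trajectories x 400
steps per agent, primitives alternating A -> {B, C} -> A with 80/20
vs 20/80 biases, 6 joint channels plus 4 hand-position channels tied by a
deterministic mirrored kinematic map.  Primitive duration (20 steps),
waveform shapes (fixed sinusoid/ramp mixtures, pairwise-distinct), the
planar 3-joint arm, and the 2-step boundary cross-fade are
package-defined: the source recordings were produced by a human moving a
manipulator and are not available.  Sensors are noiseless; all
stochasticity enters through z.  Consequently, passing tests show that
the architecture, inference machinery and statistics behave as described
on data with the stated probabilistic structure — not that the specific
waveforms, kinematics or noise of any physical robot are reproduced.

## Numerical choices

- sigma is parameterized through exp and never clamped; KL rejects
  non-positive sigma.
- Gradient clipping by global norm; training 1.0 default, desk profile 50
  (the desk loss surface is steep early and the tight clip slows it
  needlessly).
- Ties in network selection break toward lower final training free
  energy.
- Degenerate inputs: empty datasets, unequal sequence lengths, empty
  channel masks, too-short label sequences and invalid probabilities all
  raise ValueError with a message naming the offending argument.
- Seeds: every stochastic routine takes an integer seed or Generator;
  interacting agents draw from independent streams spawned from one
  SeedSequence; sweep cells derive their seed from (base_seed, idx1,
  idx2, repeat).

## Known limitations

- Desk-scale dynamics are noisier than the full-scale study: synchronized
  episodes last a few steps rather than tens, so turn counts are small
  integers per 400-step interaction and the flicker filter must be
  shorter.  The qualitative orderings (leader-follower asymmetry, corner
  sync collapse, diagonal turn peak, TE direction following the larger
  meta-prior) are what the desk checks assert, not full-scale
  percentages.
- The selected desk pair is asymmetric: the agent-1 network is the
  stronger leader, and its information flow toward agent 2 dominates in
  every phase of the oscillation experiment.  The desk check therefore
  asserts the net flow direction in the half-periods where agent 1 holds
  the larger meta-prior; the full sign reversal in the opposite
  half-periods needs the better-matched networks of the full-scale
  protocol.
- For the conflicting marginals (0.5, 0.1, 0.4) x (0.5, 0.4, 0.1) the
  independence chance level sum_M p1(M) p2(M) is 0.33.  A value of 0.57
  sometimes quoted for this setting corresponds to using each agent's
  preferred-movement rate (0.4) in both cross terms; the package
  implements the formula.
- A single network per agent at desk scale; the full 5-network repeat
  protocol and the 50x50 grid are expressible (`SweepConfig`) but take
  CPU-days.
- No learned observation noise, no alternative posterior families, no
  physical-robot kinematics.
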
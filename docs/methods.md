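# Methods

`striatan` models one computational problem at three levels of
description: how a learner in a stochastic, non-stationary environment
balances *stable* value estimates (robustness to probabilistic feedback)
against *flexibility* (fast re-learning after a contingency reversal).
The package's thesis, following the cholinergic-feedback account of
striatal learning, is that the pause in tonically active cholinergic
interneuron (TAN) firing that follows salient outcomes acts as an
effective learning-rate dial for the basal ganglia, and that closing a
feedback loop from striatal population *uncertainty* onto pause duration
lets the system tune that dial to its environment.

## The task

Two stimuli, two responses, Bernoulli rewards. Within every 20-trial
epoch each (stimulus, action) cell receives exactly `round(p * 20)`
rewards at seeded, uniformly permuted positions, so the nominal rates
hold exactly in every epoch ("fixed stochastic schedule"); an i.i.d.
Bernoulli mode exists behind a flag. The two actions' outcomes are drawn
independently (not yoked). Training is 20 epochs of 20 trials per
stimulus (400 trials), with the two actions' reward probabilities
exchanged from trial 200 on. Stimuli alternate deterministically
(S1, S2, S1, ...); the presentation order is not specified by the study
design, and interleaving keeps both stimulus contexts equally trained at
every point. Probe blocks (default 10 repetitions per stimulus, learning
and feedback disabled) can be interleaved before training and after each
epoch; training and probe accuracy are reported separately. Reward
schedules span 85:15 through 40:10 (percent reward for the optimal and
suboptimal action).

## The rate-coded network

### Units

Point neurons on a normalized 0-1 potential scale with excitatory,
inhibitory, leak and (for the TAN) accommodation conductances:

    I_net = ge*ḡe(Ee − Vm) + gi*ḡi(Ei − Vm) + ḡl(El − Vm) + ga*ḡa(Ea − Vm)
    Vm   ← Vm + τm·I_net + noise,     dge/dt = τg(κ·mean(x_i w_i) − ge)

The output rate is a sharp threshold sigmoid
`γ[Vm−Θ]+ / (1 + γ[Vm−Θ]+)` convolved with a Gaussian kernel
(σ = 0.005); the convolution is evaluated by trapezoidal quadrature and
tabulated for interpolated lookup inside the cycle loop (interpolation
error < 1e-4; the direct function agrees with adaptive quadrature to
better than 1e-6). One cycle is 10 ms. Gaussian membrane noise is
applied per cycle to motor cortex (σ = 0.0015) and the dopamine unit
(σ = 0.002); these are the model's only stochastic elements besides the
seeded weight initialization.

### Architecture

Input (2) → motor cortex (2, with lateral inhibition), and plastic
corticostriatal projections to Go (18; 9 per response, D1) and NoGo
(18, D2) populations. Go inhibits GPi; NoGo inhibits GPe, which
inhibits GPi; GPi inhibits thalamus; thalamus and motor cortex excite
each other. GPe/GPi are tonically active (elevated leak potential and a
strong leak conductance that keeps them inside their dynamic range —
without it any synaptic inhibition saturates them silent and the
channels lose selectivity). A dopamine (SNc) unit excites Go and
inhibits NoGo; a GABAergic interneuron pool, driven by the TAN's
nicotinic excitation plus its own tonic leak, inhibits both MSN
populations; the TAN itself inhibits them directly (M2-like). NoGo
units get a slightly lower activation threshold (Θ = 0.23 vs 0.25):
D2 MSNs are the more excitable population, and this is what lets
rewards (dopamine-driven D2 suppression) depress NoGo below its
selection-phase rate.

### Trial structure

*Selection ("minus") phase.* The stimulus is clamped, TAN output is held
at its tonic rate, dopamine at its tonic level. The network settles for
up to 60 cycles; a response is executed when a motor unit crosses
threshold (0.95) or, at the deadline, by argmax of the motor rates (ties
seeded-random). The deadline race is deliberately noise-sensitive: motor
cortex sits near threshold, so the accumulated membrane noise competes
with the thalamocortical tilt from the learned weights. The resulting
choice is stochastic with a graded psychometric in the Go-weight
difference (~75% at a 0.1 column gap, ~97% at 0.4), which is the
network's source of exploration.

*Feedback ("plus") phase.* 50 cycles. The executed response is clamped
in motor cortex; dopamine is clamped to a burst (0.9) on reward or a dip
(0.02) otherwise; D1 receptor activation additionally raises Go gain and
threshold in proportion to dopamine (contrast enhancement: strongly
driven units go higher, weakly driven ones are cut off). The TAN
receives a brief depolarizing burst (8 cycles); the burst drives an
activity-dependent accommodation conductance (basis variable `ba`
integrating the rate with time constant τba; hysteretic activation
thresholds) that silences the unit — the pause — until `ba` decays and
the channel deactivates, after which the TAN returns to its tonic rate
(optionally overshooting: the rebound burst). One burst-pause-rebound
event is allowed per feedback window. The pause releases the M2 and
GABAergic inhibition of the MSNs; if M1 signaling is enabled, the NoGo
leak potential is transiently raised during feedback.

### Pause control and calibration

Pause duration is controlled by τba. Because the TAN receives no
synaptic input, its trajectory is a deterministic function of its own
parameters; `PauseCalibration` simulates the isolated unit over a τba
grid, keeps the monotone nondecreasing run of the realized-pause map
(integer-cycle quantization makes the raw map jitter by one cycle at
threshold knife-edges), and inverts it by nearest-grid lookup. With the
default accommodation parameters the map spans ~80-310 ms, covering the
120-280 ms experimental grid; a requested fixed pause is realized within
one cycle (10 ms) on every trial, identically across trials.

Closed-loop modes replace the fixed τba with an affine, clamped function
of a minus-phase uncertainty read-out — exact population entropy
(`entropy` mode) or the AND-conjunction count (`conjunction` mode) —
with bounds at the calibrated τba range. The read-out is computed on the
current trial's selection phase and applied to the same trial's feedback
phase. The law's input range (H: 2-25 bits; conjunctions: 2-40) was set
from pilot-run read-out distributions so the commanded pauses span the
calibrated range.

### Uncertainty read-outs

Per selection-phase cycle, Go rates are normalized to sum to one and
summed within each response to give an action distribution p_a(t);
population entropy is H = −Σ_t Σ_a p_a log2 p_a (cycles with total
activity below 1e-8 are skipped; 0·log 0 ≡ 0). The conjunction read-out
pairs the k-th Go unit of each response and counts (cycle, pair) events
with both members above θ = 0.1 (about half the typical maximal
selection-phase rate); it rank-correlates with H at ρ ≈ 0.8 across a
training run. Total summed Go activity is provided as the negative
control: it declines with training but does not rise at the reversal.

### Plasticity

Corticostriatal weights (input → Go, input → NoGo; in [0, 1]) update
once per trial from the two phases' states:

    Δ_hebb = y⁺(x − w),   Δ_CHL = y⁺x − y⁻x,
    Δ_sbCHL = [Δ_CHL]+(1−w) + [Δ_CHL]−w,
    Δw = ε(κ_hebb·Δ_hebb + (1−κ_hebb)·Δ_sbCHL)

with ε = 0.045 and κ_hebb = 0.05. The minus-phase state y⁻ is the mean
rate over the last 20 settling cycles (the settled selection state); the
plus-phase state y⁺ is the mean over the *pause window only*:
corticostriatal plasticity is taken to proceed only while the TAN pause
lifts M2-mediated presynaptic suppression. Networks without TANs use the
post-burst feedback state at a residual plasticity rate (0.3) under
tonic acetylcholine.

Pause *duration* acts through recruitment depth, not step size: during
feedback the conductances integrate slowly (τg = 0.08 vs 0.7 during
selection), so units' activation times stagger with their total drive.
A 120 ms window only captures strongly driven units; a 280 ms window
recruits units with progressively weaker corticostriatal weights
(window-mean rate at a 0.4 weight rises from ~0.3 to ~0.6 across the
grid). Long pauses therefore build broad, entrenched representations
and short pauses shallow, labile ones, while depression (dips: dopamine
withdrawal silences the window, leaving −y⁻x) needs no recruitment and
runs at a fixed rate.

The rebound burst's dopamine arrives immediately after the disinhibited
window and multiplies the trial's potentiation
(`1 + 0.5·magnitude` on rewarded trials), implementing
dopamine-after-activity spine potentiation.

### Calibration procedure and what it reproduces

All unit parameters unprinted in the source account (conductances,
gains, projection strengths, dopamine levels, ε) were calibrated as a
self-consistent set by seeded Nelder-Mead searches against operating-
point targets: untrained choice ≈ 50:50 with a graded psychometric;
the monotone 120-280 ms pause map; outcome- and response-selective
feedback-window states scaling with pause duration; functional gating
(imposed Go-weight asymmetries steer the choice, NoGo asymmetries veto
it); and 80:20 acquisition above 80% within ten epochs. The searches and
their targets ship in `scratch/`-style scripts' final values embedded as
the `NetworkParams` defaults.

The calibrated network reproduces: acquisition and reversal learning
with the classic perseveration dip; higher pre-reversal asymptotes for
longer pauses; the 40:10 environment ordering (long pauses learn where
short pauses cannot; overall accuracies near the reported 53%/65%); the
85:15 short-pause accuracy (~74% overall, reported 78 ± 7); the
closed-loop pause pattern (≈250 ms early and after the reversal,
≈160-190 ms once the task is learned, pinned near the ceiling in 40:10);
and the rebound-magnitude effect (post-reversal asymptote rises
monotonically, pre-reversal asymptote flat). It does **not** reproduce
the 85:15 overall-accuracy ordering (short over long): in this
parametrization deeper recruitment also speeds post-reversal
*re*-learning, so long-pause networks recover quickly rather than
perseverating, the environments do not reverse the fixed-pause ranking,
and the entropy-modulated network ties rather than beats the best fixed
pause. The corresponding acceptance tests assert the published pattern
and fail; they are left red deliberately. The M1-ablation experiment is
likewise sign-inverted here: with this NoGo calibration the pathway acts
as a weight-driven brake rather than a response-specific suppressor, so
extra feedback excitability slightly impairs rather than supports
reversal.

## The Beta-belief learner

Per (stimulus, action), a Beta(α, β) belief over the reward probability,
prior (1, 1). The chosen action updates and decays multiplicatively,
α ← γ(α + r), β ← γ(β + 1 − r) — the decay preserves the posterior mean
and inflates its variance. The unchosen action's belief relaxes toward
the prior (α ← γα + (1−γ)·1): pure multiplicative decay of untouched
counts drives them to numerical zero, after which the Beta sampler
degenerates and the action is never explored again, so the to-prior form
is the default and the multiplicative form is kept only for sensitivity
analysis. Action selection is Thompson sampling. γ is fixed
(fast 0.90 / middle 0.98 / slow 0.995 in the canonical grid) or annealed
on the logit scale by the smoothed trial-to-trial change in policy
entropy, logit(γ) = γ0 + γ1·ΔH with γ1 < 0, ΔH initialized at 1 bit and
tracked by a delta rule with rate η. Defaults (γ0 = 3.4, γ1 = −2.0,
η = 0.3) come from a seeded grid search maximizing total reward on the
80:20 task. The policy probability P(Q1 > Q2) is computed to 1e-8 by a
composite Gauss-Legendre rule in the probability scale of the first
belief (singularity-free even for pseudo-counts below one), verified by
grid refinement with adaptive quadrature as fallback.

## The opponent actor-critic

A critic per stimulus learns V by δ = r − V, V ← V + ηc·δ; actors
G ← G + ηG·δ and N ← N − ηN·δ for the chosen action; softmax policy on
βG·G − βN·N. As printed with both actors receiving +δ the policy
difference is invariant under equal gains and the model cannot learn, so
the cost actor uses the opponent sign by default (the printed same-sign
form and the original multiplicative-Hebbian actor update are available
behind flags). After each update all weights contract toward the naive
prior 0.5 with factor expit(γ); γ is fixed ({1, 4, 7} as the
fast/middle/slow grid) or γ = γ0 + γ1·H with the instantaneous policy
entropy H (γ0 = 6, γ1 = −5; smoothing optional). Defaults from a seeded
grid search on the 85:15 task. This model reproduces the full trade-off:
slow decay gives a perfect asymptote with a deep post-reversal crash,
fast decay a low asymptote with no dip, and the entropy-annealed decay
achieves the slow asymptote with fast recovery and the highest total
reward of its grid.

## Sweeps and statistics

`run_sweep` executes (condition × schedule × run) cells with per-cell
seeds derived by an FNV-style hash of (master seed, condition, schedule,
run) — reruns are bit-identical and any cell is reproducible in
isolation. Accuracy is the fraction of optimal-action choices with
"optimal" defined by the contingencies in force on that trial, computed
over training trials (probes reported separately). The adaptive-vs-fixed
comparison models each condition's per-schedule accuracy as Gaussian
with the sample mean and SD, reports the expected difference in summed
mean accuracy between the adaptive condition and the best fixed one, and
a Monte-Carlo posterior probability that the adaptive condition does not
exceed it (exact for one fixed condition; checked against the closed
form). Cohen's d uses the pooled-SD two-group formula.

## Problem sizes

The default test suite runs the network at 5-8 instantiations per cell
and the algorithmic models at 8-15; `scripts/acceptance.py` uses 50 per
fixed-pause cell and 20 per cell of the adaptive-vs-fixed grid. The
cycle loop is compiled (numba); a 400-trial network run takes ~1.3 s.

## What the synthetic task does and does not capture

The generator reproduces the study conditions exactly (exact per-epoch
reward counts, independent arms, a single mid-training reversal). It has
no drifting contingencies, no reward magnitudes, no inter-trial
dependencies and no response-time pressure, so passing tests speak to
learning dynamics under abrupt non-stationarity with matched reward
statistics — not to volatility estimation in continuously changing
environments, which the decay/pause mechanisms only approximate.

## Known limitations

* The 85:15 flexibility-stability ordering and the M1-ablation sign are
  not reproduced (details above and in the acceptance tests).
* Only pause-duration control is implemented; pause depth is exposed
  (`pause_depth`) but uncalibrated.
* The subthalamic nucleus is not modeled (nothing in the simulated
  manipulations touches it); spiking dynamics, reaction times and
  dopamine mechanisms beyond phasic burst/dip/rebound are out of scope.
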
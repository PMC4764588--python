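# striatan

Models of how striatal acetylcholine could set the basal ganglia's
learning rate — and of why any *fixed* learning rate loses somewhere.

A learner facing probabilistic feedback in a world that occasionally
changes must trade **stability** (ignore the 15% of spurious outcomes
once a contingency is known) against **flexibility** (re-learn fast when
the contingency reverses). `striatan` implements one account of how the
striatum could manage that trade-off — the pause in tonically active
cholinergic interneuron (TAN) firing that follows salient outcomes
gates corticostriatal plasticity, and its duration can be driven by the
uncertainty carried in the spiny-neuron population code — at three
levels of description:

* **`striatan.network`** — a rate-coded basal-ganglia circuit
  (Go/NoGo spiny units, pallidal gating, thalamocortical choice,
  dopamine bursts/dips, TANs with an accommodation-current burst-pause).
  Pause duration controls how deep into the population plasticity
  recruitment reaches; closed-loop modes command the pause from the Go
  population's Shannon entropy or from a dendritic AND-conjunction
  approximation to it.
* **`striatan.bayes`** — the computational-level account: Beta beliefs
  per (stimulus, action) with multiplicative pseudo-count decay γ
  (mean-preserving, variance-inflating — the analogue of a shorter
  pause), Thompson sampling, and γ annealed on the logit scale by the
  smoothed change in policy entropy.
* **`striatan.opal`** — the algorithmic account: an opponent
  actor-critic (G/N weights, softmax on β_G·G − β_N·N) whose weights
  decay toward the naive prior 0.5 with factor expit(γ), fixed or
  annealed by policy entropy.

`striatan.task` generates the two-alternative probabilistic
reversal-learning task (exact per-epoch reward counts, independent
arms, reversal at trial 200 of 400), `striatan.tan` the uncertainty
read-outs, and `striatan.experiments` the seeded sweep machinery,
accuracy/divergence metrics, and the Gaussian adaptive-vs-fixed
comparison. The central quantity throughout is the Shannon entropy of
the action distribution, H = −Σ_t Σ_a p_a(t) log2 p_a(t), read off the
normalized Go-unit rates during action selection.

## A worked example

```python
from striatan import (NetworkParams, PauseCalibration, TanMode,
                      TaskConfig, run_network_session)

params = NetworkParams()
cal = PauseCalibration(params)          # tau_ba -> pause-duration map
df = run_network_session(
    TaskConfig(p_opt=0.8, p_sub=0.2, seed=12),   # 80:20, reversal at 200
    TanMode("fixed", 190.0),                     # fixed 190 ms TAN pause
    params=params, seed=13, calibration=cal,
)
print(df.groupby("epoch")["correct"].mean().round(2).tolist())
```

prints (epochs 0-9 acquisition, 10-19 after the reversal):

```
[0.52, 0.72, 0.82, 0.98, 0.95, 0.95, 0.98, 0.95, 0.92, 0.95,
 0.1, 0.25, 0.5, 0.62, 0.68, 0.85, 1.0, 0.92, 0.98, 0.92]
```

The network acquires the 80:20 contingency within a few epochs,
collapses to 10% correct when the contingencies exchange (perseveration
on the formerly correct response), then recovers as dips erode the old
Go weights and the alternative response is re-reinforced. Each trial's
record also carries the population entropy `H`, the AND-conjunction
count `Hconj`, the commanded `tau_ba`, the realized `pause_ms` and the
Go-weight divergence `w_div`.

Running `examples/06_entropy_feedback.py` shows the closed loop: with
`TanMode("entropy")` the pause follows the network's own uncertainty —
about 250 ms early in training and again right after the reversal,
160-190 ms once the task is learned.

The other examples (`examples/01` … `04`) walk the task generator, the
uncertainty read-outs, and the two algorithmic models; each prints a
few numbers and a line on what they mean.

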
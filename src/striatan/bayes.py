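"""Approximately Bayesian learner with entropy-annealed multiplicative decay.

For i.i.d. Bernoulli rewards the exact posterior over each action's
reward probability is Beta(alpha, beta).  Because the task is
non-stationary, the pseudo-counts are decayed multiplicatively by
gamma in (0, 1] on every trial:

    alpha <- gamma * (alpha + r),    beta <- gamma * (beta + 1 - r)

Decay preserves the posterior mean while inflating its variance — the
algorithmic analogue of a shorter TAN pause, which keeps the striatal
population code labile.  gamma may be fixed, or annealed by the smoothed
trial-to-trial change in policy entropy on the logit scale
(logit(gamma) = gamma0 + gamma1 * dH, gamma1 < 0): rising uncertainty
(e.g. at a contingency reversal) speeds forgetting; settled, confident
behavior slows it.

Action selection is Thompson sampling: one draw from each action's
belief, the argmax wins, so the long-run choice frequency of action 1
equals P(Q1 > Q2) under the current beliefs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .task import Schedule, TaskConfig, make_schedule

__all__ = [
    "BetaBelief",
    "DecayParams",
    "EntropyTracker",
    "update_belief",
    "policy_probabilities",
    "policy_entropy",
    "update_entropy_delta",
    "adapt_gamma",
    "select_action",
    "BayesLearner",
    "run_bayes_session",
]


@dataclass
class BetaBelief:
    """Beta pseudo-counts for one (stimulus, action)."""

    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta pseudo-counts must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class DecayParams:
    """Fixed or entropy-adaptive decay.

    In adaptive mode gamma = logistic(gamma0 + gamma1 * dH) with
    gamma1 <= 0; ``eta`` is the delta-rule smoothing rate of the
    entropy-change tracker.
    """

    mode: str = "fixed"  # "fixed" | "adaptive"
    gamma: float = 0.98
    gamma0: float = 3.4
    gamma1: float = -2.0
    eta: float = 0.3
    # garbled sign convention in the source description: the default
    # tracks delta = (H_t - H_{t-1}) - dH; flip for the literal reading
    flip_delta_sign: bool = False
    # how beliefs of the NOT-chosen action decay: "to_prior" relaxes
    # them toward Beta(1, 1) (stale beliefs lose confidence and regain
    # maximal uncertainty); "multiplicative" scales the counts toward
    # zero, which starves an action of exploration once its counts
    # underflow and is kept only for sensitivity analysis
    unchosen_decay: str = "to_prior"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown decay mode {self.mode!r}")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("fixed gamma must lie in (0, 1]")
        if self.gamma1 > 0:
            raise ValueError("gamma1 must be <= 0 (faster decay under rising uncertainty)")
        if not (0.0 < self.eta <= 1.0):
            raise ValueError("eta must lie in (0, 1]")
        if self.unchosen_decay not in ("to_prior", "multiplicative"):
            raise ValueError(f"unknown unchosen_decay {self.unchosen_decay!r}")


@dataclass
class EntropyTracker:
    """Smoothed trial-to-trial policy-entropy change.

    Initialized at 1 bit (the maximum possible policy entropy for two
    actions) so the learner starts maximally uncertain.
    """

    deltaH: float = 1.0
    last_H: float | None = None


def update_belief(belief: BetaBelief, reward: int, gamma: float) -> BetaBelief:
    """One observation followed by multiplicative decay."""
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward!r}")
    if not (0.0 < gamma <= 1.0):
        raise ValueError("gamma must lie in (0, 1]")
    return BetaBelief(
        alpha=gamma * (belief.alpha + reward),
        beta=gamma * (belief.beta + 1 - reward),
    )


def decay_belief(
    belief: BetaBelief, gamma: float, mode: str = "to_prior",
    prior: tuple[float, float] = (1.0, 1.0),
) -> BetaBelief:
    """Decay without an observation — applied to the unchosen action.

    ``to_prior`` mixes the counts toward the Beta(1, 1) prior so a stale
    belief relaxes to maximal uncertainty; ``multiplicative`` scales the
    counts directly as the chosen-action rule does.
    """
    if mode == "multiplicative":
        return BetaBelief(alpha=gamma * belief.alpha, beta=gamma * belief.beta)
    return BetaBelief(
        alpha=gamma * belief.alpha + (1.0 - gamma) * prior[0],
        beta=gamma * belief.beta + (1.0 - gamma) * prior[1],
    )


@lru_cache(maxsize=1)
def _gl_nodes(order: int = 16) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(order)


def _p_first_beats_second(a1: float, b1: float, a2: float, b2: float,
                          n_seg: int) -> float:
    """P(X1 > X2) by quadrature in the probability scale of X1.

    With u = F_1(x), the integral of f_1(x) F_2(x) becomes
    int_0^1 F_2(Q_1(u)) du — a bounded, monotone integrand with no
    endpoint singularities even for pseudo-counts below 1 — evaluated
    with a composite Gauss-Legendre rule.  The integrand is a sigmoidal
    cliff located where belief 2's mass lives; segments are concentrated
    on the image of that region under F_1 so the rule converges without
    adaptive subdivision even for nearly disjoint beliefs."""
    n2 = a2 + b2
    mu2 = a2 / n2
    sd2 = math.sqrt(a2 * b2 / (n2 * n2 * (n2 + 1.0)))
    x_lo = 0.0 if a2 < 1.0 else max(0.0, mu2 - 12.0 * sd2)
    x_hi = 1.0 if b2 < 1.0 else min(1.0, mu2 + 12.0 * sd2)
    u_lo, u_hi = special.betainc(a1, b1, np.array([x_lo, x_hi]))
    inner = np.linspace(u_lo, u_hi, n_seg + 1)
    # geometric refinement toward u = 0 and u = 1: Q_1 (and hence the
    # integrand's derivative) can behave algebraically at the endpoints
    # when pseudo-counts fall below 1
    tails = np.power(10.0, -np.arange(1.0, 8.0))
    edges = np.unique(np.concatenate([[0.0], tails, inner, 1.0 - tails, [1.0]]))
    edges = edges[(edges >= 0.0) & (edges <= 1.0)]
    if len(edges) < 3:
        edges = np.linspace(0.0, 1.0, n_seg + 1)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    t, w = _gl_nodes()
    u = mid[:, None] + half[:, None] * t[None, :]
    x = special.betaincinv(a1, b1, u)
    vals = special.betainc(a2, b2, x)
    return float(np.sum(w[None, :] * vals * half[:, None]))


def policy_probabilities(b1: BetaBelief, b2: BetaBelief, tol: float = 1e-8) -> tuple[float, float]:
    """(P(Q1 > Q2), P(Q2 > Q1)) for independent Beta beliefs.

    Numerical integration of f_1(x) * F_2(x) over [0, 1] to absolute
    tolerance ``tol``: a composite Gauss-Legendre rule verified by grid
    refinement, with adaptive quadrature as fallback if refinement
    disagrees.
    """
    a1, bb1, a2, b2 = b1.alpha, b1.beta, b2.alpha, b2.beta
    p = _p_first_beats_second(a1, bb1, a2, b2, n_seg=8)
    p_ref = _p_first_beats_second(a1, bb1, a2, b2, n_seg=16)
    if abs(p - p_ref) > tol:
        d1 = stats.beta(a1, bb1)
        d2 = stats.beta(a2, b2)
        p_ref, err = integrate.quad(
            lambda x: d1.pdf(x) * d2.cdf(x), 0.0, 1.0, epsabs=tol, limit=200
        )
        if not math.isfinite(p_ref) or err > 1e-4:
            raise RuntimeError(f"non-convergent quadrature (estimate {p_ref}, err {err})")
    p = min(1.0, max(0.0, p_ref))
    return p, 1.0 - p


def policy_entropy(p: tuple[float, float] | np.ndarray) -> float:
    """Shannon entropy (bits) of an action distribution."""
    arr = np.asarray(p, dtype=float)
    if not np.isclose(arr.sum(), 1.0, atol=1e-6):
        raise ValueError("probabilities must sum to 1")
    nz = arr[arr > 0.0]
    return float(-(nz * np.log2(nz)).sum())


def update_entropy_delta(
    tracker: EntropyTracker, H_t: float, params: DecayParams
) -> EntropyTracker:
    """Delta-rule update of the smoothed entropy change."""
    prev_H = tracker.last_H if tracker.last_H is not None else H_t
    raw = H_t - prev_H
    delta = raw - tracker.deltaH
    if params.flip_delta_sign:
        delta = -delta
    return EntropyTracker(deltaH=tracker.deltaH + params.eta * delta, last_H=H_t)


def adapt_gamma(params: DecayParams, tracker: EntropyTracker) -> float:
    """gamma = logistic(gamma0 + gamma1 * dH)."""
    z = params.gamma0 + params.gamma1 * tracker.deltaH
    return 1.0 / (1.0 + math.exp(-z))


def select_action(beliefs: list[BetaBelief], rng: np.random.Generator) -> int:
    """Thompson sampling: sample one Q per action, pick the argmax."""
    draws = [rng.beta(b.alpha, b.beta) for b in beliefs]
    return int(np.argmax(draws))


class BayesLearner:
    """Beta-belief bank over (stimulus, action) with decay and annealing."""

    def __init__(self, config: TaskConfig, decay: DecayParams, seed: int = 0):
        self.config = config
        self.decay = decay
        self.rng = np.random.default_rng(seed)
        self.beliefs = [
            [BetaBelief() for _ in range(config.n_actions)]
            for _ in range(config.n_stimuli)
        ]
        self.trackers = [EntropyTracker() for _ in range(config.n_stimuli)]

    def current_gamma(self, stimulus: int) -> float:
        if self.decay.mode == "fixed":
            return self.decay.gamma
        return adapt_gamma(self.decay, self.trackers[stimulus])

    def act(self, stimulus: int) -> int:
        return select_action(self.beliefs[stimulus], self.rng)

    def learn(self, stimulus: int, action: int, reward: int) -> float:
        """Belief update, decay, and entropy-tracker update; returns gamma used.

        The policy-entropy tracker is only advanced in adaptive mode (it
        has no behavioral effect under fixed decay, and the quadrature it
        needs dominates runtime).
        """
        row = self.beliefs[stimulus]
        if self.decay.mode == "adaptive":
            p1, _ = policy_probabilities(row[0], row[1])
            H = policy_entropy((p1, 1.0 - p1))
            self.trackers[stimulus] = update_entropy_delta(
                self.trackers[stimulus], H, self.decay
            )
        gamma = self.current_gamma(stimulus)
        for a in range(len(row)):
            if a == action:
                row[a] = update_belief(row[a], reward, gamma)
            else:
                row[a] = decay_belief(row[a], gamma, self.decay.unchosen_decay)
        return gamma


def run_bayes_session(
    config: TaskConfig,
    decay: DecayParams,
    seed: int = 0,
    schedule: Schedule | None = None,
) -> pd.DataFrame:
    """One learner on one task instantiation; tidy per-trial records.

    Stimuli alternate deterministically (S1, S2, S1, ...); the schedule is
    generated from ``config`` (seed offset so task and learner noise are
    independent) unless one is passed in.
    """
    if schedule is None:
        sched_cfg = TaskConfig(
            p_opt=config.p_opt, p_sub=config.p_sub, n_epochs=config.n_epochs,
            trials_per_epoch=config.trials_per_epoch,
            reversal_epoch=config.reversal_epoch, seed=config.seed + 1_000_003,
        )
        schedule = make_schedule(sched_cfg)
    learner = BayesLearner(config, decay, seed=seed)
    rows = []
    for trial in range(config.n_trials):
        for stim in range(config.n_stimuli):
            action = learner.act(stim)
            reward = int(schedule.outcomes[trial, stim, action])
            gamma = learner.learn(stim, action, reward)
            opt = schedule.optimal_action(trial)
            rows.append(
                {
                    "trial": trial,
                    "stimulus": stim,
                    "action": action,
                    "reward": reward,
                    "correct": int(action == opt),
                    "phase": schedule.phase(trial),
                    "epoch": trial // config.trials_per_epoch,
                    "gamma": gamma,
                    "deltaH": learner.trackers[stim].deltaH,
                }
            )
    return pd.DataFrame(rows)
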
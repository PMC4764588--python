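"""Opponent actor-critic (OpAL) with entropy-annealed weight decay.

A single critic per stimulus learns V from the reward prediction error
delta = r - V.  Two opponent actors per (stimulus, action) — G ("Go",
benefit) and N ("NoGo", cost) — are trained by the same delta with their
own learning rates, and choices follow a softmax on beta_G*G - beta_N*N.

The cholinergic mechanism enters as a multiplicative decay applied to
all actor weights after each trial's update: with lam = expit(gamma),

    w <- w * lam + 0.5 * (1 - lam)

a contraction toward the naive prior 0.5.  gamma is either fixed (large
gamma / lam near 1 mimics a long TAN pause: stable, slow to reverse) or
annealed linearly by the policy entropy, gamma = gamma0 + gamma1*H with
gamma1 < 0, so uncertain behavior forgets faster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import Schedule, TaskConfig, make_schedule

__all__ = [
    "OpalParams",
    "OpalState",
    "critic_update",
    "actor_update",
    "policy",
    "decay_weights",
    "adapt_gamma_opal",
    "run_opal_session",
]


@dataclass(frozen=True)
class OpalParams:
    eta_c: float = 0.1
    eta_G: float = 0.3
    eta_N: float = 0.3
    beta_G: float = 4.0
    beta_N: float = 4.0
    decay_mode: str = "fixed"  # "fixed" | "adaptive"
    gamma: float = 4.0  # logit-scale decay; lam = expit(gamma)
    gamma0: float = 6.0
    gamma1: float = -5.0
    # the original OpAL multiplies the actor increment by the weight
    # itself (Hebbian three-factor form); off by default, matching the
    # plain-delta update used here
    hebbian_actor: bool = False
    # the opponent N actor learns from the negated prediction error
    # (costs grow when outcomes disappoint); with opponent_n=False both
    # actors receive identical increments, leaving beta_G*G - beta_N*N
    # invariant under equal gains — kept only for comparison
    opponent_n: bool = True
    smooth_entropy: float | None = None  # optional EMA rate for annealing H

    def __post_init__(self) -> None:
        if min(self.eta_c, self.eta_G, self.eta_N) <= 0:
            raise ValueError("learning rates must be positive")
        if self.decay_mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown decay mode {self.decay_mode!r}")


@dataclass
class OpalState:
    V: np.ndarray  # (n_stimuli,)
    G: np.ndarray  # (n_stimuli, n_actions)
    N: np.ndarray  # (n_stimuli, n_actions)
    smoothed_H: float = 1.0

    @classmethod
    def initial(cls, n_stimuli: int = 2, n_actions: int = 2) -> "OpalState":
        return cls(
            V=np.zeros(n_stimuli),
            G=np.full((n_stimuli, n_actions), 0.5),
            N=np.full((n_stimuli, n_actions), 0.5),
        )


def critic_update(state: OpalState, stimulus: int, reward: float, eta_c: float) -> float:
    """V <- V + eta_c * delta; returns delta."""
    delta = reward - state.V[stimulus]
    state.V[stimulus] += eta_c * delta
    return delta


def actor_update(
    state: OpalState, stimulus: int, action: int, delta: float, params: OpalParams
) -> None:
    """G/N update for the chosen action under the current stimulus."""
    n_delta = -delta if params.opponent_n else delta
    if params.hebbian_actor:
        state.G[stimulus, action] += params.eta_G * state.G[stimulus, action] * delta
        state.N[stimulus, action] += params.eta_N * state.N[stimulus, action] * n_delta
    else:
        state.G[stimulus, action] += params.eta_G * delta
        state.N[stimulus, action] += params.eta_N * n_delta


def policy(state: OpalState, stimulus: int, params: OpalParams) -> np.ndarray:
    """Softmax over beta_G*G - beta_N*N, max-subtracted for stability."""
    z = params.beta_G * state.G[stimulus] - params.beta_N * state.N[stimulus]
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def decay_weights(state: OpalState, gamma: float) -> None:
    """Contract every actor weight toward 0.5 with factor expit(gamma)."""
    lam = 1.0 / (1.0 + math.exp(-gamma))
    state.G = state.G * lam + 0.5 * (1.0 - lam)
    state.N = state.N * lam + 0.5 * (1.0 - lam)


def adapt_gamma_opal(params: OpalParams, p: np.ndarray) -> float:
    """gamma = gamma0 + gamma1 * H(policy), H in bits."""
    nz = p[p > 0.0]
    H = float(-(nz * np.log2(nz)).sum())
    return params.gamma0 + params.gamma1 * H


def run_opal_session(
    config: TaskConfig,
    params: OpalParams,
    seed: int = 0,
    schedule: Schedule | None = None,
) -> pd.DataFrame:
    """One OpAL agent on one task instantiation; tidy per-trial records."""
    if schedule is None:
        sched_cfg = TaskConfig(
            p_opt=config.p_opt, p_sub=config.p_sub, n_epochs=config.n_epochs,
            trials_per_epoch=config.trials_per_epoch,
            reversal_epoch=config.reversal_epoch, seed=config.seed + 1_000_003,
        )
        schedule = make_schedule(sched_cfg)
    rng = np.random.default_rng(seed)
    state = OpalState.initial(config.n_stimuli, config.n_actions)
    rows = []
    for trial in range(config.n_trials):
        for stim in range(config.n_stimuli):
            p = policy(state, stim, params)
            action = int(rng.random() < p[1])
            reward = int(schedule.outcomes[trial, stim, action])
            delta = critic_update(state, stim, reward, params.eta_c)
            actor_update(state, stim, action, delta, params)
            if params.decay_mode == "adaptive":
                if params.smooth_entropy is not None:
                    nz = p[p > 0.0]
                    H_inst = float(-(nz * np.log2(nz)).sum())
                    state.smoothed_H += params.smooth_entropy * (H_inst - state.smoothed_H)
                    gamma = params.gamma0 + params.gamma1 * state.smoothed_H
                else:
                    gamma = adapt_gamma_opal(params, p)
            else:
                gamma = params.gamma
            decay_weights(state, gamma)
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
                    "G_opt": state.G[stim, 0],
                    "G_sub": state.G[stim, 1],
                }
            )
    return pd.DataFrame(rows)
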
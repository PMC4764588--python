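"""Two-alternative probabilistic reversal-learning task.

Two stimuli, two responses, Bernoulli rewards on a fixed stochastic
schedule: within every 20-trial epoch each (stimulus, action) cell
receives exactly ``round(p * 20)`` rewards at seeded, permuted positions,
so the printed reward rates hold in every epoch.  The two actions'
outcomes are drawn independently (not yoked).  Halfway through training
(trial 200 of 400 under the defaults) the contingencies for the two
actions are exchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "Schedule",
    "make_schedule",
    "feedback",
    "probe_block",
    "SCHEDULES",
]

#: The eight (p_opt, p_sub) reward schedules used across simulations.
SCHEDULES = [
    (0.85, 0.15), (0.80, 0.20), (0.75, 0.25), (0.70, 0.30),
    (0.65, 0.35), (0.60, 0.40), (0.55, 0.45), (0.40, 0.10),
]


@dataclass(frozen=True)
class TaskConfig:
    """Configuration of the reversal task.

    ``trials_per_epoch`` counts trials per stimulus per epoch; with two
    stimuli interleaved (S1, S2, S1, ...) one epoch spans
    ``2 * trials_per_epoch`` presentations, but the trial index used for
    the reversal point counts presentations of a single stimulus, so the
    default 20 epochs x 20 trials gives 400 trials per stimulus with the
    reversal at per-stimulus trial 200.
    """

    p_opt: float = 0.80
    p_sub: float = 0.20
    n_epochs: int = 20
    trials_per_epoch: int = 20
    reversal_epoch: int = 10
    n_stimuli: int = 2
    n_actions: int = 2
    iid_bernoulli: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_sub < self.p_opt <= 1.0):
            raise ValueError(
                f"need 0 <= p_sub < p_opt <= 1, got p_opt={self.p_opt}, p_sub={self.p_sub}"
            )
        if self.n_stimuli != 2 or self.n_actions != 2:
            raise ValueError("the task is fixed at 2 stimuli x 2 actions")
        if not (0 < self.reversal_epoch <= self.n_epochs):
            raise ValueError("reversal_epoch must lie within the training epochs")

    @property
    def n_trials(self) -> int:
        """Training trials per stimulus."""
        return self.n_epochs * self.trials_per_epoch

    @property
    def reversal_trial(self) -> int:
        """0-based per-stimulus trial index at which contingencies reverse."""
        return self.reversal_epoch * self.trials_per_epoch


@dataclass
class Schedule:
    """Pre-generated reward outcome table.

    ``outcomes[trial, stimulus, action]`` is the 0/1 reward that would be
    delivered if ``action`` were taken on presentation ``trial`` of
    ``stimulus``.  For each stimulus, action 0 is optimal before the
    reversal and action 1 after it.
    """

    config: TaskConfig
    outcomes: np.ndarray = field(repr=False)

    def optimal_action(self, trial: int) -> int:
        return 0 if trial < self.config.reversal_trial else 1

    def phase(self, trial: int) -> str:
        return "acquisition" if trial < self.config.reversal_trial else "reversal"

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (columns: trial, stimulus, action, reward)."""
        t, s, a = np.indices(self.outcomes.shape)
        return pd.DataFrame(
            {
                "trial": t.ravel(),
                "stimulus": s.ravel(),
                "action": a.ravel(),
                "reward": self.outcomes.ravel().astype(int),
            }
        )


def _epoch_outcomes(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Exactly round(p*n) rewards at uniformly permuted positions."""
    k = p * n
    k_int = int(round(k))
    if abs(k - k_int) > 1e-9:
        warnings.warn(
            f"reward probability {p} x epoch length {n} is not an integer; "
            f"rounding to {k_int} rewards per epoch",
            stacklevel=3,
        )
    out = np.zeros(n, dtype=np.int8)
    out[: k_int] = 1
    rng.shuffle(out)
    return out


def make_schedule(config: TaskConfig) -> Schedule:
    """Generate the full reward-outcome table for one task instantiation.

    Deterministic given ``config.seed``.  In the default fixed-schedule
    mode each epoch contains exactly ``round(p * trials_per_epoch)``
    rewards per (stimulus, action); with ``iid_bernoulli=True`` outcomes
    are independent Bernoulli draws instead.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trials
    outcomes = np.zeros((n, cfg.n_stimuli, cfg.n_actions), dtype=np.int8)
    for s in range(cfg.n_stimuli):
        for a in range(cfg.n_actions):
            for e in range(cfg.n_epochs):
                lo = e * cfg.trials_per_epoch
                hi = lo + cfg.trials_per_epoch
                # action 0 optimal during acquisition; exchanged at reversal
                pre_p = cfg.p_opt if a == 0 else cfg.p_sub
                post_p = cfg.p_sub if a == 0 else cfg.p_opt
                p = pre_p if e < cfg.reversal_epoch else post_p
                if cfg.iid_bernoulli:
                    outcomes[lo:hi, s, a] = rng.random(cfg.trials_per_epoch) < p
                else:
                    outcomes[lo:hi, s, a] = _epoch_outcomes(p, cfg.trials_per_epoch, rng)
    return Schedule(config=cfg, outcomes=outcomes)


def feedback(schedule: Schedule, trial: int, stimulus: int, action: int) -> int:
    """Pure lookup of the pre-generated outcome; repeated calls identical."""
    n, ns, na = schedule.outcomes.shape
    if not (0 <= trial < n and 0 <= stimulus < ns and 0 <= action < na):
        raise IndexError(
            f"(trial={trial}, stimulus={stimulus}, action={action}) outside "
            f"schedule of shape {schedule.outcomes.shape}"
        )
    return int(schedule.outcomes[trial, stimulus, action])


def probe_block(config: TaskConfig, repetitions: int = 10) -> list[dict]:
    """Probe trials: each stimulus presented, learning off, no feedback.

    Returns ``2 * repetitions`` trial dicts tagged ``probe=True`` so
    learners skip weight updates and no reward is delivered.
    """
    trials = []
    for rep in range(repetitions):
        for s in range(config.n_stimuli):
            trials.append({"stimulus": s, "probe": True, "repetition": rep})
    return trials
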
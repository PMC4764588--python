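"""Uncertainty read-outs over the Go population and the pause feedback law.

During action selection, the normalized firing rates of striatal Go units
are treated as a probability distribution over candidate actions.  Three
statistics summarize that trace:

* :func:`population_entropy` — exact Shannon entropy of the per-cycle
  action distribution, summed over settling cycles (bits);
* :func:`and_conjunctions` — a biophysically plausible linear-readout
  approximation: the count of (cycle, pair) events in which two units
  coding *different* responses are simultaneously supra-threshold
  (coincidence / Boolean-AND detection on a TAN dendrite);
* :func:`total_go_activity` — the plain sum of all activity, included as
  a negative control (it declines with training but does not rise at a
  reversal, so it cannot stand in for entropy).

:class:`FeedbackLaw` maps either uncertainty read-out onto the TAN
accommodation basis time-constant tau_ba, which in turn controls the
duration of the feedback-locked TAN pause: higher uncertainty, longer
pause, stronger effective learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntropyReadout",
    "ConjunctionReadout",
    "FeedbackLaw",
    "population_entropy",
    "and_conjunctions",
    "total_go_activity",
    "feedback_tau",
    "default_pairing",
]

#: cycles whose summed Go activity falls below this floor carry no
#: information about the action distribution and are skipped
ACTIVITY_FLOOR = 1e-8


@dataclass
class EntropyReadout:
    H: float
    per_cycle_p: np.ndarray  # (n_used_cycles, n_actions)


@dataclass
class ConjunctionReadout:
    Hconj: int
    theta: float


def population_entropy(go_trace: np.ndarray, action_map: np.ndarray) -> EntropyReadout:
    """Shannon entropy of the Go population code, summed over cycles.

    Parameters
    ----------
    go_trace
        Array (n_cycles, n_units) of Go firing rates from the action
        selection (minus) phase.
    action_map
        Integer array (n_units,) assigning each Go unit to one response.

    Per cycle, rates are normalized to sum to one, summed within each
    action to give p_a(t), and H = -sum_t sum_a p_a(t) log2 p_a(t).
    0 * log 0 is taken as 0.
    """
    trace = np.asarray(go_trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] == 0:
        raise ValueError("go_trace must be a non-empty (cycles x units) array")
    amap = np.asarray(action_map)
    if amap.shape[0] != trace.shape[1]:
        raise ValueError("action_map length must equal the number of Go units")
    n_actions = int(amap.max()) + 1

    totals = trace.sum(axis=1)
    used = totals > ACTIVITY_FLOOR
    trace = trace[used]
    totals = totals[used]
    if trace.shape[0] == 0:
        return EntropyReadout(H=0.0, per_cycle_p=np.zeros((0, n_actions)))

    norm = trace / totals[:, None]
    p = np.zeros((trace.shape[0], n_actions))
    for a in range(n_actions):
        p[:, a] = norm[:, amap == a].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0.0, p * np.log2(np.where(p > 0.0, p, 1.0)), 0.0)
    H = float(-plogp.sum())
    return EntropyReadout(H=H, per_cycle_p=p)


def default_pairing(action_map: np.ndarray) -> np.ndarray:
    """Fixed cross-response pairing: the k-th unit of response 0 with the
    k-th unit of response 1 (9 pairs for the standard 18-unit layer)."""
    amap = np.asarray(action_map)
    idx0 = np.flatnonzero(amap == 0)
    idx1 = np.flatnonzero(amap == 1)
    if len(idx0) != len(idx1):
        raise ValueError("responses must have equally many Go units to pair")
    return np.column_stack([idx0, idx1])


def and_conjunctions(
    go_trace: np.ndarray, theta: float, pairing: np.ndarray
) -> ConjunctionReadout:
    """Count supra-threshold AND-conjunctions over cycles and pairs.

    A pair j fires on cycle t iff both members exceed ``theta``; the
    read-out is the total count over the trace.
    """
    trace = np.asarray(go_trace, dtype=float)
    pairs = np.asarray(pairing)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairing must be an (n_pairs, 2) index array")
    if pairs.max(initial=-1) >= trace.shape[1]:
        raise ValueError("pairing indexes units outside the trace")
    above = trace > theta
    hits = above[:, pairs[:, 0]] & above[:, pairs[:, 1]]
    return ConjunctionReadout(Hconj=int(hits.sum()), theta=float(theta))


def total_go_activity(go_trace: np.ndarray) -> float:
    """Sum of all Go rates over units and cycles (negative-control statistic)."""
    return float(np.asarray(go_trace, dtype=float).sum())


@dataclass(frozen=True)
class FeedbackLaw:
    """Affine, clamped map from an uncertainty read-out to tau_ba.

    ``tau = tau_lo + (tau_hi - tau_lo) * clip((x - x_lo)/(x_hi - x_lo))``
    — monotone nondecreasing (higher uncertainty never commands a shorter
    pause) and bounded to the calibrated tau_ba range.  ``x_lo``/``x_hi``
    are the read-out values mapped onto the pause-range endpoints; they
    are set from pilot-run read-out ranges.
    """

    mode: str  # "entropy" or "conjunction"
    x_lo: float
    x_hi: float
    tau_lo: float
    tau_hi: float

    def __post_init__(self) -> None:
        if self.mode not in ("entropy", "conjunction"):
            raise ValueError(f"unknown feedback mode {self.mode!r}")
        if not (self.x_hi > self.x_lo and self.tau_hi >= self.tau_lo):
            raise ValueError("feedback law bounds must be ordered")


def feedback_tau(readout: float, law: FeedbackLaw) -> float:
    """Commanded tau_ba for an uncertainty read-out under ``law``."""
    frac = (float(readout) - law.x_lo) / (law.x_hi - law.x_lo)
    frac = min(1.0, max(0.0, frac))
    return law.tau_lo + (law.tau_hi - law.tau_lo) * frac
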
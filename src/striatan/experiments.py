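"""Sweep runner, metrics and model comparisons for the reversal task.

Everything here operates on the tidy per-trial tables produced by the
session runners (one row per trial with ``correct``, ``epoch``,
``phase``, ... columns) and aggregates them into the quantities the
models are judged on: per-epoch accuracy curves, overall training
accuracy, corticostriatal weight divergence, and the Gaussian
fixed-vs-adaptive comparison across reward schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import DecayParams, run_bayes_session
from .network import NetworkParams, PauseCalibration, TanMode, run_network_session
from .opal import OpalParams, run_opal_session
from .task import TaskConfig

__all__ = [
    "SweepSpec",
    "run_sweep",
    "accuracy_curves",
    "overall_accuracy",
    "weight_divergence_curve",
    "compare_adaptive_vs_fixed",
    "cohens_d",
    "derive_seed",
]


def derive_seed(master_seed: int, condition: str, run: int, schedule: str = "") -> int:
    """Deterministic per-cell seed below 2**31 from (master, condition, run)."""
    h = np.uint32(2166136261)
    for ch in f"{master_seed}|{condition}|{schedule}|{run}":
        h = np.uint32((int(h) ^ ord(ch)) * 16777619 & 0xFFFFFFFF)
    return int(h % np.uint32(2**31 - 1))


@dataclass
class SweepSpec:
    """A grid of (condition x schedule x run) simulation cells.

    ``conditions`` maps a label to keyword arguments for the model
    runner: for the network, ``tan_mode`` (:class:`TanMode`) and optional
    ``params`` (:class:`NetworkParams`); for bayes, ``decay``
    (:class:`DecayParams`); for opal, ``params`` (:class:`OpalParams`).
    """

    model: str  # "network" | "bayes" | "opal"
    conditions: dict[str, dict[str, Any]]
    schedules: list[tuple[float, float]] = field(default_factory=lambda: [(0.85, 0.15)])
    n_runs: int = 50
    master_seed: int = 0
    task_kwargs: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in ("network", "bayes", "opal"):
            raise ValueError(f"unknown model {self.model!r}")


def _run_cell(spec: SweepSpec, label: str, cond: dict, p_opt: float,
              p_sub: float, run: int, calibration: PauseCalibration | None) -> pd.DataFrame:
    seed = derive_seed(spec.master_seed, label, run, f"{p_opt}:{p_sub}")
    config = TaskConfig(p_opt=p_opt, p_sub=p_sub, seed=seed, **spec.task_kwargs)
    if spec.model == "network":
        df = run_network_session(
            config, cond["tan_mode"], params=cond.get("params"),
            seed=seed + 7, calibration=calibration,
            probe_repetitions=cond.get("probe_repetitions", 0),
        )
    elif spec.model == "bayes":
        df = run_bayes_session(config, cond["decay"], seed=seed + 7)
    else:
        df = run_opal_session(config, cond["params"], seed=seed + 7)
    df = df.copy()
    df.attrs = {}  # per-session weight snapshots don't survive concat
    df["condition"] = label
    df["schedule"] = f"{p_opt:g}:{p_sub:g}"
    df["run"] = run
    df["seed"] = seed
    return df


def run_sweep(
    spec: SweepSpec,
    progress: Callable[[str], None] | None = None,
) -> pd.DataFrame:
    """Execute every cell of the sweep; returns one tidy concatenated table.

    Seeds are derived deterministically from ``(master_seed, condition,
    schedule, run)``, so a rerun with the same spec is bit-identical and
    individual cells can be reproduced in isolation.  Cell failures are
    collected and re-raised at the end so one bad cell does not discard
    the remainder.
    """
    calibration = None
    if spec.model == "network":
        shared = [c.get("params") for c in spec.conditions.values()]
        base = next((p for p in shared if p is not None), None) or NetworkParams()
        calibration = PauseCalibration(base)
    frames: list[pd.DataFrame] = []
    failures: list[tuple[str, str, int, Exception]] = []
    for label, cond in spec.conditions.items():
        for (p_opt, p_sub) in spec.schedules:
            for run in range(spec.n_runs):
                try:
                    frames.append(
                        _run_cell(spec, label, cond, p_opt, p_sub, run, calibration)
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    failures.append((label, f"{p_opt}:{p_sub}", run, exc))
                if progress is not None:
                    progress(f"{label} {p_opt}:{p_sub} run {run}")
    if failures:
        raise RuntimeError(f"{len(failures)} sweep cells failed: {failures[:3]}")
    return pd.concat(frames, ignore_index=True)


def _training(df: pd.DataFrame) -> pd.DataFrame:
    if "probe" in df.columns:
        return df[~df["probe"].astype(bool)]
    return df


def accuracy_curves(result: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch mean and SD of accuracy per condition (and schedule).

    Accuracy is the fraction of optimal-action choices, with "optimal"
    defined by the contingencies in force on that trial.
    """
    df = _training(result)
    keys = [k for k in ("condition", "schedule") if k in df.columns]
    per_run = (
        df.groupby(keys + ["run", "epoch"], observed=True)["correct"]
        .mean()
        .reset_index(name="accuracy")
    )
    out = (
        per_run.groupby(keys + ["epoch"], observed=True)["accuracy"]
        .agg(["mean", "std"])
        .reset_index()
    )
    return out


def overall_accuracy(result: pd.DataFrame) -> pd.DataFrame:
    """Per-run accuracy over all training trials, with condition labels."""
    df = _training(result)
    keys = [k for k in ("condition", "schedule") if k in df.columns]
    return (
        df.groupby(keys + ["run"], observed=True)["correct"]
        .mean()
        .reset_index(name="accuracy")
    )


def weight_divergence_curve(result: pd.DataFrame, stimulus: int = 0) -> pd.DataFrame:
    """Mean Go-weight divergence (acquisition-optimal minus alternative)
    across trials, averaged over runs, per condition."""
    df = _training(result)
    df = df[df["stimulus"] == stimulus]
    keys = [k for k in ("condition", "schedule") if k in df.columns]
    return (
        df.groupby(keys + ["trial"], observed=True)["w_div"]
        .mean()
        .reset_index(name="divergence")
    )


def compare_adaptive_vs_fixed(
    per_run: pd.DataFrame,
    adaptive_label: str,
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Gaussian comparison of the adaptive condition against the best fixed.

    ``per_run`` is an :func:`overall_accuracy` table spanning the
    adaptive condition and a grid of fixed conditions on (usually two)
    schedules.  Each condition's accuracy per schedule is modelled as
    Normal with the sample mean and SD; the summed mean accuracy over
    schedules (an L1 norm of the mean vector) is compared between the
    adaptive condition and the best fixed condition.

    Returns the expected advantage ``E[||mu_adaptive||_1 - max_fixed
    ||mu_fixed||_1]`` and the Monte-Carlo posterior probability that the
    adaptive condition does *not* exceed the best fixed one, using the
    sampling distribution of each per-schedule mean.
    """
    rng = rng or np.random.default_rng(0)
    stats_tbl = (
        per_run.groupby(["condition", "schedule"], observed=True)["accuracy"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    if adaptive_label not in set(stats_tbl["condition"]):
        raise ValueError(f"missing adaptive condition {adaptive_label!r}")
    labels = [c for c in stats_tbl["condition"].unique()]
    fixed = [c for c in labels if c != adaptive_label]
    if not fixed:
        raise ValueError("no fixed conditions to compare against")

    def summed(label: str) -> tuple[float, np.ndarray]:
        rows = stats_tbl[stats_tbl["condition"] == label]
        mu = rows["mean"].sum()
        se = np.sqrt((rows["std"] ** 2 / rows["count"]).sum())
        draws = rng.normal(mu, se, n_draws)
        return float(mu), draws

    mu_a, draws_a = summed(adaptive_label)
    fixed_mu = {}
    fixed_draws = np.empty((len(fixed), n_draws))
    for i, c in enumerate(fixed):
        fixed_mu[c], fixed_draws[i] = summed(c)
    best_fixed = max(fixed_mu, key=fixed_mu.get)
    advantage = mu_a - fixed_mu[best_fixed]
    p_not_better = float(np.mean(draws_a <= fixed_draws.max(axis=0)))
    return {
        "advantage": float(advantage),
        "best_fixed": best_fixed,
        "p_adaptive_not_better": p_not_better,
        "mu_adaptive": mu_a,
        "mu_fixed": fixed_mu,
    }


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Two-group Cohen's d with the pooled-SD denominator."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    na, nb = len(a), len(b)
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0.0:
        raise ValueError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)
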
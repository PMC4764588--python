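"""Point-neuron primitives: conductance dynamics and the noisy activation.

Each unit is a rate-coded point neuron on a normalized 0-1 potential
scale with excitatory, inhibitory, leak and (for TANs) accommodation
conductances:

    I_net = ge*gbar_e*(Ee - Vm) + gi*gbar_i*(Ei - Vm)
            + gbar_l*(El - Vm) + ga*gbar_a*(Ea - Vm)
    Vm   <- Vm + tau_m * I_net + noise

The output rate is a sharp threshold sigmoid of Vm,

    f(Vm) = gain*[Vm - theta]+ / (1 + gain*[Vm - theta]+),

smoothed by convolution with a Gaussian kernel (sigma = 0.005) to give a
soft threshold; :func:`noisy_activation` evaluates the convolution by
trapezoidal quadrature, and :func:`activation_table` precomputes it on a
fine grid for fast interpolated lookup inside the network loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "UnitParams",
    "AccommodationParams",
    "raw_activation",
    "noisy_activation",
    "activation_table",
    "accommodation_step",
]


@dataclass(frozen=True)
class UnitParams:
    """Conductance and activation parameters for one layer's units."""

    g_bar_e: float = 1.0
    g_bar_i: float = 1.0
    g_bar_l: float = 0.1
    g_bar_a: float = 0.0
    E_e: float = 1.0
    E_i: float = 0.15
    E_l: float = 0.15
    E_a: float = 0.05
    tau_m: float = 0.355
    tau_g: float = 0.7
    kappa: float = 1.0
    gain: float = 600.0
    theta: float = 0.25
    act_noise_sigma: float = 0.005
    vm_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.E_i <= self.E_l < self.E_e):
            raise ValueError("need E_i <= E_l < E_e on the normalized scale")
        if self.tau_m <= 0 or self.tau_g <= 0:
            raise ValueError("time constants must be positive")
        if self.act_noise_sigma <= 0:
            raise ValueError("activation noise kernel width must be positive")


@dataclass(frozen=True)
class AccommodationParams:
    """Activity-dependent accommodation (Ca-dependent K-like) channel.

    ``tau_ba`` is the integration rate of the basis variable (the
    controlled quantity for TAN pauses); ``theta_a``/``theta_d`` are the
    activation and deactivation thresholds with hysteresis between them.
    """

    tau_ga: float = 0.3
    tau_ba: float = 0.02
    theta_a: float = 0.042
    theta_d: float = 0.038

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_d <= self.theta_a < 1.0):
            raise ValueError("need 0 < theta_d <= theta_a < 1")
        if self.tau_ga <= 0 or self.tau_ba <= 0:
            raise ValueError("accommodation rates must be positive")


def raw_activation(vm: np.ndarray | float, gain: float, theta: float) -> np.ndarray:
    """Un-smoothed threshold sigmoid gain*[Vm-theta]+ / (1 + gain*[Vm-theta]+)."""
    d = np.maximum(np.asarray(vm, dtype=float) - theta, 0.0)
    return gain * d / (1.0 + gain * d)


def noisy_activation(
    vm: np.ndarray | float,
    gain: float,
    theta: float,
    sigma: float = 0.005,
    n_kernel: int = 16001,
) -> np.ndarray | float:
    """Gaussian-kernel-smoothed activation, by trapezoidal quadrature.

    Convolves the sharp sigmoid with N(0, sigma^2) over +-6 sigma.
    Monotone nondecreasing in Vm; -> 0 far below threshold and -> 1 far
    above.  Quadrature error is far below 1e-6 at the default resolution.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    v = np.atleast_1d(np.asarray(vm, dtype=float))
    z = np.linspace(-6.0 * sigma, 6.0 * sigma, n_kernel)
    w = np.exp(-0.5 * (z / sigma) ** 2)
    w /= np.trapezoid(w, z)
    # f evaluated at vm - z for every (vm, z) pair
    vals = raw_activation(v[:, None] - z[None, :], gain, theta)
    out = np.trapezoid(vals * w[None, :], z, axis=1)
    return out if np.ndim(vm) else float(out[0])


@lru_cache(maxsize=64)
def activation_table(
    gain: float,
    theta: float,
    sigma: float = 0.005,
    lo: float = -0.12,
    hi: float = 0.40,
    n: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed (vm_grid, rate_grid) for interpolated lookup.

    The grid spans ``theta + lo`` to ``theta + hi``; outside it the rate
    is clamped to the endpoint values (0 below, the asymptote above).
    """
    grid = theta + np.linspace(lo, hi, n)
    vals = np.empty(n)
    # a coarser kernel suffices here: the table's interpolation error
    # dominates the quadrature error at this resolution
    for i in range(0, n, 512):
        vals[i : i + 512] = noisy_activation(
            grid[i : i + 512], gain, theta, sigma, n_kernel=2001
        )
    return grid, vals


def lookup_activation(vm: np.ndarray, table: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    grid, vals = table
    return np.interp(vm, grid, vals)


def accommodation_step(
    ga: float, ba: float, y: float, params: AccommodationParams
) -> tuple[float, float]:
    """One Euler step of the accommodation channel.

    ba integrates the unit's rate at rate tau_ba; ga is driven toward 1
    while ba > theta_a, toward 0 while ba < theta_d, and holds in the
    hysteresis band between the thresholds.
    """
    ba = ba + params.tau_ba * (y - ba)
    if ba > params.theta_a:
        ga = ga + params.tau_ga * (1.0 - ga)
    elif ba < params.theta_d:
        ga = ga + params.tau_ga * (0.0 - ga)
    return ga, ba
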
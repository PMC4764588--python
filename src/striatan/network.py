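"""Rate-coded basal-ganglia network with a cholinergic (TAN) feedback loop.

Architecture (two response channels throughout): a sensory input layer
projects to motor cortex and, through plastic corticostriatal synapses,
to striatal Go (D1) and NoGo (D2) populations of 9 units per response.
Go units inhibit the internal globus pallidus (GPi), disinhibiting the
thalamus; NoGo units inhibit the external segment (GPe), which in turn
inhibits GPi — so the response with the largest Go-NoGo differential is
gated through the thalamocortical loop and wins the lateral-inhibition
race in motor cortex.  A substantia nigra (SNc) unit broadcasts dopamine:
excitatory to Go (D1, plus a contrast-enhancing gain/threshold boost
during feedback) and inhibitory to NoGo (D2).  Tonically active
cholinergic interneurons (TANs) inhibit both MSN populations directly
(M2-like presynaptic suppression) and indirectly through GABAergic
interneurons (nicotinic drive); during feedback a burst drives an
activity-dependent accommodation current that silences the TAN for a
pause whose duration is set by the basis-variable time constant tau_ba,
releasing the MSNs from inhibition exactly while the dopaminergic
prediction-error signal is present.  Longer pauses mean stronger
disinhibition, larger plus-minus activity differentials, and hence a
larger effective learning rate.

Each trial has an action-selection ("minus") phase with TAN output held
at its tonic level, and a feedback ("plus") phase with the executed
response clamped in motor cortex, dopamine clamped to a burst (reward)
or dip (non-reward), and the TAN burst-pause-rebound sequence.
Corticostriatal weights then move by a mixture of Hebbian and
soft-bounded contrastive-Hebbian terms contrasting the settled
selection state with the activity inside the pause's plasticity window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .task import Schedule, TaskConfig, make_schedule
from .tan import (
    FeedbackLaw,
    and_conjunctions,
    default_pairing,
    feedback_tau,
    population_entropy,
    total_go_activity,
)
from ._kernel import settle_loop
from .units import AccommodationParams, activation_table, lookup_activation

__all__ = [
    "NetworkParams",
    "TanMode",
    "BGNetwork",
    "PauseCalibration",
    "run_network_session",
]

# ---------------------------------------------------------------- layout

N_GO_PER_RESP = 9
GO_ACTION_MAP = np.repeat([0, 1], N_GO_PER_RESP)

IN = slice(0, 2)
MC = slice(2, 4)
GO = slice(4, 22)
NG = slice(22, 40)
INT = slice(40, 41)
TAN = slice(41, 42)
SNC = slice(42, 43)
GPE = slice(43, 45)
GPI = slice(45, 47)
THL = slice(47, 49)
N_UNITS = 49


@dataclass(frozen=True)
class NetworkParams:
    """All tunable constants of the network in one place.

    Potentials live on a normalized 0-1 scale.  The unprinted values
    (conductances, gains, projection strengths, dopamine levels, the
    learning rate) form a self-consistent calibrated set chosen so that
    untrained networks choose ~50:50, the 120-280 ms pause grid is
    realizable and monotone in tau_ba, and an 80:20 task is acquired
    within ten epochs (see docs/methods.md).
    """

    # conductance / membrane
    E_e: float = 1.0
    E_i: float = 0.15
    E_l: float = 0.15
    E_a: float = 0.05
    g_bar_e: float = 1.0
    g_bar_i: float = 1.0
    g_bar_l: float = 0.1
    g_bar_l_tan: float = 0.6      # TANs have a fast membrane
    g_bar_l_gp: float = 0.5       # pallidal tonic drive (keeps GPe/GPi in range)
    g_bar_a: float = 0.8          # TAN accommodation channel
    tau_m: float = 0.355
    tau_g: float = 0.7
    # slow conductance integration during feedback: units' activation
    # times stagger by drive strength, so the pause duration sets how
    # deep into the population plasticity recruitment reaches
    tau_g_plus: float = 0.08
    gain: float = 100.0
    gain_tan: float = 600.0
    theta: float = 0.25
    theta_ng: float = 0.23   # D2 MSNs are the more excitable population
    act_noise_sigma: float = 0.005
    vm_noise_mc: float = 0.0015
    vm_noise_snc: float = 0.002

    # tonic leak potentials for endogenously active layers
    E_l_tan: float = 0.26
    E_l_gpe: float = 0.30
    E_l_gpi: float = 0.30
    E_l_int: float = 0.26

    # projection strengths (kappa scaling of the averaged weighted input)
    k_in_mc: float = 0.062
    k_in_go: float = 0.1920
    k_in_ng: float = 0.097
    k_mc_go: float = 0.0590
    k_mc_ng: float = 0.008
    k_snc_go: float = 0.1291
    k_snc_ng: float = 0.23
    k_tan_go: float = 0.1753
    k_tan_ng: float = 0.016
    k_tan_int: float = 0.1328
    k_int_go: float = 0.8856
    k_int_ng: float = 0.03
    k_go_gpi: float = 0.9
    k_ng_gpe: float = 0.5
    k_gpe_gpi: float = 0.09
    k_gpi_thl: float = 0.5
    k_mc_thl: float = 0.06
    k_thl_mc: float = 0.25
    k_mc_lat: float = 0.12

    # dopamine
    da_tonic: float = 0.5
    da_burst: float = 0.9
    da_dip: float = 0.02
    d1_gain_boost: float = 3.9222
    d1_threshold_boost: float = 0.0475

    # acetylcholine
    tans_enabled: bool = True
    m1_enabled: bool = True
    m1_el_increment: float = 0.06
    tan_burst_vm: float = 0.45
    burst_cycles: int = 8
    pause_rate_frac: float = 0.10     # "paused" while rate < frac * tonic
    pause_depth: float = 1.0          # 1 = full silencing during the pause
    rebound_magnitude: float = 0.0
    rebound_rate_gain: float = 0.25   # TAN overshoot = tonic*(1+gain*magnitude)
    rebound_da_gain: float = 0.30     # DA burst scale-up during the rebound
    # dopamine released by the post-pause burst arrives right after the
    # disinhibited window and potentiates the synapses active during it
    rebound_ltp_gain: float = 0.5
    # potentiation requires glutamate release and dopamine within the
    # ACh-gated window, so its rate scales with the pause's share of the
    # feedback phase; depression (low dopamine, no recruitment needed)
    # proceeds at a fixed rate.  Networks without TANs learn at the
    # residual fraction under tonic ACh in both directions.
    ltd_scale: float = 1.0
    control_plasticity_frac: float = 0.3

    # accommodation (tau_ba is the controlled quantity)
    tau_ga: float = 1.0
    theta_a: float = 0.100
    theta_d: float = 0.099
    tau_ba_lo: float = 0.0085
    tau_ba_hi: float = 0.0180

    # trial loop
    cycle_ms: float = 10.0
    minus_min_cycles: int = 15
    minus_max_cycles: int = 60
    minus_state_cycles: int = 20   # settled window defining the minus-phase state
    plus_cycles: int = 50
    motor_threshold: float = 0.95

    # plasticity
    epsilon: float = 0.045
    kappa_hebb: float = 0.05
    w_init_lo: float = 0.45
    w_init_hi: float = 0.55

    # uncertainty read-out
    conj_theta: float = 0.1
    entropy_x_lo: float = 2.0
    entropy_x_hi: float = 25.0
    conj_x_lo: float = 2.0
    conj_x_hi: float = 40.0


@dataclass(frozen=True)
class TanMode:
    """How the TAN pause is controlled on each trial.

    mode 'fixed' uses a constant target pause (ms, via the tau_ba
    calibration); 'entropy' / 'conjunction' close the MSN->TAN feedback
    loop through the corresponding uncertainty read-out; 'none' removes
    the TANs (output clamped tonic, no pause, no burst, no rebound).
    """

    mode: str = "fixed"
    pause_ms: float = 190.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "entropy", "conjunction", "none"):
            raise ValueError(f"unknown tan mode {self.mode!r}")


class PauseCalibration:
    """Monotone tau_ba -> realized pause (ms) lookup and its inverse.

    The TAN layer receives no synaptic input, so its burst-pause
    trajectory depends only on its own parameters; the map is computed
    once by simulating the isolated TAN over a tau_ba grid and kept as a
    piecewise-linear interpolant restricted to its monotone span.
    """

    def __init__(self, params: NetworkParams, n_grid: int = 120):
        self.params = params
        taus = np.linspace(params.tau_ba_lo, params.tau_ba_hi, n_grid)
        pauses = np.array([simulate_tan_pause(params, t) for t in taus])
        # keep the monotone nondecreasing run starting at the shortest
        # realizable pause (integer-cycle quantization makes the raw map
        # jitter by one cycle near threshold knife-edges)
        start = int(np.argmin(pauses))
        keep = np.zeros(len(taus), dtype=bool)
        best = -np.inf
        for i in range(start, len(taus)):
            if pauses[i] >= best:
                best = pauses[i]
                keep[i] = True
        self.taus = taus[keep]
        self.pauses = pauses[keep]
        if len(self.taus) < 2 or self.pauses[-1] <= self.pauses[0]:
            raise RuntimeError("pause calibration failed: map is not increasing")

    @property
    def pause_range_ms(self) -> tuple[float, float]:
        return float(self.pauses[0]), float(self.pauses[-1])

    def tau_for_pause(self, pause_ms: float) -> float:
        """tau_ba whose realized pause is closest to the requested ms.

        Nearest-grid-point selection (not interpolation): the realized
        pause is a deterministic, 10 ms-quantized function of tau_ba, so
        returning an actual grid point guarantees the realized duration
        matches the tabulated one."""
        i = int(np.argmin(np.abs(self.pauses - pause_ms)))
        return float(self.taus[i])

    def pause_for_tau(self, tau_ba: float) -> float:
        return float(np.interp(tau_ba, self.taus, self.pauses))


def simulate_tan_pause(params: NetworkParams, tau_ba: float, n_cycles: int | None = None) -> float:
    """Realized pause (ms) of the isolated TAN for one tau_ba value.

    Burst clamp for ``burst_cycles``, then free evolution under leak and
    accommodation; the pause is the count of cycles with rate below
    ``pause_rate_frac`` of the tonic level, times the cycle duration.
    """
    p = params
    if n_cycles is None:
        n_cycles = p.plus_cycles
    table = activation_table(p.gain_tan, p.theta, p.act_noise_sigma)
    accom = AccommodationParams(
        tau_ga=p.tau_ga, tau_ba=tau_ba, theta_a=p.theta_a, theta_d=p.theta_d
    )
    vm = p.E_l_tan
    ga = 0.0
    ba = 0.0
    tonic = float(np.interp(p.E_l_tan, table[0], table[1]))
    paused = 0
    pause_seen = False
    for c in range(n_cycles):
        if c < p.burst_cycles:
            vm = p.tan_burst_vm
        else:
            inet = p.g_bar_l_tan * (p.E_l_tan - vm) + ga * p.g_bar_a * (p.E_a - vm)
            vm = vm + p.tau_m * inet
        y = float(np.interp(vm, table[0], table[1]))
        ba = ba + accom.tau_ba * (y - ba)
        if ba > accom.theta_a:
            ga = ga + accom.tau_ga * (1.0 - ga)
        elif ba < accom.theta_d:
            ga = ga + accom.tau_ga * (0.0 - ga)
        if c >= p.burst_cycles and y < p.pause_rate_frac * tonic:
            paused += 1
            pause_seen = True
        elif pause_seen:
            break  # single burst-pause event per feedback window
    return paused * p.cycle_ms


# ---------------------------------------------------------------- network


class BGNetwork:
    """One instantiation of the basal-ganglia network.

    Mutable state: plastic corticostriatal weights (input -> Go, input ->
    NoGo, each (2 stimuli x 18 units) in [0, 1]) and the per-trial unit
    state vectors.  Everything else is fixed wiring derived from
    :class:`NetworkParams`.
    """

    def __init__(
        self,
        params: NetworkParams | None = None,
        seed: int = 0,
        calibration: PauseCalibration | None = None,
    ):
        self.params = params or NetworkParams()
        self.rng = np.random.default_rng(seed)
        p = self.params
        self.w_go = self.rng.uniform(p.w_init_lo, p.w_init_hi, size=(2, 18))
        self.w_ng = self.rng.uniform(p.w_init_lo, p.w_init_hi, size=(2, 18))
        self.calibration = calibration or PauseCalibration(p)
        self.pairing = default_pairing(GO_ACTION_MAP)
        self._build_wiring()
        self._table_base = activation_table(p.gain, p.theta, p.act_noise_sigma)
        self._table_ng = activation_table(p.gain, p.theta_ng, p.act_noise_sigma)
        self._table_tan = activation_table(p.gain_tan, p.theta, p.act_noise_sigma)
        #: tonic TAN rate implied by its leak potential (used both as the
        #: action-selection clamp level and the pause-measurement baseline)
        self.tan_tonic = float(
            np.interp(p.E_l_tan, self._table_tan[0], self._table_tan[1])
        )

    # -- wiring -----------------------------------------------------

    def _build_wiring(self) -> None:
        p = self.params
        Ke = np.zeros((N_UNITS, N_UNITS))
        Ki = np.zeros((N_UNITS, N_UNITS))
        go = np.arange(GO.start, GO.stop)
        ng = np.arange(NG.start, NG.stop)
        col = GO_ACTION_MAP  # response column of each MSN within its layer

        # input -> motor cortex (both candidate responses, equally)
        Ke[MC, IN] = p.k_in_mc / 2.0
        # motor cortex -> MSNs of its own column (corollary discharge)
        for r in (0, 1):
            Ke[go[col == r], MC.start + r] = p.k_mc_go
            Ke[ng[col == r], MC.start + r] = p.k_mc_ng
        # dopamine: D1 excites Go, D2 inhibits NoGo
        Ke[GO, SNC.start] = p.k_snc_go
        Ki[NG, SNC.start] = p.k_snc_ng
        # TANs: M2-like inhibition of both MSN populations,
        # nicotinic excitation of GABAergic interneurons
        Ki[GO, TAN.start] = p.k_tan_go
        Ki[NG, TAN.start] = p.k_tan_ng
        Ke[INT, TAN.start] = p.k_tan_int
        Ki[GO, INT.start] = p.k_int_go
        Ki[NG, INT.start] = p.k_int_ng
        # pallidal gating chain
        for r in (0, 1):
            Ki[GPI.start + r, go[col == r]] = p.k_go_gpi / N_GO_PER_RESP
            Ki[GPE.start + r, ng[col == r]] = p.k_ng_gpe / N_GO_PER_RESP
            Ki[GPI.start + r, GPE.start + r] = p.k_gpe_gpi
            Ki[THL.start + r, GPI.start + r] = p.k_gpi_thl
            Ke[THL.start + r, MC.start + r] = p.k_mc_thl
            Ke[MC.start + r, THL.start + r] = p.k_thl_mc
            Ki[MC.start + r, MC.start + (1 - r)] = p.k_mc_lat
        self.Ke = Ke
        self.Ki = Ki
        self._refresh_plastic()

        # per-unit passive parameters
        self.el = np.full(N_UNITS, p.E_l)
        self.el[TAN] = p.E_l_tan
        self.el[GPE] = p.E_l_gpe
        self.el[GPI] = p.E_l_gpi
        self.el[INT] = p.E_l_int
        self.gl = np.full(N_UNITS, p.g_bar_l)
        self.gl[TAN] = p.g_bar_l_tan
        self.gl[GPE] = p.g_bar_l_gp
        self.gl[GPI] = p.g_bar_l_gp
        self.vm_noise = np.zeros(N_UNITS)
        self.vm_noise[MC] = p.vm_noise_mc

    def _refresh_plastic(self) -> None:
        """Write the plastic weight matrices into the drive matrix."""
        p = self.params
        self.Ke[GO, IN] = p.k_in_go * self.w_go.T / 2.0
        self.Ke[NG, IN] = p.k_in_ng * self.w_ng.T / 2.0

    # -- state ------------------------------------------------------

    def _fresh_state(self) -> dict:
        return {
            "vm": self.el.copy(),
            "ge": np.zeros(N_UNITS),
            "gi": np.zeros(N_UNITS),
            "y": np.zeros(N_UNITS),
            "ga": 0.0,
            "ba": 0.0,
        }

    def _snc_vm(self, level: float) -> float:
        """Membrane potential whose (kernel-smoothed) rate equals ``level``."""
        grid, vals = self._table_base
        level = min(max(level, 0.0), float(vals[-1]) - 1e-6)
        if level <= float(vals[0]):
            return float(grid[0])
        return float(np.interp(level, vals, grid))

    # -- core cycle loop --------------------------------------------

    def _settle(
        self,
        state: dict,
        stimulus_vec: np.ndarray,
        n_cycles: int,
        da_level: float,
        *,
        plus: bool,
        mc_clamp: int | None = None,
        tan_free: bool = False,
        tau_ba: float = 0.0,
        el_ng_boost: float = 0.0,
        motor_stop: bool = False,
        record_ng: bool = False,
        rebound: bool = False,
    ) -> dict:
        """Advance the network ``n_cycles`` (or until a motor unit crosses
        threshold when ``motor_stop``).  Returns traces and summaries.

        The cycle loop itself runs in the compiled kernel
        (:func:`striatan._kernel.settle_loop`); all noise is drawn here
        so a fixed seed reproduces the trajectory exactly."""
        p = self.params
        vm, ge, gi, y = state["vm"], state["ge"], state["gi"], state["y"]
        tau_g = p.tau_g_plus if plus else p.tau_g
        el = self.el.copy()
        if el_ng_boost:
            el[NG] += el_ng_boost
        tonic = self.tan_tonic
        pause_floor = tonic * (1.0 - p.pause_depth)
        if plus and da_level > p.da_tonic:
            # D1 contrast enhancement for Go units during feedback
            table_go = activation_table(
                p.gain * (1.0 + p.d1_gain_boost * da_level),
                p.theta + p.d1_threshold_boost * da_level,
                p.act_noise_sigma,
            )
            use_go = True
        else:
            table_go = self._table_base
            use_go = False

        da_eff = da_level
        use_rebound_da = bool(
            rebound and p.rebound_magnitude > 0 and da_level > p.da_tonic
        )
        da_rebound = min(
            0.995, da_level * (1.0 + p.rebound_da_gain * p.rebound_magnitude)
        )
        rebound_rate = min(
            1.0, tonic * (1.0 + p.rebound_rate_gain * p.rebound_magnitude)
        )

        go_trace = np.empty((n_cycles, 18))
        ng_trace = np.empty((n_cycles, 18))
        mc_trace = np.empty((n_cycles, 2))
        tan_rate = np.empty(n_cycles)
        pause_mask = np.zeros(n_cycles, dtype=np.bool_)
        mc_noise = self.rng.normal(0.0, p.vm_noise_mc, (n_cycles, 2))
        snc_noise = self.rng.normal(0.0, p.vm_noise_snc, n_cycles)

        stim_idx = int(np.argmax(stimulus_vec))
        used, paused_cycles, _ = settle_loop(
            self.Ke, self.Ki, self.gl, el, vm, ge, gi, y,
            n_cycles,
            tau_g, p.tau_m, p.g_bar_e, p.g_bar_i,
            p.E_e, p.E_i,
            self._table_base[0], self._table_base[1],
            self._table_ng[0], self._table_ng[1],
            use_go, table_go[0], table_go[1],
            0.40, stim_idx,
            self._snc_vm(da_eff), self._snc_vm(da_rebound), snc_noise,
            mc_noise, -1 if mc_clamp is None else int(mc_clamp), 0.40,
            bool(tan_free), tonic, p.tan_burst_vm, p.burst_cycles,
            self._table_tan[0], self._table_tan[1],
            p.g_bar_l_tan, p.E_l_tan, p.g_bar_a, p.E_a,
            max(tau_ba, 1e-6), p.tau_ga, p.theta_a, p.theta_d,
            p.pause_rate_frac * tonic, pause_floor, rebound_rate,
            use_rebound_da,
            bool(motor_stop), p.minus_min_cycles, p.motor_threshold,
            go_trace, ng_trace, mc_trace, tan_rate, pause_mask,
        )
        if not np.all(np.isfinite(y)):
            bad = int(np.flatnonzero(~np.isfinite(y))[0])
            raise FloatingPointError(f"non-finite rate at unit {bad} after settling")

        choice = None
        if motor_stop:
            final_mc = mc_trace[used - 1]
            if abs(final_mc[0] - final_mc[1]) < 1e-12:
                choice = int(self.rng.integers(2))
            else:
                choice = int(np.argmax(final_mc))
        return {
            "go_trace": go_trace[:used],
            "ng_trace": ng_trace[:used] if record_ng else None,
            "mc_trace": mc_trace[:used],
            "tan_rate": tan_rate[:used],
            "cycles": used,
            "choice": choice,
            "pause_cycles": paused_cycles,
            "pause_mask": pause_mask[:used],
        }

    # -- phases -----------------------------------------------------

    def run_minus_phase(self, stimulus: int) -> dict:
        """Action selection with TAN output at its tonic level."""
        state = self._fresh_state()
        stim = np.zeros(2)
        stim[stimulus] = 1.0
        out = self._settle(
            state,
            stim,
            self.params.minus_max_cycles,
            self.params.da_tonic,
            plus=False,
            tan_free=False,
            motor_stop=True,
            record_ng=True,
        )
        out["state"] = state
        return out

    def run_plus_phase(
        self, stimulus: int, choice: int, reward: int, tau_ba: float
    ) -> dict:
        """Feedback: DA burst/dip, TAN burst-pause(-rebound), M1 boost."""
        p = self.params
        state = self._fresh_state()
        stim = np.zeros(2)
        stim[stimulus] = 1.0
        da = p.da_burst if reward else p.da_dip
        if p.plus_cycles <= p.burst_cycles:
            raise ValueError("plus phase must be longer than the TAN burst")
        out = self._settle(
            state,
            stim,
            p.plus_cycles,
            da,
            plus=True,
            mc_clamp=choice,
            tan_free=p.tans_enabled,
            tau_ba=tau_ba,
            el_ng_boost=(p.m1_el_increment if (p.m1_enabled and p.tans_enabled) else 0.0),
            rebound=p.rebound_magnitude > 0,
            record_ng=True,
        )
        out["pause_ms"] = out["pause_cycles"] * p.cycle_ms
        out["da_level"] = da
        return out

    # -- plasticity -------------------------------------------------

    def update_weights(
        self,
        stimulus: int,
        minus_go: np.ndarray,
        minus_ng: np.ndarray,
        plus_go: np.ndarray,
        plus_ng: np.ndarray,
        ltp_scale: float = 1.0,
        ltd_scale: float = 1.0,
    ) -> None:
        """Hebbian + soft-bounded CHL update of the corticostriatal weights.

        Arguments are phase-averaged MSN rates (length 18); for the plus
        phase the average is taken over the ACh-gated plasticity window.
        ``ltp_scale`` is the pause window's share of the feedback phase
        (potentiation requires the TAN pause to lift M2-mediated
        presynaptic suppression, so its rate grows with pause duration);
        ``ltd_scale`` is the fixed depression rate.  The presented stimulus
        has pre-synaptic rate 1, the other 0 (the input layer is clamped
        one-hot in both phases).
        """
        p = self.params
        for arr in (minus_go, minus_ng, plus_go, plus_ng):
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("phase-averaged rates must lie in [0, 1]")
        x = np.zeros(2)
        x[stimulus] = 1.0
        for w, y_minus, y_plus in (
            (self.w_go, minus_go, plus_go),
            (self.w_ng, minus_ng, plus_ng),
        ):
            # (2 stimuli x 18 units) outer products
            hebb = y_plus[None, :] * (x[:, None] - w)
            chl = y_plus[None, :] * x[:, None] - y_minus[None, :] * x[:, None]
            sb = np.where(chl > 0, chl * (1.0 - w), chl * w)
            pos = p.kappa_hebb * np.maximum(hebb, 0.0) + (1.0 - p.kappa_hebb) * np.maximum(sb, 0.0)
            neg = p.kappa_hebb * np.minimum(hebb, 0.0) + (1.0 - p.kappa_hebb) * np.minimum(sb, 0.0)
            w += p.epsilon * (ltp_scale * pos + ltd_scale * neg)
            np.clip(w, 0.0, 1.0, out=w)
        self._refresh_plastic()

    # -- trial ------------------------------------------------------

    def commanded_tau(self, tan_mode: TanMode, go_trace: np.ndarray) -> tuple[float, float, float]:
        """(tau_ba, H, Hconj) for this trial's feedback phase."""
        p = self.params
        ent = population_entropy(go_trace, GO_ACTION_MAP)
        conj = and_conjunctions(go_trace, p.conj_theta, self.pairing)
        if tan_mode.mode == "fixed":
            tau = self.calibration.tau_for_pause(tan_mode.pause_ms)
        elif tan_mode.mode == "entropy":
            law = FeedbackLaw("entropy", p.entropy_x_lo, p.entropy_x_hi,
                              p.tau_ba_lo, p.tau_ba_hi)
            tau = feedback_tau(ent.H, law)
        elif tan_mode.mode == "conjunction":
            law = FeedbackLaw("conjunction", p.conj_x_lo, p.conj_x_hi,
                              p.tau_ba_lo, p.tau_ba_hi)
            tau = feedback_tau(conj.Hconj, law)
        else:  # "none": no TAN dynamics at all
            tau = 0.0
        return tau, ent.H, float(conj.Hconj)

    def run_trial(
        self,
        stimulus: int,
        schedule: Schedule,
        trial_index: int,
        tan_mode: TanMode,
        learn: bool = True,
    ) -> dict:
        """Minus phase -> read-out -> feedback -> plus phase -> weights."""
        p = self.params
        minus = self.run_minus_phase(stimulus)
        choice = minus["choice"]
        tau_ba, H, Hconj = self.commanded_tau(tan_mode, minus["go_trace"])
        reward = int(schedule.outcomes[trial_index, stimulus, choice])
        record: dict = {
            "trial": trial_index,
            "stimulus": stimulus,
            "action": choice,
            "reward": reward,
            "correct": int(choice == schedule.optimal_action(trial_index)),
            "phase": schedule.phase(trial_index),
            "epoch": trial_index // schedule.config.trials_per_epoch,
            "H": H,
            "Hconj": Hconj,
            "total_go": total_go_activity(minus["go_trace"]),
            "tau_ba": tau_ba,
            "minus_cycles": minus["cycles"],
            "probe": not learn,
        }
        if not learn:
            record.update(pause_ms=0.0, da_level=np.nan,
                          w_div=self.weight_divergence(stimulus))
            return record
        plus = self.run_plus_phase(stimulus, choice, reward, tau_ba)
        mask = plus["pause_mask"]
        if p.tans_enabled and mask.any():
            plus_go = plus["go_trace"][mask].mean(axis=0)
            plus_ng = plus["ng_trace"][mask].mean(axis=0)
            # pause duration acts through recruitment depth (the slow
            # feedback-phase conductances stagger unit activation), not
            # through the per-synapse step size
            ltp_scale = 1.0
            if reward and p.rebound_magnitude > 0 and mask.sum() + p.burst_cycles < p.plus_cycles:
                # post-pause burst: extra dopamine right after the window
                ltp_scale *= 1.0 + p.rebound_ltp_gain * p.rebound_magnitude
            ltd_scale = p.ltd_scale
        else:
            # tonic ACh: steady feedback state, residual plasticity
            post = slice(p.burst_cycles, None)
            plus_go = plus["go_trace"][post].mean(axis=0)
            plus_ng = plus["ng_trace"][post].mean(axis=0)
            ltp_scale = ltd_scale = p.control_plasticity_frac
        tail = max(1, min(p.minus_state_cycles, minus["go_trace"].shape[0]))
        self.update_weights(
            stimulus,
            minus["go_trace"][-tail:].mean(axis=0),
            minus["ng_trace"][-tail:].mean(axis=0),
            plus_go,
            plus_ng,
            ltp_scale=ltp_scale,
            ltd_scale=ltd_scale,
        )
        record.update(
            pause_ms=plus["pause_ms"],
            da_level=plus["da_level"],
            w_div=self.weight_divergence(stimulus),
        )
        return record

    def weight_divergence(self, stimulus: int) -> float:
        """Mean Go weight for the acquisition-optimal response (0) minus
        the mean for the alternative, for one stimulus."""
        w = self.w_go[stimulus]
        return float(w[GO_ACTION_MAP == 0].mean() - w[GO_ACTION_MAP == 1].mean())

    # -- manipulations ----------------------------------------------

    def ablate_m1(self) -> "BGNetwork":
        """Remove the M1-receptor leak-potential boost (feedback only)."""
        return self._with_params(replace(self.params, m1_enabled=False))

    def remove_tans(self) -> "BGNetwork":
        """Control network: TAN output clamped tonic at all times."""
        return self._with_params(replace(self.params, tans_enabled=False))

    def set_rebound(self, magnitude: float) -> "BGNetwork":
        """Scale the post-pause TAN overshoot and coupled DA drive."""
        if not (0.0 <= magnitude <= 1.0):
            raise ValueError("rebound magnitude must lie in [0, 1]")
        return self._with_params(replace(self.params, rebound_magnitude=magnitude))

    def _with_params(self, params: NetworkParams) -> "BGNetwork":
        clone = object.__new__(BGNetwork)
        clone.params = params
        clone.rng = self.rng
        clone.w_go = self.w_go
        clone.w_ng = self.w_ng
        clone.calibration = self.calibration
        clone.pairing = self.pairing
        clone._table_base = activation_table(
            params.gain, params.theta, params.act_noise_sigma
        )
        clone._table_ng = activation_table(
            params.gain, params.theta_ng, params.act_noise_sigma
        )
        clone._table_tan = activation_table(
            params.gain_tan, params.theta, params.act_noise_sigma
        )
        clone.tan_tonic = float(
            np.interp(params.E_l_tan, clone._table_tan[0], clone._table_tan[1])
        )
        clone._build_wiring()
        return clone


# ---------------------------------------------------------------- sessions


def run_network_session(
    config: TaskConfig,
    tan_mode: TanMode,
    params: NetworkParams | None = None,
    seed: int = 0,
    schedule: Schedule | None = None,
    probe_repetitions: int = 0,
    calibration: PauseCalibration | None = None,
) -> pd.DataFrame:
    """Train one network instantiation on one task; tidy per-trial records.

    Stimuli alternate deterministically (S1, S2, ...).  If
    ``probe_repetitions`` > 0, a probe block (learning off, no feedback)
    runs before training and after every epoch, tagged ``probe=True``.
    """
    if schedule is None:
        sched_cfg = TaskConfig(
            p_opt=config.p_opt, p_sub=config.p_sub, n_epochs=config.n_epochs,
            trials_per_epoch=config.trials_per_epoch,
            reversal_epoch=config.reversal_epoch, seed=config.seed + 1_000_003,
        )
        schedule = make_schedule(sched_cfg)
    net = BGNetwork(params, seed=seed, calibration=calibration)
    rows = []

    def probe(epoch: int) -> None:
        for rep in range(probe_repetitions):
            for stim in range(config.n_stimuli):
                t = min(epoch * config.trials_per_epoch, config.n_trials - 1)
                rec = net.run_trial(stim, schedule, t, tan_mode, learn=False)
                rec["epoch"] = epoch
                rows.append(rec)

    if probe_repetitions:
        probe(0)
    for trial in range(config.n_trials):
        for stim in range(config.n_stimuli):
            rows.append(net.run_trial(stim, schedule, trial, tan_mode))
        if probe_repetitions and (trial + 1) % config.trials_per_epoch == 0:
            probe((trial + 1) // config.trials_per_epoch)
    df = pd.DataFrame(rows)
    df.attrs["final_w_go"] = net.w_go.copy()
    df.attrs["final_w_ng"] = net.w_ng.copy()
    return df
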
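"""Numba-compiled inner loop of the network's cycle-by-cycle dynamics.

The loop is a direct transcription of the Euler updates described in
:mod:`striatan.network`; all stochastic draws are pre-generated by the
caller so the compiled path is bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# layer index constants mirrored from striatan.network (kept as plain
# ints for the compiled path)
N_UNITS = 49
IN0, IN1 = 0, 2
MC0, MC1 = 2, 4
GO0, GO1 = 4, 22
NG0, NG1 = 22, 40
INT0 = 40
TAN0 = 41
SNC0 = 42


@njit(cache=False)
def settle_loop(
    Ke, Ki, gl, el, vm, ge, gi, y,
    n_cycles,
    tau_g, tau_m, g_bar_e, g_bar_i,
    E_e, E_i,
    base_grid, base_vals, ng_grid, ng_vals,
    use_go_table, go_grid, go_vals,
    stim_hot_vm, stim_idx,
    snc_vm_base, snc_vm_rebound, snc_noise,
    mc_noise, mc_clamp, mc_clamp_vm,
    tan_free, tan_tonic, tan_burst_vm, burst_cycles,
    tan_grid, tan_vals,
    g_bar_l_tan, E_l_tan, g_bar_a, E_a,
    tau_ba, tau_ga, theta_a, theta_d,
    pause_thresh, pause_floor, rebound_rate,
    use_rebound_da,
    motor_stop, min_cycles, motor_threshold,
    go_trace, ng_trace, mc_trace, tan_rate, pause_mask,
):
    """Advance the network ``n_cycles`` (or until a motor unit crosses
    threshold).  Returns (used_cycles, paused_cycles, rebound_started)."""
    ga = 0.0
    ba = 0.0
    vm_tan = E_l_tan
    paused = 0
    pause_seen = False
    rebound_on = False
    snc_target = snc_vm_base
    used = n_cycles

    for c in range(n_cycles):
        e_drive = Ke @ y
        i_drive = Ki @ y
        for j in range(N_UNITS):
            ge[j] += tau_g * (e_drive[j] - ge[j])
            gi[j] += tau_g * (i_drive[j] - gi[j])
            inet = (
                ge[j] * g_bar_e * (E_e - vm[j])
                + gi[j] * g_bar_i * (E_i - vm[j])
                + gl[j] * (el[j] - vm[j])
            )
            vm[j] += tau_m * inet
        vm[MC0] += mc_noise[c, 0]
        vm[MC0 + 1] += mc_noise[c, 1]
        # clamped layers
        for j in range(IN0, IN1):
            vm[j] = el[j]
        vm[IN0 + stim_idx] = stim_hot_vm
        vm[SNC0] = snc_target + snc_noise[c]
        if mc_clamp >= 0:
            vm[MC0] = el[MC0]
            vm[MC0 + 1] = el[MC0 + 1]
            vm[MC0 + mc_clamp] = mc_clamp_vm

        for j in range(N_UNITS):
            y[j] = np.interp(vm[j], base_grid, base_vals)
        for j in range(NG0, NG1):
            y[j] = np.interp(vm[j], ng_grid, ng_vals)
        if use_go_table:
            for j in range(GO0, GO1):
                y[j] = np.interp(vm[j], go_grid, go_vals)

        # TAN: clamped tonic outside feedback; burst-pause-rebound inside
        if not tan_free:
            y[TAN0] = tan_tonic
            vm[TAN0] = E_l_tan
        elif rebound_on:
            y[TAN0] = rebound_rate
            vm[TAN0] = E_l_tan
            if use_rebound_da:
                snc_target = snc_vm_rebound
        else:
            if c < burst_cycles:
                vm_tan = tan_burst_vm
            else:
                inet_tan = g_bar_l_tan * (E_l_tan - vm_tan) + ga * g_bar_a * (
                    E_a - vm_tan
                )
                vm_tan = vm_tan + tau_m * inet_tan
            vm[TAN0] = vm_tan
            y_tan = np.interp(vm_tan, tan_grid, tan_vals)
            ba = ba + tau_ba * (y_tan - ba)
            if ba > theta_a:
                ga = ga + tau_ga * (1.0 - ga)
            elif ba < theta_d:
                ga = ga + tau_ga * (0.0 - ga)
            if c >= burst_cycles and y_tan < pause_thresh:
                paused += 1
                pause_seen = True
                pause_mask[c] = True
                if y_tan < pause_floor:
                    y_tan = pause_floor
            elif pause_seen:
                rebound_on = True
            y[TAN0] = y_tan

        for j in range(GO0, GO1):
            go_trace[c, j - GO0] = y[j]
        for j in range(NG0, NG1):
            ng_trace[c, j - NG0] = y[j]
        mc_trace[c, 0] = y[MC0]
        mc_trace[c, 1] = y[MC0 + 1]
        tan_rate[c] = y[TAN0]

        if motor_stop and c >= min_cycles:
            if y[MC0] > motor_threshold or y[MC0 + 1] > motor_threshold:
                used = c + 1
                break

    return used, paused, rebound_on
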
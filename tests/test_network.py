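"""Basal-ganglia network: pause calibration, phases, plasticity, gating."""

from dataclasses import replace

import numpy as np
import pytest

from striatan.network import (
    GO_ACTION_MAP,
    BGNetwork,
    NetworkParams,
    PauseCalibration,
    TanMode,
    run_network_session,
    simulate_tan_pause,
)
from striatan.task import TaskConfig, make_schedule


@pytest.fixture(scope="session")
def params() -> NetworkParams:
    return NetworkParams()


@pytest.fixture(scope="session")
def cal(params) -> PauseCalibration:
    return PauseCalibration(params)


class TestPauseCalibration:
    def test_map_is_monotone_and_spans_target_range(self, cal):
        """Realized pause is nondecreasing in tau_ba over the calibrated
        grid and covers the 120-280 ms span used in the simulations."""
        assert np.all(np.diff(cal.pauses) >= 0)
        lo, hi = cal.pause_range_ms
        assert lo <= 120.0 and hi >= 280.0

    @pytest.mark.parametrize("target", [120.0, 190.0, 280.0])
    def test_inversion_realizes_requested_pause(self, cal, target):
        tau = cal.tau_for_pause(target)
        assert abs(cal.pause_for_tau(tau) - target) <= 10.0

    def test_larger_tau_never_shortens_pause(self, params):
        taus = np.linspace(params.tau_ba_lo, params.tau_ba_hi, 15)
        pauses = [simulate_tan_pause(params, t) for t in taus]
        # raw map may jitter by one cycle at knife edges; calibration grid
        # is the monotone run, checked above -- here the raw trend
        assert pauses[-1] >= pauses[0] + 100.0 or max(pauses) >= 280.0


class TestPhases:
    def test_fixed_mode_pause_stable_across_trials(self, params, cal):
        """A fixed 190 ms command realizes 190 +- 10 ms on every trial."""
        net = BGNetwork(params, seed=3, calibration=cal)
        sched = make_schedule(TaskConfig(seed=9))
        tm = TanMode("fixed", 190.0)
        for t in range(5):
            rec = net.run_trial(0, sched, t, tm)
            assert abs(rec["pause_ms"] - 190.0) <= 10.0

    def test_rates_and_weights_stay_in_unit_interval(self, params, cal):
        net = BGNetwork(params, seed=4, calibration=cal)
        sched = make_schedule(TaskConfig(seed=10))
        tm = TanMode("fixed", 280.0)
        for t in range(8):
            for stim in range(2):
                net.run_trial(stim, sched, t, tm)
        assert np.all((net.w_go >= 0) & (net.w_go <= 1))
        assert np.all((net.w_ng >= 0) & (net.w_ng <= 1))
        out = net.run_minus_phase(0)
        assert np.all((out["go_trace"] >= 0) & (out["go_trace"] <= 1))

    def test_no_tans_means_no_pause(self, params, cal):
        net = BGNetwork(replace(params, tans_enabled=False), seed=5, calibration=cal)
        pl = net.run_plus_phase(0, 0, 1, cal.tau_for_pause(190.0))
        assert pl["pause_ms"] == 0.0
        assert np.all(np.abs(pl["tan_rate"] - net.tan_tonic) < 1e-9)

    def test_plus_phase_shorter_than_burst_rejected(self, params, cal):
        bad = replace(params, plus_cycles=4)
        net = BGNetwork(bad, seed=5, calibration=cal)
        with pytest.raises(ValueError):
            net.run_plus_phase(0, 0, 1, 0.01)

    def test_no_tan_plus_phase_go_never_exceeds_intact(self, params, cal):
        """Without the pause's disinhibition, feedback-phase Go activity
        stays at or below the TAN-intact network's (matched weights)."""
        tau = cal.tau_for_pause(280.0)
        net_a = BGNetwork(params, seed=6, calibration=cal)
        net_b = BGNetwork(replace(params, tans_enabled=False), seed=6, calibration=cal)
        net_b.w_go[:] = net_a.w_go
        net_b.w_ng[:] = net_a.w_ng
        net_b._refresh_plastic()
        pa = net_a.run_plus_phase(0, 0, 1, tau)
        pb = net_b.run_plus_phase(0, 0, 1, tau)
        sel = GO_ACTION_MAP == 0
        a = pa["go_trace"][pa["pause_mask"]][:, sel].mean()
        b = pb["go_trace"][8:][:, sel].mean()
        assert b <= a + 1e-6


class TestChoice:
    def test_go_weights_steer_the_choice(self, params, cal):
        """Strongly asymmetric Go weights pick their response in > 90%
        of stochastic runs."""
        hits = 0
        n = 12
        for s in range(n):
            net = BGNetwork(params, seed=900 + s, calibration=cal)
            net.w_go[:, GO_ACTION_MAP == 0] = 0.9
            net.w_go[:, GO_ACTION_MAP == 1] = 0.1
            net._refresh_plastic()
            hits += net.run_minus_phase(s % 2)["choice"] == 0
        assert hits >= int(0.9 * n)

    def test_nogo_weights_veto_the_choice(self, params, cal):
        hits = 0
        n = 12
        for s in range(n):
            net = BGNetwork(params, seed=700 + s, calibration=cal)
            net.w_ng[:, GO_ACTION_MAP == 1] = 0.85
            net.w_ng[:, GO_ACTION_MAP == 0] = 0.15
            net._refresh_plastic()
            hits += net.run_minus_phase(0)["choice"] == 0
        assert hits >= int(0.75 * n)

    def test_symmetric_weights_choose_both_actions(self, params, cal):
        choices = []
        for s in range(24):
            net = BGNetwork(params, seed=500 + s, calibration=cal)
            choices.append(net.run_minus_phase(s % 2)["choice"])
        frac = np.mean(choices)
        assert 0.2 <= frac <= 0.8  # binomial band around 0.5 at n=24

    def test_same_seed_reproduces_session(self, params, cal):
        cfg = TaskConfig(p_opt=0.8, p_sub=0.2, seed=2, n_epochs=2, reversal_epoch=1)
        a = run_network_session(cfg, TanMode("fixed", 190.0), params=params,
                                seed=7, calibration=cal)
        b = run_network_session(cfg, TanMode("fixed", 190.0), params=params,
                                seed=7, calibration=cal)
        assert a.drop(columns=[]).equals(b)


class TestPlasticity:
    def test_identical_phases_give_zero_chl(self, params, cal):
        net = BGNetwork(replace(params, kappa_hebb=0.0), seed=1, calibration=cal)
        w0 = net.w_go.copy()
        rates = np.full(18, 0.4)
        net.update_weights(0, rates, rates, rates, rates)
        assert np.allclose(net.w_go, w0)

    def test_soft_bound_freezes_saturated_weight(self, params, cal):
        net = BGNetwork(replace(params, kappa_hebb=0.0), seed=1, calibration=cal)
        net.w_go[:] = 1.0
        low = np.zeros(18)
        high = np.full(18, 0.9)
        net.update_weights(0, low, low, high, low)  # positive CHL at ceiling
        assert np.allclose(net.w_go, 1.0)

    def test_pure_hebbian_direct_substitution(self, params, cal):
        """kappa_hebb = 1, y+ = 0.5, x = 1(presented)/0, w = 0.2:
        dw = eps * 0.5 * (1 - 0.2) for the presented stimulus."""
        p = replace(params, kappa_hebb=1.0, epsilon=0.1)
        net = BGNetwork(p, seed=1, calibration=cal)
        net.w_go[:] = 0.2
        net.w_ng[:] = 0.2
        y_plus = np.full(18, 0.5)
        zeros = np.zeros(18)
        net.update_weights(0, zeros, zeros, y_plus, y_plus)
        assert np.allclose(net.w_go[0], 0.2 + 0.1 * 0.5 * 0.8)
        assert np.allclose(net.w_go[1], 0.2 - 0.1 * 0.5 * 0.2)  # x = 0 decay

    def test_out_of_range_rates_rejected(self, params, cal):
        net = BGNetwork(params, seed=1, calibration=cal)
        bad = np.full(18, 1.4)
        ok = np.full(18, 0.4)
        with pytest.raises(ValueError):
            net.update_weights(0, bad, ok, ok, ok)

    def test_probe_trials_leave_weights_untouched(self, params, cal):
        net = BGNetwork(params, seed=2, calibration=cal)
        sched = make_schedule(TaskConfig(seed=3))
        w0, n0 = net.w_go.copy(), net.w_ng.copy()
        rec = net.run_trial(0, sched, 0, TanMode("fixed", 190.0), learn=False)
        assert rec["probe"]
        assert np.array_equal(net.w_go, w0) and np.array_equal(net.w_ng, n0)


class TestManipulations:
    def test_ablate_m1_is_a_pure_feedback_toggle(self, params, cal):
        """M1 removal leaves action selection bit-identical (it only
        touches the NoGo leak potential during feedback)."""
        a = BGNetwork(params, seed=11, calibration=cal)
        b = a.ablate_m1()
        assert not b.params.m1_enabled
        net1 = BGNetwork(params, seed=11, calibration=cal)
        net2 = BGNetwork(replace(params, m1_enabled=False), seed=11, calibration=cal)
        m1 = net1.run_minus_phase(0)
        m2 = net2.run_minus_phase(0)
        assert np.array_equal(m1["go_trace"], m2["go_trace"])
        assert m1["choice"] == m2["choice"]

    def test_remove_tans_clamps_tonic(self, params, cal):
        net = BGNetwork(params, seed=12, calibration=cal).remove_tans()
        assert not net.params.tans_enabled

    def test_rebound_magnitude_validated(self, params, cal):
        net = BGNetwork(params, seed=13, calibration=cal)
        with pytest.raises(ValueError):
            net.set_rebound(1.5)
        assert net.set_rebound(0.5).params.rebound_magnitude == 0.5

    def test_zero_rebound_matches_baseline(self, params, cal):
        tau = cal.tau_for_pause(190.0)
        n0 = BGNetwork(replace(params, rebound_magnitude=0.0), seed=14, calibration=cal)
        nb = BGNetwork(params, seed=14, calibration=cal)
        p0 = n0.run_plus_phase(0, 0, 1, tau)
        pb = nb.run_plus_phase(0, 0, 1, tau)
        assert np.allclose(p0["tan_rate"], pb["tan_rate"])


def test_network_acquires_probabilistic_contingency(params, cal):
    """An 80:20 task is acquired well above chance within ten epochs."""
    cfg = TaskConfig(p_opt=0.8, p_sub=0.2, seed=12)
    df = run_network_session(cfg, TanMode("fixed", 190.0), params=params,
                            seed=13, calibration=cal)
    late_acq = df[(df.epoch >= 6) & (df.epoch < 10)]["correct"].mean()
    assert late_acq > 0.8


def test_entropy_feedback_commands_stay_in_bounds(params, cal):
    """Closed-loop pause commands remain inside the calibrated tau range
    on every trial."""
    cfg = TaskConfig(p_opt=0.85, p_sub=0.15, seed=4, n_epochs=4, reversal_epoch=2)
    df = run_network_session(cfg, TanMode("entropy"), params=params,
                            seed=5, calibration=cal)
    assert (df["tau_ba"] >= params.tau_ba_lo - 1e-12).all()
    assert (df["tau_ba"] <= params.tau_ba_hi + 1e-12).all()


def test_readout_statistics_across_training(params, cal):
    """Across a training run: population entropy falls with learning and
    rises again after the reversal; the AND-conjunction count tracks it
    (positive rank correlation, declines with training); total summed Go
    activity does NOT rise at the reversal, which is why it cannot serve
    as the uncertainty signal."""
    from scipy.stats import spearmanr

    cfg = TaskConfig(p_opt=0.8, p_sub=0.2, seed=3)
    df = run_network_session(cfg, TanMode("fixed", 180.0), params=params,
                            seed=103, calibration=cal)
    late = df[(df.trial >= 160) & (df.trial < 200)]
    post = df[(df.trial >= 200) & (df.trial < 320)]
    early = df[df.trial < 40]
    # entropy: declines over acquisition, rebounds after the reversal
    assert early["H"].mean() > late["H"].mean()
    assert post["H"].mean() > late["H"].mean()
    # conjunctions: decline with training, track entropy
    assert early["Hconj"].mean() > late["Hconj"].mean()
    assert spearmanr(df["H"], df["Hconj"]).statistic > 0.3
    # total activity: no reversal rebound
    assert post["total_go"].mean() <= late["total_go"].mean() * 1.1
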
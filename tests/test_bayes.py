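"""Beta-belief learner: decay algebra, policy integrals, annealing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striatan.bayes import (
    BayesLearner,
    BetaBelief,
    DecayParams,
    EntropyTracker,
    adapt_gamma,
    policy_entropy,
    policy_probabilities,
    run_bayes_session,
    select_action,
    update_belief,
    update_entropy_delta,
)
from striatan.task import TaskConfig


class TestBeliefUpdate:
    def test_no_decay_counts_observations(self):
        b = update_belief(BetaBelief(1, 1), reward=1, gamma=1.0)
        assert (b.alpha, b.beta) == (2.0, 1.0)

    def test_decay_after_update(self):
        b = update_belief(BetaBelief(4, 2), reward=0, gamma=0.5)
        assert (b.alpha, b.beta) == (2.0, 1.5)

    @given(
        st.floats(0.1, 50), st.floats(0.1, 50),
        st.floats(0.05, 0.999), st.integers(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_decay_preserves_mean_inflates_variance(self, a, b, g, r):
        """gamma scales both counts, so the post-update mean is invariant
        and the Beta variance strictly increases for gamma < 1."""
        post = BetaBelief(a + r, b + 1 - r)
        dec = update_belief(BetaBelief(a, b), r, g)
        assert dec.mean == pytest.approx(post.mean, rel=1e-12)

        def var(x: BetaBelief) -> float:
            n = x.alpha + x.beta
            return x.alpha * x.beta / (n * n * (n + 1))

        assert var(dec) > var(post)

    def test_non_binary_reward_rejected(self):
        with pytest.raises(ValueError):
            update_belief(BetaBelief(), reward=2, gamma=0.9)


class TestPolicyProbabilities:
    def test_symmetric_beliefs_give_half(self):
        p1, p2 = policy_probabilities(BetaBelief(1, 1), BetaBelief(1, 1))
        assert p1 == pytest.approx(0.5, abs=1e-8)
        assert p1 + p2 == pytest.approx(1.0)

    def test_extreme_beliefs_near_certainty(self):
        p1, _ = policy_probabilities(BetaBelief(100, 1), BetaBelief(1, 100))
        assert p1 > 0.999

    @pytest.mark.parametrize(
        "b1,b2", [((3.0, 5.0), (4.0, 2.0)), ((1.5, 1.0), (9.0, 3.0))]
    )
    def test_matches_monte_carlo_oracle(self, b1, b2):
        rng = np.random.default_rng(42)
        n = 1_000_000
        x = rng.beta(*b1, n)
        y = rng.beta(*b2, n)
        mc = (x > y).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        p1, _ = policy_probabilities(BetaBelief(*b1), BetaBelief(*b2))
        assert abs(p1 - mc) < 3 * se + 1e-6

    def test_thompson_frequency_matches_quadrature(self):
        b1, b2 = BetaBelief(6, 3), BetaBelief(2, 4)
        rng = np.random.default_rng(7)
        n = 100_000
        picks = np.array([select_action([b1, b2], rng) for _ in range(n)])
        freq1 = (picks == 0).mean()
        p1, _ = policy_probabilities(b1, b2)
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(freq1 - p1) < 3 * se


class TestPolicyEntropy:
    @pytest.mark.parametrize(
        "p,expected",
        [((0.5, 0.5), 1.0), ((1.0, 0.0), 0.0), ((0.8, 0.2), 0.7219280948873623)],
    )
    def test_known_values(self, p, expected):
        assert policy_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            policy_entropy((0.7, 0.6))


class TestEntropyTracker:
    def test_stationary_entropy_decays_tracker_geometrically(self):
        params = DecayParams(mode="adaptive", eta=0.3)
        t = EntropyTracker()
        for _ in range(3):
            t = update_entropy_delta(t, 0.9, params)
        # after the first step raw differences are 0, so dH shrinks by (1-eta)
        assert t.deltaH == pytest.approx(1.0 * 0.7**3)

    def test_eta_one_tracks_raw_difference(self):
        params = DecayParams(mode="adaptive", eta=1.0)
        t = EntropyTracker(deltaH=0.5, last_H=0.4)
        t = update_entropy_delta(t, 0.9, params)
        assert t.deltaH == pytest.approx(0.5)  # raw diff = 0.9 - 0.4

    def test_matches_recursive_oracle(self):
        params = DecayParams(mode="adaptive", eta=0.1)
        rng = np.random.default_rng(3)
        hs = rng.random(50)
        t = EntropyTracker()
        dh, last = 1.0, None
        for h in hs:
            t = update_entropy_delta(t, h, params)
            raw = h - (last if last is not None else h)
            dh = dh + 0.1 * ((raw - dh))
            last = h
            assert t.deltaH == pytest.approx(dh, abs=1e-12)


class TestAdaptiveGamma:
    def test_slope_zero_is_constant(self):
        p = DecayParams(mode="adaptive", gamma0=1.2, gamma1=0.0)
        g1 = adapt_gamma(p, EntropyTracker(deltaH=0.0))
        g2 = adapt_gamma(p, EntropyTracker(deltaH=5.0))
        assert g1 == g2 == pytest.approx(1 / (1 + np.exp(-1.2)))

    def test_zero_intercept_zero_delta_gives_half(self):
        p = DecayParams(mode="adaptive", gamma0=0.0, gamma1=-1.0)
        assert adapt_gamma(p, EntropyTracker(deltaH=0.0)) == pytest.approx(0.5)

    def test_strictly_decreasing_in_delta_h(self):
        p = DecayParams(mode="adaptive", gamma0=2.0, gamma1=-3.0)
        gs = [adapt_gamma(p, EntropyTracker(deltaH=d)) for d in (-1, 0, 0.5, 1)]
        assert all(a > b for a, b in zip(gs, gs[1:]))

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError):
            DecayParams(mode="adaptive", gamma1=0.5)


class TestConsistency:
    def test_symmetric_start_chooses_half(self):
        rng = np.random.default_rng(0)
        picks = [
            select_action([BetaBelief(), BetaBelief()], rng) for _ in range(4000)
        ]
        assert np.mean(picks) == pytest.approx(0.5, abs=0.03)

    def test_posterior_concentrates_without_decay(self):
        """With gamma = 1 on a stationary 80:20 arm, the optimal-choice
        probability approaches 1."""
        cfg = TaskConfig(p_opt=0.8, p_sub=0.2, n_epochs=50, reversal_epoch=50, seed=2)
        df = run_bayes_session(cfg, DecayParams(mode="fixed", gamma=1.0), seed=3)
        late = df[df["trial"] >= 800]["correct"].mean()
        assert late > 0.95
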
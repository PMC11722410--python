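"""Analytical companion: absorption probabilities, thresholds, fixation."""

import numpy as np
import pytest
from _oracles import birth_death_fixation, psi_linear_system

from mlscoop import analytics as an
from mlscoop._core import mc_reach_threshold


class TestPsi:
    def test_t_up_values(self):
        assert an.t_up(0, 10) == 0.0
        assert an.t_up(10, 10) == 0.0
        assert an.t_up(5, 10) == pytest.approx(0.25)
        assert an.t_up(3, 10) == pytest.approx(0.21)

    def test_certain_survival_reaches_threshold(self):
        for K in (2, 5, 17, 50):
            ctx = an.SurvivalContext(1.0, K)
            assert all(an.psi(n, ctx) == pytest.approx(1.0) for n in range(1, K + 1))

    def test_two_site_closed_form(self):
        # single factor: 0.8*0.25 / (0.2 + 0.8*0.25) = 0.5
        assert an.psi(1, an.SurvivalContext(0.8, 2)) == pytest.approx(0.5)

    def test_matches_linear_system_oracle(self):
        """Master oracle: product solution equals the direct solve of the
        defining recursion, over a (K, delta, b) grid."""
        for K in range(2, 13):
            for delta in (0.5, 0.9, 0.99):
                for b in (1.0, 2.0, 4.0):
                    ctx = an.SurvivalContext(delta, K, b)
                    oracle = psi_linear_system(K, delta, b)
                    got = np.array([an.psi(n, ctx) for n in range(1, K + 1)])
                    assert np.max(np.abs(got - oracle)) < 1e-10

    def test_matches_monte_carlo_absorption(self):
        """psi equals the Monte-Carlo absorption frequency of a simulated
        single group with per-step survival delta, across the (K, delta, b)
        grid (one fixed seed per combo, indexed a priori)."""
        reps = 100_000
        i = 0
        for K in (3, 6, 12):
            for delta in (0.5, 0.9, 0.99):
                for b in (1.0, 2.0, 4.0):
                    i += 1
                    n0 = max(1, K // 2)
                    expected = an.psi(n0, an.SurvivalContext(delta, K, b))
                    freq = mc_reach_threshold(n0, K, b, delta, reps, 1000 + i)
                    se = np.sqrt(expected * (1 - expected) / reps)
                    assert abs(freq - expected) < 3 * se + 1e-9

    def test_psi_avg_small_case_by_hand(self):
        # K=3, delta=0.9: psi_2 = 2/3, psi_1 = 4/9, mean = 5/9
        assert an.psi_avg(an.SurvivalContext(0.9, 3)) == pytest.approx(5 / 9)

    def test_psi_avg_monotonicities(self):
        deltas = [0.9, 0.95, 0.99, 0.999]
        vals = [an.psi_avg(an.SurvivalContext(d, 10)) for d in deltas]
        assert np.all(np.diff(vals) > 0)
        Ks = [5, 10, 20, 40]
        vals = [an.psi_avg(an.SurvivalContext(0.99, K)) for K in Ks]
        assert np.all(np.diff(vals) < 0)


class TestHighDeltaLimit:
    def test_expansion_value(self):
        # K=10, delta=0.999, b=1: 1 - 0.001 * H9 * 100/9
        H9 = an.harmonic(9)
        assert an.psi_avg_high_delta(
            an.SurvivalContext(0.999, 10)
        ) == pytest.approx(1 - 0.001 * H9 * 100 / 9)

    @pytest.mark.parametrize("K", [5, 10, 20])
    @pytest.mark.parametrize("b", [1.0, 2.0, 4.0])
    def test_agrees_with_exact_average_near_one(self, K, b):
        eps = 1e-3 * (K - 1) / (K**2 * an.harmonic(K - 1))
        ctx = an.SurvivalContext(1.0 - eps, K, b)
        exact = an.psi_avg(ctx)
        approx = an.psi_avg_high_delta(ctx)
        assert abs(approx - exact) / exact < 0.01

    @pytest.mark.parametrize("K", [3, 5, 10, 20])
    def test_is_true_first_order_expansion(self, K):
        """(1 - <psi>)/(1 - delta) converges to H_{K-1} K^2 / (b(K-1))."""
        b = 2.0
        target = an.harmonic(K - 1) * K**2 / (b * (K - 1))
        ratios = [
            (1 - an.psi_avg(an.SurvivalContext(1 - eps, K, b))) / eps
            for eps in (1e-4, 1e-5, 1e-6)
        ]
        errs = np.abs(np.array(ratios) - target) / target
        assert np.all(np.diff(errs) < 0)
        assert errs[-1] < 1e-3


class TestThresholds:
    def test_delta_star_values(self):
        assert an.delta_star(10) == pytest.approx(0.984093, abs=1e-6)
        assert an.delta_star(2) == pytest.approx(0.875)
        assert an.delta_star(10, 4.0) < an.delta_star(10, 1.0)

    def test_delta_star_is_a_conservative_bound(self):
        """The linearised threshold delta* sits above the exact psi = 1/2
        root: the exact average is still > 1/2 at delta*, and inverting the
        linear expansion at delta* returns exactly 1/2 (self-consistency)."""
        for K, b in [(5, 1.0), (10, 1.0), (10, 4.0), (20, 2.0)]:
            d = an.delta_star(K, b)
            assert an.psi_avg(an.SurvivalContext(d, K, b)) > 0.5
            assert an.psi_avg_high_delta(
                an.SurvivalContext(d, K, b)
            ) == pytest.approx(0.5, abs=1e-12)

    def test_neutral_threshold_solutions(self):
        assert an.neutral_threshold(10, 1.0, Ng=50) == pytest.approx(0.79535, abs=1e-4)
        mu4 = an.neutral_threshold(20, 4.0, mu=0.7)
        mu1 = an.neutral_threshold(20, 1.0, mu=0.7)
        assert mu1 / mu4 == pytest.approx(4.0)  # Ng* scales as 1/b
        ng_stars = [an.neutral_threshold(K, 1.0, mu=0.7) for K in (10, 20, 40)]
        assert np.all(np.diff(ng_stars) > 0)

    def test_numeric_threshold_self_consistency(self):
        mu = an.solve_threshold_numeric(10, 50)
        assert an.psi_avg(
            an.SurvivalContext(1 - mu / 50, 10)
        ) == pytest.approx(0.5, abs=1e-7)
        mus = [an.solve_threshold_numeric(K, 50) for K in (5, 10, 20)]
        assert np.all(np.diff(mus) < 0)

    def test_closed_form_lower_bounds_the_numeric_threshold(self):
        """The linearised proliferation threshold in mu is a lower bound on
        the exact root: the two curves bracket the transition."""
        for K in (5, 10, 20):
            numeric = an.solve_threshold_numeric(K, 50)
            closed = 50 * (K - 1) / (2 * an.harmonic(K - 1) * K**2)
            assert closed < numeric < 2.0 * closed


class TestSurvivalProbs:
    def test_relative_hand_values(self):
        dA, dB = an.survival_probs("relative", 20, 10, 0.7, 0.4)
        assert (dA, dB) == pytest.approx((0.97375, 0.95625))

    def test_absolute_hand_values(self):
        dA, dB = an.survival_probs("absolute", 20, 10, 0.7, 0.4)
        assert (dA, dB) == pytest.approx((1 - 0.7 * 0.6 / 20, 1 - 0.7 / 20))

    def test_neutral_reduction_at_zero_trait(self):
        for mode in ("relative", "absolute"):
            dA, dB = an.survival_probs(mode, 20, 10, 0.7, 0.0)
            assert dA == dB == pytest.approx(1 - 0.7 / 20)

    def test_relative_mode_conserves_total_death(self):
        for NgA in range(0, 21, 5):
            for a in (0.0, 0.3, 0.9):
                dA, dB = an.survival_probs("relative", 20, NgA, 0.7, a)
                total = NgA * (1 - dA) + (20 - NgA) * (1 - dB)
                assert total == pytest.approx(0.7, abs=1e-12)

    def test_monotonicities(self):
        """More cooperator groups hurt everyone's survival in the relative
        mode; a stronger trait helps cooperators and hurts cheaters."""
        dAs, dBs = zip(*[
            an.survival_probs("relative", 20, NgA, 0.7, 0.5)
            for NgA in range(0, 21, 4)
        ])
        assert np.all(np.diff(dAs) < 0) and np.all(np.diff(dBs) < 0)
        dAs, dBs = zip(*[
            an.survival_probs("relative", 20, 10, 0.7, a)
            for a in np.linspace(0, 1, 6)
        ])
        assert np.all(np.diff(dAs) > 0) and np.all(np.diff(dBs) < 0)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            an.survival_probs("relative", 1, 1, 0.9, 1.0)  # Ng - a NgA = 0


class TestCompetitionThresholds:
    def test_relative_hand_values(self):
        th = an.competition_thresholds("relative", 0.7, 10, 20, 10)
        assert th.a_star == pytest.approx(0.70594, abs=1e-4)
        assert th.b_star == pytest.approx(3.4007, abs=1e-3)
        assert th.a_in_regime and th.b_in_regime

    def test_absolute_hand_values(self):
        th = an.competition_thresholds("absolute", 0.7, 10, 20)
        assert th.a_star == pytest.approx(0.54552, abs=1e-4)
        assert th.b_star == pytest.approx(2.2003, abs=1e-3)

    def test_algebraic_round_trip(self):
        """Survival probability at a* (b=1) plugged back into the high-delta
        expansion lands exactly on 1/2."""
        th = an.competition_thresholds("relative", 0.7, 10, 20, 10)
        dA, _ = an.survival_probs("relative", 20, 10, 0.7, th.a_star)
        assert an.psi_avg_high_delta(
            an.SurvivalContext(dA, 10, 1.0)
        ) == pytest.approx(0.5, abs=1e-9)

    def test_out_of_regime_flagged(self):
        th = an.competition_thresholds("absolute", 0.1, 10, 50)
        assert not th.a_in_regime  # weak death pressure: a* < 0

    def test_numeric_roots_are_bounded_by_closed_forms(self):
        """At the competition-heatmap parameters the exact psi = 1/2 roots
        exist, lie in their admissible ranges, and sit below the linearised
        thresholds (which are conservative bounds)."""
        mu, K, Ng, NgA = 0.7, 10, 20, 10
        th = an.competition_thresholds("relative", mu, K, Ng, NgA)
        a_num = an.psi_half_a("relative", mu, K, Ng, NgA)
        assert 0.0 < a_num < th.a_star
        b_num = an.psi_half_b("relative", mu, K, Ng, NgA, a_num)
        b_closed = an.b_star_of_a("relative", mu, K, Ng, NgA, a_num)
        assert 1.0 < b_num < b_closed


class TestPsiHalfCurves:
    def test_cooperator_curve_independent_of_b(self):
        curves = an.psi_half_curves("relative", 0.7, 10, 20, 10,
                                    np.array([1.0, 2.0, 4.0]))
        assert np.allclose(curves.a_A, curves.a_A[0], atol=1e-12)

    def test_cooperator_ng_threshold_exceeds_cheater_threshold(self):
        """Over the (K, Ng) plane at a=0.4, b=4: the minimum Ng admitting
        cooperator proliferation is larger than the cheater one, and both
        grow with K."""
        ngA_prev = ngB_prev = 0.0
        for K in (10, 15, 20, 25, 30):
            ngA = an.psi_half_ng("relative", 0.7, K, 1.0, "A", 0.4)
            ngB = an.psi_half_ng("relative", 0.7, K, 4.0, "B", 0.4)
            assert ngA > ngB
            assert ngA > ngA_prev and ngB > ngB_prev
            ngA_prev, ngB_prev = ngA, ngB


class TestMoranLimit:
    def test_transition_hand_values(self):
        td, tu = an.moran_limit_transitions("relative", 1, 2, 0.1, 0.5)
        assert (td, tu) == pytest.approx((1 / 60, 1 / 30))

    @pytest.mark.parametrize("mode", ["relative", "absolute"])
    def test_ratio_is_one_minus_a(self, mode):
        for a in (0.0, 0.25, 0.6, 0.9):
            for NgA in (1, 7, 19):
                td, tu = an.moran_limit_transitions(mode, NgA, 20, 0.3, a)
                assert td / tu == pytest.approx(1 - a, abs=1e-12)

    @pytest.mark.parametrize("mode", ["relative", "absolute"])
    def test_fixation_matches_chain_oracle(self, mode):
        """Closed-form fixation equals the absorbing-chain solve of the
        transition probabilities, for both modes and independent of mu."""
        Kg, a = 12, 0.35
        for mu in (0.01, 0.5):
            interior = np.array([
                an.moran_limit_transitions(mode, i, Kg, mu, a)
                for i in range(1, Kg)
            ])
            phi = birth_death_fixation(Kg, interior[:, 0], interior[:, 1])
            for i in range(Kg + 1):
                assert an.fixation_probability(i, Kg, a) == pytest.approx(
                    phi[i], abs=1e-10
                )

    def test_neutral_and_boundary_values(self):
        assert an.fixation_probability(3, 10, 0.0) == pytest.approx(0.3)
        assert an.fixation_probability(0, 10, 0.5) == 0.0
        assert an.fixation_probability(10, 10, 0.5) == 1.0
        assert an.fixation_probability(1, 3, 0.5) == pytest.approx(0.571429, abs=1e-6)

    def test_fixation_increases_with_trait_strength(self):
        vals = [an.fixation_probability(5, 30, a) for a in np.linspace(0, 0.9, 8)]
        assert np.all(np.diff(vals) > 0)
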
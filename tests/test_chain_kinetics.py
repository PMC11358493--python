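"""Parent/daughter activity relations, frame coincidence, decay correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alphadose3d import (
    AC225_CHAIN,
    DecayChain,
    Nuclide,
    RatioSeries,
    decay_correct,
    fit_initial_ratio,
    frame_coincidence_factor,
    free_daughter_excess,
    initial_daughter_activity,
    ratio_at_time,
    simulate_frame_coincidence,
)
from alphadose3d.chain_kinetics import parse_duration
from alphadose3d.phantoms import simulate_ratio_series

from conftest import bateman_ratio_ode


class TestChainConstants:
    def test_alpha_yields_sum_to_four(self, chain):
        assert chain.alphas_per_chain == pytest.approx(4.0, abs=0.05)

    def test_parent_is_longest_lived(self, chain):
        assert chain.parent.name == "Ac-225"
        assert all(n.half_life <= chain.parent.half_life for n in chain.nuclides)

    def test_equilibrium_ratio_slightly_above_one(self, chain):
        # lam_b/(lam_b - lam_a) for Ac-225/Bi-213 is ~1.003
        assert 1.0 < chain.equilibrium_ratio < 1.01

    def test_invalid_chain_rejected(self):
        with pytest.raises(ValueError, match="longest"):
            DecayChain(
                (
                    Nuclide("short", 1.0, alpha_yield=1.0),
                    Nuclide("long", 10.0, alpha_yield=1.0),
                ),
                yield_tolerance=0.5,
            )

    def test_duration_parsing_requires_units(self):
        assert parse_duration("9.9 d") == pytest.approx(9.9 * 86400)
        assert parse_duration("32 ms") == pytest.approx(0.032)
        with pytest.raises(ValueError):
            parse_duration("9.9 fortnights")


class TestRatioAtTime:
    def test_identity_at_t_zero(self, chain):
        assert ratio_at_time(5.0, 0.0, chain) == pytest.approx(5.0)

    def test_equilibrium_ratio_is_fixed_point(self, chain):
        k = chain.equilibrium_ratio
        for t in (0.0, 600.0, 3600.0, 86400.0):
            assert ratio_at_time(k, t, chain) == pytest.approx(k, rel=1e-12)

    def test_matches_bateman_ode(self, chain):
        r = ratio_at_time(14.7, 3600.0, chain)
        oracle = bateman_ratio_ode(14.7, 3600.0, chain.lam_parent, chain.lam_daughter)
        assert r == pytest.approx(oracle, rel=1e-6)

    def test_asymptote_at_long_times(self, chain):
        # the transient decays as (r0 - k) e^{-(lam_b - lam_a) t}
        for r0 in (0.0, 1.0, 14.7, 100.0):
            t20 = 20 * chain.daughter.half_life
            residual = abs(r0 - chain.equilibrium_ratio) * math.exp(
                -(chain.lam_daughter - chain.lam_parent) * t20
            )
            assert ratio_at_time(r0, t20, chain) == pytest.approx(
                chain.equilibrium_ratio, abs=max(residual * 1.001, 1e-12)
            )
            # and is below 1e-6 by 30 daughter half-lives
            t30 = 30 * chain.daughter.half_life
            assert ratio_at_time(r0, t30, chain) == pytest.approx(
                chain.equilibrium_ratio, abs=1e-6
            )

    def test_rejects_negative_time_and_equal_decay_constants(self, chain):
        with pytest.raises(ValueError):
            ratio_at_time(1.0, -1.0, chain)
        degenerate = DecayChain(
            (
                Nuclide("p", 100.0, alpha_yield=1.0),
                Nuclide("d", 100.0, alpha_yield=1.0),
            ),
            monitored_daughter="d",
            yield_tolerance=0.5,
        )
        with pytest.raises(ValueError, match="daughter decay constant"):
            ratio_at_time(1.0, 1.0, degenerate)


class TestInitialDaughterActivity:
    def test_zero_elapsed_returns_measured(self, chain):
        assert initial_daughter_activity(7.0, 3.0, 0.0, chain) == pytest.approx(7.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        r0=st.floats(0.1, 30.0),
        aa0=st.floats(0.5, 100.0),
        hours=st.floats(0.01, 5.0),
    )
    def test_forward_inverse_round_trip(self, r0, aa0, hours):
        chain = AC225_CHAIN
        t = hours * 3600.0
        ab0 = r0 * aa0
        aa_t = aa0 * math.exp(-chain.lam_parent * t)
        ab_t = ratio_at_time(r0, t, chain) * aa_t
        back = initial_daughter_activity(ab_t, aa_t, t, chain)
        assert back == pytest.approx(ab0, rel=1e-10)

    def test_matches_bateman_ode(self, chain):
        rng = np.random.default_rng(42)
        la, lb = chain.lam_parent, chain.lam_daughter
        for _ in range(100):
            aa0 = rng.uniform(1.0, 50.0)
            r0 = rng.uniform(0.1, 20.0)
            t = rng.uniform(60.0, 4 * 3600.0)
            aa_t = aa0 * math.exp(-la * t)
            ab_t = bateman_ratio_ode(r0, t, la, lb) * aa_t
            back = initial_daughter_activity(ab_t, aa_t, t, chain)
            assert back == pytest.approx(r0 * aa0, rel=1e-6)


class TestFitInitialRatio:
    def test_noiseless_series_recovered_exactly(self, chain):
        times = np.array([1800.0, 3600.0, 5400.0, 7200.0])
        series = RatioSeries(times, ratio_at_time(14.7, times, chain))
        r0, r2 = fit_initial_ratio(series, chain)
        assert r0 == pytest.approx(14.7, abs=1e-8)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_equilibrium_series(self, chain):
        k = chain.equilibrium_ratio
        series = RatioSeries(np.array([600.0, 1200.0, 1800.0]), np.full(3, k))
        r0, _ = fit_initial_ratio(series, chain)
        assert r0 == pytest.approx(k, rel=1e-9)

    def test_mean_recovery_under_noise(self, chain):
        times = np.array([1800.0, 3600.0, 5400.0, 7200.0])
        estimates = []
        for rep in range(200):
            series = simulate_ratio_series(14.7, times, 0.01, chain, rng=rep)
            estimates.append(fit_initial_ratio(series, chain)[0])
        assert np.mean(estimates) == pytest.approx(14.7, rel=0.02)

    def test_degenerate_series_rejected(self, chain):
        with pytest.raises(ValueError):
            RatioSeries(np.array([100.0, 100.0]), np.array([2.0, 2.0]))


class TestFreeDaughterExcess:
    @pytest.mark.parametrize(
        "ab0,aa0,expected,status",
        [
            (10.0, 10.0, 0.0, "equilibrium"),
            (147.0, 10.0, 137.0, "excess"),
            (6.2, 10.0, 0.0, "deficit"),
            (10.3, 10.0, 0.0, "equilibrium"),  # 1.03 within default 5% tolerance
        ],
    )
    def test_cases(self, ab0, aa0, expected, status):
        excess, flag = free_daughter_excess(ab0, aa0)
        assert excess == pytest.approx(expected)
        assert flag == status


class TestFrameCoincidence:
    def test_reproduces_device_factor(self):
        # 40 ms frames, 32 ms daughter half-life, 4 alphas per chain
        assert frame_coincidence_factor(0.040, 0.032, 4) == pytest.approx(1.09, abs=0.005)

    def test_no_coincidence_for_fast_frames(self):
        assert frame_coincidence_factor(1e-6, 0.032, 4) == pytest.approx(1.0, abs=1e-4)

    def test_instant_daughter_limit(self):
        # t1/2 -> 0: every daughter lands in the parent's frame, P -> 1
        assert frame_coincidence_factor(0.040, 1e-9, 4) == pytest.approx(4.0 / 3.0, rel=1e-6)

    def test_monte_carlo_agrees_with_analytic(self):
        lam = math.log(2) / 0.032
        x = lam * 0.040
        p_analytic = 1.0 - (1.0 - math.exp(-x)) / x
        p_hat, sigma = simulate_frame_coincidence(0.040, 0.032, 10**6, rng=123)
        assert abs(p_hat - p_analytic) < 3 * sigma

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        t_frame=st.floats(1e-3, 1.0),
        t_half=st.floats(1e-3, 1.0),
    )
    def test_factor_at_least_one_and_monotone(self, t_frame, t_half):
        f = frame_coincidence_factor(t_frame, t_half, 4)
        assert f >= 1.0
        assert frame_coincidence_factor(t_frame * 1.5, t_half, 4) >= f
        # faster daughter decay (shorter half-life) raises the factor
        assert frame_coincidence_factor(t_frame, t_half / 1.5, 4) >= f


class TestDecayCorrect:
    def test_half_life_doubles(self, chain):
        assert decay_correct(1.0, chain.parent.half_life, chain.parent.half_life) == (
            pytest.approx(2.0, rel=1e-12)
        )
        lam = chain.parent.lam
        t = 9.9 * 86400.0
        assert decay_correct(3.0, t, chain.parent.half_life) == pytest.approx(
            3.0 * math.exp(lam * t), rel=1e-12
        )

    def test_zero_and_negative_elapsed(self):
        assert decay_correct(5.0, 0.0, 100.0) == 5.0
        assert decay_correct(5.0, -100.0, 100.0) == pytest.approx(2.5)
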
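"""Exponential kinetics: rates, doubling times, virtual growth, aggregation."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from dtec import (
    DegenerateKineticsError,
    Trajectory,
    VirtualStrategy,
    VolumePhase,
    doubling_time,
    effective_kinetics,
    half_life,
    rate_constant,
    t_d_intraday,
    virtualize,
)
from dtec.units import SECONDS_PER_DAY as D

LN2 = math.log(2)


def phase(v0, v1, duration):
    return VolumePhase(v_start=v0, v_end=v1, duration=duration)


class TestRateAndDoublingTime:
    def test_growth_rate_matches_hand_value(self):
        # 0.1 -> 1.2 cm^3 over 3.5 weeks
        assert rate_constant(phase(0.1, 1.2, 2_116_800)) == pytest.approx(
            1.1738976992573698e-06, rel=1e-12
        )

    def test_doubling_definition(self):
        p = phase(0.2, 0.4, 86_400)
        assert rate_constant(p) == pytest.approx(LN2 / 86_400, rel=1e-12)
        assert doubling_time(p) == pytest.approx(86_400, rel=1e-12)

    def test_shrink_phase_rate_and_half_life(self):
        # 0.15 -> 0.09 cm^3 over 6 days
        p = phase(0.15, 0.09, 6 * D)
        assert rate_constant(p) < 0
        assert half_life(p) == pytest.approx(703424.9686873256, rel=1e-12)

    def test_exact_doubling_over_window(self):
        # 0.1 -> 0.2 over 24.5 days: doubling time equals the window
        assert doubling_time(phase(0.1, 0.2, 24.5 * D)) == pytest.approx(24.5 * D)

    def test_static_phase_rejected(self):
        with pytest.raises(DegenerateKineticsError):
            rate_constant(phase(1.0, 1.0, D))

    def test_doubling_time_refuses_shrinking_phase(self):
        with pytest.raises(DegenerateKineticsError, match="virtualize"):
            doubling_time(phase(0.15, 0.09, 6 * D))


class TestVirtualize:
    def test_half_life_equivalence_end_volume(self):
        # 0.4 -> 0.02 cm^3: virtual end volume = 0.4^2/0.02 = 8.0
        v = virtualize(phase(0.4, 0.02, 85 * D))
        assert v.v_end == pytest.approx(8.0, rel=1e-12)
        assert doubling_time(v) == pytest.approx(19.66714811857953 * D, rel=1e-12)

    def test_reflection_end_volume(self):
        v = virtualize(phase(0.4, 0.02, 85 * D), VirtualStrategy.REFLECTION)
        assert v.v_end == pytest.approx(0.78, rel=1e-12)

    def test_literal_end_volume(self):
        v = virtualize(phase(0.4, 0.02, 85 * D), VirtualStrategy.LITERAL)
        assert v.v_end == pytest.approx(0.4 + 0.16 / 0.38, rel=1e-12)

    def test_growing_phase_returned_unchanged(self):
        p = phase(0.1, 0.2, D)
        assert virtualize(p) == p

    @pytest.mark.parametrize(
        "strategy",
        [VirtualStrategy.HALF_LIFE_EQUIVALENCE, VirtualStrategy.REFLECTION],
    )
    def test_vanishing_shrinkage_limit(self, strategy):
        # v_end -> v_start: virtual end volume -> v_start, doubling time -> inf
        p = phase(1.0, 1.0 - 1e-9, D)
        v = virtualize(p, strategy)
        assert v.v_end == pytest.approx(1.0, abs=1e-6)
        assert doubling_time(v) > 1e8 * D

    def test_vanishing_shrinkage_diverges_under_literal_reading(self):
        # the face-value reading instead sends the virtual end volume (and
        # the virtual rate) to infinity as the shrinkage vanishes
        v = virtualize(phase(1.0, 1.0 - 1e-9, D), VirtualStrategy.LITERAL)
        assert v.v_end > 1e8
        assert doubling_time(v) < D

    @settings(derandomize=True, max_examples=200)
    @given(
        v0=st.floats(0.01, 10.0),
        frac=st.floats(0.01, 0.99),
        dur=st.floats(3600.0, 100 * D),
    )
    def test_virtual_doubling_time_equals_half_life(self, v0, frac, dur):
        """Default strategy: virtual t_d == observed t_1/2 to 1e-12 relative."""
        p = phase(v0, v0 * frac, dur)
        v = virtualize(p)
        assert math.isclose(doubling_time(v), half_life(p), rel_tol=1e-12)
        assert math.isclose(
            rate_constant(v), abs(rate_constant(p)), rel_tol=1e-12
        )


class TestEffectiveKinetics:
    def test_single_growing_phase_matches_doubling_time(self):
        p = phase(0.1, 1.2, 2_116_800)
        traj = Trajectory(phases=(p,))
        kin = effective_kinetics(traj)
        assert kin.t_d == pytest.approx(doubling_time(p), rel=1e-12)
        assert not kin.virtual

    def test_shrink_then_grow_arm(self):
        # shrink 0.15->0.09 in 6 d then grow 0.09->0.17 in 8 d:
        # virtual rate = [ln(0.25/0.15) + ln(0.17/0.09)] / 14 d
        traj = Trajectory(phases=(phase(0.15, 0.09, 6 * D), phase(0.09, 0.17, 8 * D)))
        kin = effective_kinetics(traj)
        assert kin.virtual
        assert kin.rate * D == pytest.approx(0.08191531360614197, rel=1e-12)
        assert kin.t_d / D == pytest.approx(8.46175336509941, rel=1e-12)

    def test_two_identical_phases_same_rate_as_one(self):
        p1, p2 = phase(0.1, 0.2, D), phase(0.2, 0.4, D)
        one = effective_kinetics(Trajectory(phases=(p1,)))
        both = effective_kinetics(Trajectory(phases=(p1, p2)))
        assert both.rate == pytest.approx(one.rate, rel=1e-12)

    def test_all_static_trajectory_degenerate(self):
        with pytest.raises(DegenerateKineticsError):
            effective_kinetics(Trajectory(phases=(phase(1.0, 1.0, D),)))

    @settings(derandomize=True, max_examples=100)
    @given(
        rate_per_day=st.floats(0.01, 0.5),
        v0=st.floats(0.01, 1.0),
        n_samples=st.integers(2, 12),
    )
    def test_recovers_generating_rate_from_sampled_exponential(
        self, rate_per_day, v0, n_samples
    ):
        """Brute-force oracle: noiseless exponential sampled at many points."""
        k = rate_per_day / D
        dt = 2 * D
        vols = [v0 * math.exp(k * i * dt) for i in range(n_samples + 1)]
        phases = tuple(
            phase(vols[i], vols[i + 1], dt) for i in range(n_samples)
        )
        kin = effective_kinetics(Trajectory(phases=phases))
        assert math.isclose(kin.rate, k, rel_tol=1e-9)


class TestIntradayDoublingTime:
    def test_value_at_window_end(self):
        # 0.1 -> 0.42 over 24.5 days
        traj = Trajectory(phases=(phase(0.1, 0.42, 24.5 * D),))
        assert t_d_intraday(traj, 24.5 * D) == pytest.approx(
            LN2 * 24.5 * D / math.log(4.2), rel=1e-12
        )

    @pytest.mark.parametrize("a", [0.1, 0.25, 0.5, 0.9, 1.0])
    def test_linear_in_time(self, a):
        traj = Trajectory(phases=(phase(0.1, 0.42, 24.5 * D),))
        full = t_d_intraday(traj, 24.5 * D)
        assert t_d_intraday(traj, a * 24.5 * D) == pytest.approx(a * full, rel=1e-12)

    def test_pure_doubling_trajectory_gives_total_duration(self):
        traj = Trajectory(phases=(phase(0.1, 0.2, 10 * D),))
        assert t_d_intraday(traj, 10 * D) == pytest.approx(10 * D, rel=1e-12)

    def test_uses_virtualized_endpoints_for_shrinking_arms(self):
        traj = Trajectory(phases=(phase(0.15, 0.09, 6 * D), phase(0.09, 0.17, 8 * D)))
        total_log = math.log(0.25 / 0.15) + math.log(0.17 / 0.09)
        assert t_d_intraday(traj, 7 * D) == pytest.approx(
            LN2 * 7 * D / total_log, rel=1e-12
        )

    @pytest.mark.parametrize("t", [0.0, -1.0, 25 * D])
    def test_time_out_of_range_rejected(self, t):
        traj = Trajectory(phases=(phase(0.1, 0.42, 24.5 * D),))
        with pytest.raises(ValueError):
            t_d_intraday(traj, t)
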
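"""Exponential growth/shrinkage kinetics of tumor-volume trajectories.

The model is strictly exponential: a phase from ``v_start`` to ``v_end``
over ``duration`` seconds has signed rate constant

    k = (ln v_end - ln v_start) / duration      [1/s]

interpreted as the net mitosis-minus-apoptosis rate per cell. Growing
phases carry a doubling time t_d = ln2/k; shrinking phases a half-life
t_half = ln2/|k|.

Shrinking phases are mapped onto equivalent *virtual growth* phases before
any energy computation (see :func:`virtualize`), because the growth-energy
formula is defined only for doubling times. The default mapping,
``half_life_equivalence``, replaces v_end by v_start^2/v_end so that the
virtual doubling time equals the observed half-life exactly.

The *intraday* doubling time tD(t) = ln2 * t / (ln V_final - ln V_initial)
grows linearly in elapsed time t for fixed endpoint volumes; it is the
quantity compared against inter-dose intervals by the regimen-efficiency
criterion.
"""

from __future__ import annotations

import logging
import math

from .errors import DegenerateKineticsError
from .models import (
    Direction,
    Kinetics,
    Trajectory,
    VirtualStrategy,
    VolumePhase,
)

logger = logging.getLogger(__name__)

LN2 = math.log(2)


def rate_constant(phase: VolumePhase) -> float:
    """Signed exponential rate constant of a single phase, in 1/s.

    Positive for growth, negative for shrinkage. Static phases (no volume
    change) have no finite doubling time and are rejected.
    """
    if phase.direction is Direction.STATIC:
        raise DegenerateKineticsError(
            "static phase: doubling time is infinite, rate constant undefined"
        )
    return phase.log_change / phase.duration


def doubling_time(phase: VolumePhase) -> float:
    """Doubling time in seconds of a growing phase: ln2 * t / ln(v1/v0)."""
    if phase.direction is not Direction.GROW:
        raise DegenerateKineticsError(
            "doubling time is defined for growing phases only; "
            "virtualize shrinking phases first"
        )
    return LN2 * phase.duration / phase.log_change


def half_life(phase: VolumePhase) -> float:
    """Half-life in seconds of a shrinking phase: ln2 * t / ln(v0/v1)."""
    if phase.direction is not Direction.SHRINK:
        raise DegenerateKineticsError("half-life is defined for shrinking phases only")
    return LN2 * phase.duration / (-phase.log_change)


def phase_kinetics(phase: VolumePhase) -> Kinetics:
    """Raw (non-virtualized) kinetics of one phase."""
    k = rate_constant(phase)
    if k > 0:
        return Kinetics(rate=k, t_d=LN2 / k)
    return Kinetics(rate=k, t_half=LN2 / abs(k))


def virtualize(
    phase: VolumePhase,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> VolumePhase:
    """Replace a shrinking phase by an equivalent virtual growth phase.

    Keeps ``v_start`` and ``duration``; the virtual end volume depends on
    the strategy:

    - ``half_life_equivalence`` (default): v_end' = v_start^2 / v_end, so
      the virtual doubling time equals the observed half-life exactly.
    - ``reflection``: v_end' = 2*v_start - v_end (mirror the volume loss).
    - ``literal``: v_end' = v_start + v_start^2 / (v_start - v_end), the
      shrinkage-fraction identity read off at face value.

    Growing phases are returned unchanged (with a logged notice).
    """
    strategy = VirtualStrategy(strategy)
    if phase.direction is Direction.GROW:
        logger.info("virtualize called on a growing phase; returned unchanged")
        return phase
    if phase.direction is Direction.STATIC:
        raise DegenerateKineticsError("cannot virtualize a static phase")
    if strategy is VirtualStrategy.HALF_LIFE_EQUIVALENCE:
        v_end = phase.v_start**2 / phase.v_end
    elif strategy is VirtualStrategy.REFLECTION:
        v_end = 2 * phase.v_start - phase.v_end
    else:  # literal
        v_end = phase.v_start + phase.v_start**2 / (phase.v_start - phase.v_end)
    return VolumePhase(v_start=phase.v_start, v_end=v_end, duration=phase.duration)


def virtualize_trajectory(
    trajectory: Trajectory,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> tuple[list[VolumePhase], bool]:
    """Virtualize every shrinking phase; returns (phases, any_virtualized).

    Virtual phases are generally not volume-contiguous with their
    neighbours, so the result is a plain phase list, consumed only through
    per-phase log-volume changes.
    """
    out: list[VolumePhase] = []
    any_virtual = False
    for p in trajectory.phases:
        if p.direction is Direction.SHRINK:
            out.append(virtualize(p, strategy))
            any_virtual = True
        else:
            out.append(p)
    return out, any_virtual


def effective_kinetics(
    trajectory: Trajectory,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> Kinetics:
    """Single time-weighted growth constant of a (virtualized) trajectory.

    Each shrinking phase is virtualized, then

        rate = sum_k ln(v_end'_k / v_start_k) / sum_k duration_k

    i.e. total virtual log-volume change over total elapsed time. Static
    phases contribute zero log-change but full duration.
    """
    strategy = VirtualStrategy(strategy)
    phases, any_virtual = virtualize_trajectory(trajectory, strategy)
    total_log = sum(p.log_change for p in phases)
    total_t = sum(p.duration for p in phases)
    if total_log <= 0:
        raise DegenerateKineticsError(
            "trajectory has no net (virtual) growth; kinetics degenerate"
        )
    rate = total_log / total_t
    return Kinetics(
        rate=rate,
        t_d=LN2 / rate,
        virtual=any_virtual,
        strategy=strategy if any_virtual else None,
    )


def t_d_intraday(
    trajectory: Trajectory,
    t: float,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> float:
    """Intraday doubling time at elapsed time t, in seconds.

    Uses the whole-trajectory virtualized endpoints (the total virtual
    log-volume change), so tD(t) = ln2 * t / sum_k ln(v_end'_k/v_start_k)
    is exactly linear in t.
    """
    total = trajectory.total_duration
    if not (0 < t <= total):
        raise ValueError(
            f"evaluation time {t} s outside observation window (0, {total}] s"
        )
    phases, _ = virtualize_trajectory(trajectory, strategy)
    total_log = sum(p.log_change for p in phases)
    if total_log <= 0:
        raise DegenerateKineticsError("no net (virtual) growth over the trajectory")
    return LN2 * t / total_log


def t_d_intraday_per_phase(
    trajectory: Trajectory,
    t: float,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> float:
    """Intraday doubling time using the endpoints of the phase containing t.

    tD(t) = ln2 * t / (ln v_end' - ln v_start) of the containing
    (virtualized) phase, with t still the global elapsed time. Unlike the
    whole-trajectory form this is only piecewise linear and can *decrease*
    across a phase boundary when regrowth accelerates.
    """
    total = trajectory.total_duration
    if not (0 < t <= total):
        raise ValueError(
            f"evaluation time {t} s outside observation window (0, {total}] s"
        )
    phases, _ = virtualize_trajectory(trajectory, strategy)
    elapsed = 0.0
    for p in phases:
        if t <= elapsed + p.duration or p is phases[-1]:
            if p.log_change <= 0:
                raise DegenerateKineticsError("containing phase has no virtual growth")
            return LN2 * t / p.log_change
        elapsed += p.duration
    raise AssertionError("unreachable")
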
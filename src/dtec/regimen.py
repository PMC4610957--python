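"""Regimen-efficiency criterion and schedule classification.

A cell-cycle-specific agent such as docetaxel acts only on cells passing
through a susceptible cycle phase, so scheduling matters as much as dose.
The efficiency criterion compares the treated tumor's intraday doubling
time at each dose-delivery time t_k against a time interval measured from
therapy start:

- ``to_next_dose`` (default): the interval ends at the *next* dose time
  (observation end for the last dose);
- ``from_start``: the interval ends at t_k itself.

A dose is flagged efficient when the drug-slowed intraday doubling time has
grown at least as long as the comparison interval (ties count as
efficient). A dose delivered exactly at therapy start has intraday doubling
time 0 by linearity and is reported as not evaluable rather than
inefficient.
"""

from __future__ import annotations

import statistics

from .errors import TableValidationError
from .kinetics import t_d_intraday, t_d_intraday_per_phase
from .models import (
    CriterionMode,
    EfficiencyAssessment,
    PerDoseAssessment,
    RegimenSpec,
    ScheduleClass,
    TreatmentRecord,
    VirtualStrategy,
)
from .units import SECONDS_PER_DAY

#: Schedules with median inter-dose gap at most this (and low per-injection
#: dose) are classed metronomic.
METRONOMIC_MAX_GAP_S = 3.5 * SECONDS_PER_DAY
METRONOMIC_MAX_DOSE_MG_KG = 1.0


def classify_schedule_from(
    injection_times: list[float] | tuple[float, ...],
    dose_per_injection: float,
    max_gap_s: float = METRONOMIC_MAX_GAP_S,
    max_dose: float = METRONOMIC_MAX_DOSE_MG_KG,
) -> ScheduleClass:
    """Classify a raw schedule; single-injection regimens are standard."""
    if len(injection_times) < 2:
        return ScheduleClass.STANDARD
    gaps = [b - a for a, b in zip(injection_times, injection_times[1:])]
    if statistics.median(gaps) <= max_gap_s and dose_per_injection <= max_dose:
        return ScheduleClass.METRONOMIC
    return ScheduleClass.STANDARD


def classify_schedule(spec: RegimenSpec, **kwargs) -> ScheduleClass:
    """Classify a parsed regimen as metronomic or standard."""
    return classify_schedule_from(
        list(spec.injection_times), spec.dose_per_injection, **kwargs
    )


def efficiency_profile(
    record: TreatmentRecord,
    spec: RegimenSpec,
    mode: CriterionMode | str = CriterionMode.TO_NEXT_DOSE,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> EfficiencyAssessment:
    """Per-dose efficiency flags and the overall regimen verdict.

    The intraday doubling time of the *treated* arm is evaluated at every
    injection time (whole-trajectory virtualized endpoints); each is
    compared with the mode-dependent interval, flag = (tD >= interval).
    Verdict aggregates the evaluable flags.
    """
    mode = CriterionMode(mode)
    times = spec.injection_times
    if not times:
        raise TableValidationError("empty injection list")
    span = record.treated.total_duration
    entries: list[PerDoseAssessment] = []
    for k, t_k in enumerate(times):
        if mode is CriterionMode.TO_NEXT_DOSE:
            interval = times[k + 1] if k + 1 < len(times) else span
        else:
            interval = t_k
        if t_k == 0:
            entries.append(
                PerDoseAssessment(
                    dose_time=0.0,
                    t_d_intraday=0.0,
                    comparison_interval=interval,
                    efficient=None,
                )
            )
            continue
        t_eval = min(t_k, span)  # a dose at observation end evaluates there
        td = t_d_intraday(record.treated, t_eval, strategy)
        entries.append(
            PerDoseAssessment(
                dose_time=t_k,
                t_d_intraday=td,
                comparison_interval=interval,
                efficient=td >= interval,
            )
        )
    flags = [e.efficient for e in entries if e.efficient is not None]
    if not flags:
        verdict = "not_evaluable"
    elif all(flags):
        verdict = "efficient"
    elif not any(flags):
        verdict = "inefficient"
    else:
        verdict = "mixed"
    return EfficiencyAssessment(
        per_dose=tuple(entries), verdict=verdict, criterion_mode=mode
    )


def steadiness_check(
    record: TreatmentRecord,
    spec: RegimenSpec,
    per_phase: bool = False,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> bool:
    """True iff the intraday doubling time rises strictly dose over dose.

    With whole-trajectory endpoints (default) the intraday doubling time is
    linear in t, so any single-phase arm passes; ``per_phase=True`` instead
    evaluates each dose time against its containing phase's endpoints,
    which can reveal a drop when regrowth accelerates between phases.
    """
    times = [t for t in spec.injection_times]
    if len(times) < 2:
        raise TableValidationError("steadiness check needs at least 2 dose times")
    span = record.treated.total_duration
    eval_fn = t_d_intraday_per_phase if per_phase else t_d_intraday
    values = []
    for t in times:
        if t == 0:
            values.append(0.0)
        else:
            values.append(eval_fn(record.treated, min(t, span), strategy))
    return all(b > a for a, b in zip(values, values[1:]))
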
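"""Compare a metronomic and a standard regimen on the same tumor model.

Both records use the same 2.5e5-cell HeyA8 model. The efficiency criterion
asks, at each dose-delivery time, whether the drug has already stretched
the tumor's intraday doubling time to at least the interval up to the next
dose -- the condition for a cell-cycle-specific agent to keep catching
cells in a susceptible phase.
"""

from dtec import (
    classify_schedule,
    dose_energy,
    efficiency_profile,
    load_table1,
    parse_regimen,
)
from dtec.units import SECONDS_PER_DAY as D

records = {r.treatment_id: r for r in load_table1()}
for tid in (1, 11):
    rec = records[tid]
    spec = parse_regimen(rec.regimen_text, rec.treated.total_duration)
    result = efficiency_profile(rec, spec)
    e = dose_energy(rec).e_dose_emad
    print(f"record {tid}: {rec.regimen_text!r}")
    print(f"  schedule class: {classify_schedule(spec).value}")
    print(f"  E_Dose: {e:.0f} Emad   verdict: {result.verdict}")
    for entry in result.per_dose[:4]:
        flag = {True: "efficient", False: "inefficient", None: "n/a (t=0)"}[entry.efficient]
        print(f"    dose at day {entry.dose_time / D:5.2f}: "
              f"tD intraday {entry.t_d_intraday / D:6.2f} d vs "
              f"interval {entry.comparison_interval / D:5.2f} d -> {flag}")
    if len(result.per_dose) > 4:
        print(f"    ... {len(result.per_dose) - 4} more doses")
    print()

print("The low-dose metronomic schedule yields more energy than the 5.7x")
print("higher standard dose on the same model, yet neither satisfies the")
print("intraday criterion here - dosing outpaces the induced slowdown.")
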
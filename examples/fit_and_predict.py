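"""Fit the dose-energy model and predict a treated doubling time.

The three models with identical 840 ug/ml energy yields support a
through-origin linear model E_Dose = slope x dose. Given a new patient's
control kinetics (histologic grade) and a proposed dose, the model
predicts the treated doubling time before therapy.
"""

from dtec import (
    dose_energy,
    effective_kinetics,
    fit_dose_energy,
    load_table1,
    predict_response,
)
from dtec.units import SECONDS_PER_DAY as D

records = {r.treatment_id: r for r in load_table1()}
pts = [(records[i].dose_ug_per_ml, dose_energy(records[i]).e_dose_emad)
       for i in (7, 8, 9)]
model = fit_dose_energy(pts, through_origin=True)
print(f"through-origin fit on records 7-9: slope = {model.slope:.2f} Emad/(ug/ml), "
      f"R^2 = {model.r_squared:.5f}")

rec = records[9]
control_t_d = effective_kinetics(rec.control).t_d
pred = predict_response(model, control_t_d, rec.inoculum, 840.0)
observed = effective_kinetics(rec.treated).t_d
print(f"record 9 control tD: {control_t_d / D:.2f} d")
print(f"predicted treated tD at 840 ug/ml: {pred.t_d / D:.2f} d "
      f"(observed {observed / D:.2f} d, "
      f"error {abs(pred.t_d - observed) / observed:.1%})")
print(f"predicted volume fold-change over the control tD window: "
      f"{pred.fold_change:.2f}x")
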
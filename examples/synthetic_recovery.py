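"""Closed-loop check: simulate a cohort with a known dose-energy line,
then recover it with the analyzer.

With no measurement noise the recovered slope matches the generating value
to machine-level precision; with 5% lognormal volume noise on 20 animals
it stays within a few percent.
"""

from dtec import dose_energy, fit_dose_energy, simulate_cohort
from dtec.models import SyntheticCohortConfig
from dtec.units import SECONDS_PER_DAY as D

for sigma in (0.0, 0.05):
    cfg = SyntheticCohortConfig(
        n_records=20,
        control_t_d=7 * D,          # a typical xenograft control arm
        inoculum=1e6,
        dose_grid=tuple(50.0 * i for i in range(1, 21)),  # 50..1000 ug/ml
        true_slope=175.0,           # Emad per (ug/ml)
        true_intercept=0.0,
        noise_sigma=sigma,
        observation_span=14 * D,
        seed=1,
    )
    records, truth = simulate_cohort(cfg)
    pts = [(r.dose_ug_per_ml, dose_energy(r).e_dose_emad) for r in records]
    model = fit_dose_energy(pts)
    print(f"sigma = {sigma:>4}: recovered slope {model.slope:8.3f} "
          f"(truth {truth['true_slope']}), "
          f"intercept {model.intercept:10.3f}, r = {model.pearson_r:.5f}")

print("\nThe generator and analyzer are exact inverses at sigma = 0;")
print("noise enters only through the endpoint volumes.")
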
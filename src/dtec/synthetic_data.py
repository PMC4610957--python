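"""Synthetic xenograft cohorts with known ground truth.

Every trajectory is exponential by construction (the same model the
analysis assumes), so the generator closes the loop: analyzing a noiseless
cohort must return the generating parameters exactly. A cohort is built
backwards from a target linear dose-energy relation:

    E_Dose(d) = true_slope * d + true_intercept          [Emad]
    E_treated = E_G(control_t_d) + E_Dose(d) / C0xh      per cell
    t_d,treated = invert(E_treated)

and both arms are rendered as endpoint-volume trajectories over the
observation span. Measurement error, when requested, is multiplicative
lognormal on the endpoint volume (volumes are positive and errors scale
with size); a single integer seed drives all randomness.

What this emulates: the endpoint-only volume records of published studies,
exponential growth, known inoculum. What it does not: intra-trajectory
sampling, inter-animal variability structure, pharmacokinetics, or any
departure from exponential kinetics.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import TableValidationError
from .energetics import energy_to_doubling_time, growth_energy
from .models import (
    SyntheticCohortConfig,
    Trajectory,
    TreatmentRecord,
    VolumePhase,
)

LN2 = math.log(2)


def simulate_trajectory(
    t_d_or_t_half: float,
    v0: float,
    duration: float,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
    arm: str = "synthetic",
) -> Trajectory:
    """Simulate one exponential phase; sign selects growth vs shrinkage.

    Positive ``t_d_or_t_half`` is a doubling time (growth); negative, a
    half-life (shrinkage): v_end = v0 * 2^(+-duration/|t|). With
    ``noise_sigma`` > 0 the endpoint volume is multiplied by exp(eps),
    eps ~ N(0, noise_sigma^2), drawn from ``rng`` (an int seeds a fresh
    generator). sigma = 0 is exactly deterministic.
    """
    if t_d_or_t_half == 0:
        raise TableValidationError("doubling time / half-life must be nonzero")
    if v0 <= 0 or duration <= 0:
        raise TableValidationError("v0 and duration must be positive")
    if noise_sigma < 0:
        raise TableValidationError("noise_sigma must be >= 0")
    sign = 1.0 if t_d_or_t_half > 0 else -1.0
    v_end = v0 * 2.0 ** (sign * duration / abs(t_d_or_t_half))
    if noise_sigma > 0:
        if rng is None:
            raise TableValidationError("a seed or Generator is required when noise_sigma > 0")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        v_end *= math.exp(noise_sigma * rng.standard_normal())
    return Trajectory(
        phases=(VolumePhase(v_start=v0, v_end=v_end, duration=duration),), arm=arm
    )


def simulate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[TreatmentRecord], dict]:
    """Generate a cohort following a known dose-energy line.

    Records cycle over ``config.dose_grid``. Returns the records plus a
    ground-truth sidecar recording every latent quantity (generating slope
    and intercept, per-record true E_Dose, control and treated doubling
    times, noiseless endpoint volumes).
    """
    rng = np.random.default_rng(config.seed)
    e_control = growth_energy(config.control_t_d)
    records: list[TreatmentRecord] = []
    truth_rows: list[dict] = []
    for i in range(config.n_records):
        dose = config.dose_grid[i % len(config.dose_grid)]
        e_dose = config.true_slope * dose + config.true_intercept
        e_treated = e_control + e_dose / config.inoculum
        try:
            t_d_treated = energy_to_doubling_time(e_treated)
        except (OverflowError, ValueError) as exc:
            raise TableValidationError(
                f"dose {dose} ug/ml drives the treated energy outside the "
                f"invertible domain ({e_treated:.4g} Emad per cell)"
            ) from exc
        if not math.isfinite(t_d_treated):
            raise TableValidationError(
                f"dose {dose} ug/ml yields a non-finite treated doubling time"
            )
        # standard-normal draws are consumed unconditionally so the same
        # seed produces proportionally scaled noise across sigma values
        eps_c = config.noise_sigma * rng.standard_normal()
        eps_t = config.noise_sigma * rng.standard_normal()
        span = config.observation_span
        v_end_control = config.v0 * 2.0 ** (span / config.control_t_d)
        v_end_treated = config.v0 * 2.0 ** (span / t_d_treated)
        control = Trajectory(
            phases=(
                VolumePhase(
                    v_start=config.v0,
                    v_end=v_end_control * math.exp(eps_c),
                    duration=span,
                ),
            ),
            arm="control",
        )
        treated = Trajectory(
            phases=(
                VolumePhase(
                    v_start=config.v0,
                    v_end=v_end_treated * math.exp(eps_t),
                    duration=span,
                ),
            ),
            arm="treated",
        )
        records.append(
            TreatmentRecord(
                treatment_id=i + 1,
                study_label="synthetic cohort",
                cell_line="synthetic",
                inoculum=config.inoculum,
                dose_ug_per_ml=dose,
                regimen_text=f"{dose / 28:g} mg/kg on day 0",
                control=control,
                treated=treated,
            )
        )
        truth_rows.append(
            {
                "treatment_id": i + 1,
                "dose_ug_per_ml": dose,
                "e_dose_emad": e_dose,
                "control_t_d": config.control_t_d,
                "treated_t_d": t_d_treated,
                "v_end_control_noiseless": v_end_control,
                "v_end_treated_noiseless": v_end_treated,
            }
        )
    truth = {
        "true_slope": config.true_slope,
        "true_intercept": config.true_intercept,
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
        "records": truth_rows,
    }
    return records, truth
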
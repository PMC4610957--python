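"""Dose-energy modeling: clustering, regression, prediction, dose audit.

The central claim under test is that a given docetaxel dose, delivered in
an efficient schedule, yields a reproducible energy E_Dose regardless of
tumor model. "Identical" effects are detected by single-linkage clustering
under a relative tolerance; the dose -> energy relation is fitted by
ordinary least squares; and a fitted model plus a patient's control-arm
kinetics (histologic grade) predicts the treated doubling time at a
proposed dose.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy import stats

from .errors import PredictionDomainError, TableValidationError
from .energetics import energy_to_doubling_time, growth_energy
from .models import DoseEnergyModel, RegimenSpec, TreatmentRecord

#: Empirical regularity of the reference table: the tabulated ug/ml dose is
#: 28x the cumulative mg/kg of the regimen text. Audit-only, never used in
#: analysis values.
UG_ML_PER_CUMULATIVE_MG_KG = 28.0
AUDIT_REL_TOL = 0.005


def cluster_identical(
    e_doses: Sequence[tuple[int, float]], rel_tol: float = 0.05
) -> list[list[tuple[int, float]]]:
    """Group energy yields that are pairwise-chained within ``rel_tol``.

    Single linkage: two values join a cluster if |a-b|/max(|a|,|b|) <=
    rel_tol for some chain of members. Returns clusters sorted by size
    (descending), ties by smallest member id.
    """
    if not 0 < rel_tol < 0.5:
        raise TableValidationError(f"rel_tol must be in (0, 0.5), got {rel_tol}")
    items = list(e_doses)
    if not items:
        raise TableValidationError("empty E_Dose list")
    n = len(items)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i][1], items[j][1]
            denom = max(abs(a), abs(b))
            close = (a == b) if denom == 0 else abs(a - b) / denom <= rel_tol
            if close:
                parent[find(i)] = find(j)

    groups: dict[int, list[tuple[int, float]]] = {}
    for i, item in enumerate(items):
        groups.setdefault(find(i), []).append(item)
    return sorted(groups.values(), key=lambda g: (-len(g), min(i for i, _ in g)))


def fit_dose_energy(
    points: Sequence[tuple[float, float]], through_origin: bool = False
) -> DoseEnergyModel:
    """Ordinary least squares fit of E_Dose (Emad) against dose (ug/ml).

    With an intercept the design must contain at least two distinct doses;
    the through-origin fit tolerates replicated doses (slope = Sxy/Sxx).
    Pearson r is computed on the raw pairs and is None when either variable
    is constant; two-point intercept fits are flagged underdetermined.
    """
    pts = list(points)
    if len(pts) < 2:
        raise TableValidationError("need at least 2 (dose, E_Dose) points")
    x = np.asarray([p[0] for p in pts], dtype=float)
    y = np.asarray([p[1] for p in pts], dtype=float)

    x_const = np.ptp(x) == 0
    y_const = np.ptp(y) == 0
    pearson: Optional[float] = None
    if not x_const and not y_const:
        pearson = float(stats.pearsonr(x, y).statistic)

    if through_origin:
        sxx = float(x @ x)
        if sxx == 0:
            raise TableValidationError("all doses are zero; degenerate design")
        slope = float(x @ y) / sxx
        resid = y - slope * x
        ss_tot = float(y @ y)  # uncentered: model has no intercept
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
        return DoseEnergyModel(
            slope=slope,
            intercept=0.0,
            pearson_r=pearson,
            r_squared=r2,
            n=len(pts),
            through_origin=True,
            underdetermined=len(pts) < 3 or x_const,
        )

    if x_const:
        raise TableValidationError(
            "all doses equal: intercept fit is degenerate (use through_origin)"
        )
    res = stats.linregress(x, y)
    return DoseEnergyModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        n=len(pts),
        through_origin=False,
        underdetermined=len(pts) < 3,
    )


class PredictedResponse(BaseModel):
    """Predicted treated-arm response to a proposed dose."""

    model_config = ConfigDict(frozen=True)

    t_d: float
    e_dose_emad: float
    treated_e_per_cell: float
    control_e_per_cell: float
    fold_change: float
    horizon: float


def predict_response(
    model: DoseEnergyModel,
    control_t_d: float,
    inoculum: float,
    dose_ug_per_ml: float,
    horizon: float | None = None,
) -> PredictedResponse:
    """Predict the treated doubling time and volume fold-change at a dose.

    The model's E_Dose at the proposed dose is added (per cell) to the
    control growth energy and mapped back through the inverse energy
    formula:

        t_d,treated = invert(E_G(t_d,control) + E_Dose(dose) / C0xh)

    ``horizon`` (seconds; defaults to the control doubling time) sets the
    window for the reported fold-change 2^(horizon / t_d,treated).
    """
    if inoculum < 1:
        raise TableValidationError(f"inoculum must be >= 1, got {inoculum}")
    e_control = growth_energy(control_t_d)
    e_dose = model.predict_e_dose(dose_ug_per_ml)
    e_treated = e_control + e_dose / inoculum
    try:
        t_d = energy_to_doubling_time(e_treated)
    except (OverflowError, ValueError) as exc:
        raise PredictionDomainError(
            f"predicted per-cell energy {e_treated:.4g} Emad exceeds the "
            "invertible domain: response exceeds model domain"
        ) from exc
    if not math.isfinite(t_d):
        raise PredictionDomainError(
            f"predicted per-cell energy {e_treated:.4g} Emad maps to a "
            "non-finite doubling time: response exceeds model domain"
        )
    h = control_t_d if horizon is None else horizon
    return PredictedResponse(
        t_d=t_d,
        e_dose_emad=e_dose,
        treated_e_per_cell=e_treated,
        control_e_per_cell=e_control,
        fold_change=2.0 ** (h / t_d),
        horizon=h,
    )


class DoseAuditEntry(BaseModel):
    """Consistency check between the dose column and the regimen text."""

    model_config = ConfigDict(frozen=True)

    treatment_id: int
    cumulative_mg_per_kg: float
    expected_ug_per_ml: float
    tabulated_ug_per_ml: float
    rel_deviation: float
    consistent: bool


def audit_dose_column(
    record: TreatmentRecord, spec: RegimenSpec
) -> DoseAuditEntry:
    """Flag rows whose ug/ml dose is not 28x the regimen's cumulative mg/kg.

    Warning-level bookkeeping only: the tabulated ug/ml column remains
    authoritative for every energy analysis regardless of the outcome.
    """
    cumulative = spec.cumulative_mg_per_kg
    expected = UG_ML_PER_CUMULATIVE_MG_KG * cumulative
    rel = abs(record.dose_ug_per_ml - expected) / expected
    return DoseAuditEntry(
        treatment_id=record.treatment_id,
        cumulative_mg_per_kg=cumulative,
        expected_ug_per_ml=expected,
        tabulated_ug_per_ml=record.dose_ug_per_ml,
        rel_deviation=rel,
        consistent=rel <= AUDIT_REL_TOL,
    )
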
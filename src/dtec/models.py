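"""Domain types for the doubling-time/energy-conversion (DT-EC) analysis.

Volumes are in cm^3, durations and times in seconds, energies in Emad
(per-cell) unless a field name says MeV, doses in ug/ml (tabulated) or
mg/kg (per injection).
"""

from __future__ import annotations

import enum
import math
from typing import Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import TableValidationError


class Direction(str, enum.Enum):
    GROW = "grow"
    SHRINK = "shrink"
    STATIC = "static"


class VirtualStrategy(str, enum.Enum):
    """How a shrinking phase is mapped onto an equivalent growing phase."""

    HALF_LIFE_EQUIVALENCE = "half_life_equivalence"
    REFLECTION = "reflection"
    LITERAL = "literal"


class CriterionMode(str, enum.Enum):
    """Comparison interval for the regimen-efficiency criterion."""

    TO_NEXT_DOSE = "to_next_dose"
    FROM_START = "from_start"


class ScheduleClass(str, enum.Enum):
    STANDARD = "standard"
    METRONOMIC = "metronomic"


class VolumePhase(BaseModel):
    """One monotone segment of a tumor-volume trajectory."""

    model_config = ConfigDict(frozen=True)

    v_start: float = Field(gt=0, description="starting volume, cm^3")
    v_end: float = Field(gt=0, description="ending volume, cm^3")
    duration: float = Field(gt=0, description="phase duration, seconds")

    @property
    def direction(self) -> Direction:
        if self.v_end > self.v_start:
            return Direction.GROW
        if self.v_end < self.v_start:
            return Direction.SHRINK
        return Direction.STATIC

    @property
    def log_change(self) -> float:
        """ln(v_end / v_start); signed."""
        return math.log(self.v_end / self.v_start)


class Trajectory(BaseModel):
    """Ordered, volume-contiguous phases observed on one study arm."""

    model_config = ConfigDict(frozen=True)

    phases: tuple[VolumePhase, ...]
    arm: Literal["control", "treated", "synthetic"] = "control"

    @model_validator(mode="after")
    def _check_contiguity(self) -> "Trajectory":
        if not self.phases:
            raise TableValidationError("trajectory must contain at least one phase")
        for k in range(len(self.phases) - 1):
            if self.phases[k].v_end != self.phases[k + 1].v_start:
                raise TableValidationError(
                    f"phases {k} and {k + 1} are not volume-contiguous: "
                    f"{self.phases[k].v_end} != {self.phases[k + 1].v_start}"
                )
        return self

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def v_initial(self) -> float:
        return self.phases[0].v_start

    @property
    def v_final(self) -> float:
        return self.phases[-1].v_end


class RegimenSpec(BaseModel):
    """Explicit dosing schedule parsed from a regimen description.

    ``nominal_n_doses`` is the dose count implied by the phrasing itself
    (dose rate x stated duration for rate phrasings, so it may be
    fractional, e.g. thrice weekly for 3.5 weeks -> 10.5); it is the basis
    for cumulative-dose audits and is unaffected by truncation of
    ``injection_times`` to the observation span.
    """

    model_config = ConfigDict(frozen=True)

    dose_per_injection: float = Field(gt=0, description="mg/kg per injection")
    injection_times: tuple[float, ...] = Field(
        description="seconds from therapy start, strictly increasing"
    )
    schedule_class: ScheduleClass
    nominal_n_doses: float = Field(gt=0)
    source_text: str = ""

    @model_validator(mode="after")
    def _check_times(self) -> "RegimenSpec":
        t = self.injection_times
        if not t:
            raise TableValidationError("regimen must have at least one injection")
        if t[0] < 0:
            raise TableValidationError("first injection time must be >= 0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise TableValidationError("injection times must be strictly increasing")
        return self

    @property
    def cumulative_mg_per_kg(self) -> float:
        return self.dose_per_injection * self.nominal_n_doses


class TreatmentRecord(BaseModel):
    """One treatment-table row: a control arm and a treated arm."""

    model_config = ConfigDict(frozen=True)

    treatment_id: int = Field(ge=1)
    study_label: str
    cell_line: str
    inoculum: float = Field(ge=1, description="inoculated cell count C0xh")
    dose_ug_per_ml: float = Field(gt=0)
    regimen_text: str
    control: Trajectory
    treated: Trajectory


class Kinetics(BaseModel):
    """Effective exponential kinetics of one arm.

    ``rate`` is the signed rate constant in 1/s (positive = growth). For a
    growing (or virtualized) arm ``t_d`` = ln2/rate; for a raw shrinking
    phase ``t_half`` = ln2/|rate| is populated instead.
    """

    model_config = ConfigDict(frozen=True)

    rate: float
    t_d: Optional[float] = None
    t_half: Optional[float] = None
    virtual: bool = False
    strategy: Optional[VirtualStrategy] = None

    @model_validator(mode="after")
    def _check_consistency(self) -> "Kinetics":
        if self.rate == 0:
            raise TableValidationError("rate constant must be nonzero")
        ln2 = math.log(2)
        defined = [x for x in (self.t_d, self.t_half) if x is not None]
        if len(defined) != 1:
            raise TableValidationError("exactly one of t_d / t_half must be set")
        if abs(defined[0] * abs(self.rate) - ln2) > 1e-12 * ln2:
            raise TableValidationError("t_d/t_half inconsistent with rate")
        return self


class EnergyResult(BaseModel):
    """Per-cell growth energy and total tumor (histologic-grade) energy."""

    model_config = ConfigDict(frozen=True)

    e_per_cell: float = Field(description="per-cell growth energy, Emad")
    hg_emad: float
    hg_mev: float
    inoculum: float = Field(ge=1)


class DoseEnergy(BaseModel):
    """Energy yield of a regimen: treated-minus-control HG difference."""

    model_config = ConfigDict(frozen=True)

    e_dose_emad: float
    e_dose_mev: float
    treated_e_per_cell: float
    control_e_per_cell: float
    virtual_used: bool
    strategy: VirtualStrategy


class PerDoseAssessment(BaseModel):
    """Efficiency check at one dose-delivery time.

    ``efficient`` is None when the dose falls at therapy start (t = 0),
    where the intraday doubling time is identically zero and the criterion
    is not evaluable.
    """

    model_config = ConfigDict(frozen=True)

    dose_time: float
    t_d_intraday: float
    comparison_interval: float
    efficient: Optional[bool]


class EfficiencyAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    per_dose: tuple[PerDoseAssessment, ...]
    verdict: Literal["efficient", "inefficient", "mixed", "not_evaluable"]
    criterion_mode: CriterionMode


class DoseEnergyModel(BaseModel):
    """Fitted linear dose -> energy-yield relation with diagnostics."""

    model_config = ConfigDict(frozen=True)

    slope: float = Field(description="Emad per (ug/ml)")
    intercept: float = Field(description="Emad; 0 for through-origin fits")
    pearson_r: Optional[float] = Field(
        default=None, description="None when either variable is constant"
    )
    r_squared: float
    n: int = Field(ge=2)
    through_origin: bool
    underdetermined: bool = False

    @model_validator(mode="after")
    def _check_r(self) -> "DoseEnergyModel":
        if self.pearson_r is not None and abs(self.pearson_r) > 1 + 1e-12:
            raise TableValidationError(f"|pearson_r| must be <= 1, got {self.pearson_r}")
        return self

    def predict_e_dose(self, dose_ug_per_ml: float) -> float:
        return self.slope * dose_ug_per_ml + self.intercept


class SyntheticCohortConfig(BaseModel):
    """Ground-truth parameters for a simulated xenograft cohort."""

    model_config = ConfigDict(frozen=True)

    n_records: int = Field(ge=1)
    control_t_d: float = Field(gt=0, description="control doubling time, s")
    inoculum: float = Field(ge=1)
    dose_grid: tuple[float, ...] = Field(description="doses in ug/ml, cycled over records")
    true_slope: float = Field(description="Emad per (ug/ml)")
    true_intercept: float = 0.0
    noise_sigma: float = Field(ge=0, default=0.0)
    observation_span: float = Field(gt=0, description="seconds")
    v0: float = Field(gt=0, default=0.1, description="inoculation volume, cm^3")
    seed: int

    @model_validator(mode="after")
    def _check_grid(self) -> "SyntheticCohortConfig":
        if not self.dose_grid or any(d <= 0 for d in self.dose_grid):
            raise TableValidationError("dose_grid must be non-empty and positive")
        return self


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    input_path: str
    output_dir: str
    virtual_strategy: VirtualStrategy = VirtualStrategy.HALF_LIFE_EQUIVALENCE
    criterion_mode: CriterionMode = CriterionMode.TO_NEXT_DOSE
    cluster_tol: float = Field(gt=0, lt=0.5, default=0.05)
    fit_subset: Optional[tuple[int, ...]] = None
    through_origin: bool = False
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_subset(self) -> "RunConfig":
        if self.fit_subset is not None and len(self.fit_subset) < 2:
            raise TableValidationError("fit_subset needs at least 2 record ids")
        return self


def make_trajectory(
    phases: Sequence[VolumePhase], arm: str = "control"
) -> Trajectory:
    """Convenience constructor accepting any phase sequence."""
    return Trajectory(phases=tuple(phases), arm=arm)
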
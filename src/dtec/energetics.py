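"""Doubling time-energy conversion (DT-EC).

Maps exponential kinetics to energies:

- per-cell growth energy   E_G(t_d) = ln[ (ln(ln2 / t_d))^2 ]   [Emad]
- unit conversion          1 Emad = 23234.59 MeV
- histologic-grade energy  H_G = E_G * C0xh                     [Emad, MeV]
- dose energy              E_Dose = (E_G,treated - E_G,control) * C0xh

where C0xh is the inoculated cell count of the xenograft. For every
biological doubling time ln2/t_d < 1, so the inner logarithm is negative
and the formula is read as the logarithm *of the square* (the square taken
first), which is the only real-valued reading. On that branch E_G is
strictly increasing in t_d: slower-dividing (better differentiated,
therapy-slowed) tumors carry more converted energy per cell, and a
treatment that slows growth yields a positive E_Dose.

All energies are computed and stored in Emad; MeV is applied as a final
presentation conversion so the large constant never enters comparisons.
"""

from __future__ import annotations

import logging
import math
import warnings

from .errors import EnergyDomainError
from .kinetics import effective_kinetics
from .models import (
    DoseEnergy,
    EnergyResult,
    TreatmentRecord,
    VirtualStrategy,
)
from .units import MEV_PER_EMAD

logger = logging.getLogger(__name__)

LN2 = math.log(2)

#: Mathematical lower bound of the nonnegative-energy branch: at
#: t_d = ln2*e s the inner logarithm is -1 and E_G = 0.
T_D_LOWER_BOUND = LN2 * math.e

#: Doubling times below one hour are biologically implausible for tumors;
#: values in (ln2*e, 3600) s are accepted with a warning.
T_D_PLAUSIBILITY_FLOOR = 3600.0


def growth_energy(t_d: float) -> float:
    """Per-cell growth energy in Emad for doubling time ``t_d`` seconds.

    E_G = ln[(ln(ln2/t_d))^2], defined (and nonnegative) for
    t_d >= ln2*e s; strictly increasing in t_d on that domain.
    """
    if t_d < T_D_LOWER_BOUND:
        raise EnergyDomainError(
            f"doubling time {t_d} s below ln2*e s ({T_D_LOWER_BOUND:.4f} s); "
            "growth energy undefined on the nonnegative branch"
        )
    if t_d < T_D_PLAUSIBILITY_FLOOR:
        warnings.warn(
            f"doubling time {t_d} s is below the plausibility floor "
            f"({T_D_PLAUSIBILITY_FLOOR} s); energy computed anyway",
            stacklevel=2,
        )
    inner = math.log(LN2 / t_d)  # <= -1 on the valid domain
    return math.log(inner * inner)


def energy_to_doubling_time(e_g: float) -> float:
    """Inverse of :func:`growth_energy` on the biological branch.

    t_d = ln2 * exp(+sqrt(exp(E_G))), the branch where ln(ln2/t_d) < 0
    (doubling times above ln2*e seconds).
    """
    if not math.isfinite(e_g):
        raise EnergyDomainError(f"energy must be finite, got {e_g}")
    return LN2 * math.exp(math.sqrt(math.exp(e_g)))


def emad_to_mev(e: float) -> float:
    """Convert an energy from Emad to MeV (1 Emad = 23234.59 MeV)."""
    return e * MEV_PER_EMAD


def mev_to_emad(e: float) -> float:
    """Convert an energy from MeV to Emad."""
    return e / MEV_PER_EMAD


def histologic_grade(t_d: float, inoculum: float) -> EnergyResult:
    """Total tumor energy H_G = E_G(t_d) * C0xh, in Emad and MeV."""
    if inoculum < 1:
        raise EnergyDomainError(f"inoculum must be >= 1 cell, got {inoculum}")
    e = growth_energy(t_d)
    hg = e * inoculum
    return EnergyResult(
        e_per_cell=e, hg_emad=hg, hg_mev=emad_to_mev(hg), inoculum=inoculum
    )


def dose_energy(
    record: TreatmentRecord,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> DoseEnergy:
    """Energy yield of the regimen on one record.

    Effective kinetics are computed per arm (shrinking portions replaced by
    virtual growth per ``strategy``), converted to per-cell energies, and
    differenced: E_Dose = (E_treated - E_control) * C0xh. Negative values
    are allowed (treatment that accelerates growth drains energy).
    """
    strategy = VirtualStrategy(strategy)
    kin_c = effective_kinetics(record.control, strategy)
    kin_t = effective_kinetics(record.treated, strategy)
    e_c = growth_energy(kin_c.t_d)
    e_t = growth_energy(kin_t.t_d)
    e_dose = (e_t - e_c) * record.inoculum
    return DoseEnergy(
        e_dose_emad=e_dose,
        e_dose_mev=emad_to_mev(e_dose),
        treated_e_per_cell=e_t,
        control_e_per_cell=e_c,
        virtual_used=kin_c.virtual or kin_t.virtual,
        strategy=strategy,
    )
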
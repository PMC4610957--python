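"""Exception hierarchy for the dtec package.

All package errors derive from :class:`DtecError` so callers can catch one
base class; per-record pipeline failures are wrapped in :class:`RecordError`
carrying the offending treatment id.
"""


class DtecError(Exception):
    """Base class for all dtec errors."""


class PhaseParseError(DtecError, ValueError):
    """A trajectory phase string does not match the ``v0->v1@Nu`` grammar."""


class RegimenParseError(DtecError, ValueError):
    """A regimen description does not match any recognized phrasing."""


class TableValidationError(DtecError):
    """A treatment-table row or domain-type invariant is violated.

    Deliberately not a ValueError: pydantic validators re-raise it
    unwrapped, so callers always see this type for invariant violations.
    """


class DegenerateKineticsError(DtecError, ValueError):
    """Kinetics are undefined: static phase or zero net volume change."""


class EnergyDomainError(DtecError, ValueError):
    """Doubling time outside the domain of the growth-energy formula."""


class PredictionDomainError(DtecError, ValueError):
    """Predicted per-cell energy falls outside the invertible domain."""


class RecordError(DtecError):
    """Wraps any error raised while analyzing a single treatment record."""

    def __init__(self, treatment_id: int, cause: Exception):
        self.treatment_id = treatment_id
        self.cause = cause
        super().__init__(f"record {treatment_id}: {cause}")
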
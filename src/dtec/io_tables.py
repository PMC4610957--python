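"""Reading and writing treatment tables, trajectory and regimen grammars.

The treatment table is a CSV with one row per (control, treated) xenograft
study arm pair:

    treatment_id, study_label, cell_line, inoculum, dose_ug_per_ml,
    regimen_text, control_phases, treated_phases

Volume trajectories use a compact phase grammar, ``v0->v1@Nu`` with
``;``-separated phases and unit ``d`` (days) or ``w`` (weeks), e.g.
``0.15->0.09@6d;0.09->0.17@8d`` for a shrink-then-regrow arm. All durations
are stored internally in seconds (1 d = 86,400 s, 1 w = 604,800 s).

Regimen descriptions follow a small set of fixed phrasings (explicit dose
days, "every Nth day", weekly / biweekly / thrice-weekly rates); anything
else must be supplied as an explicit injection-time list.

A 14-row reference table of published docetaxel xenograft studies is
packaged as ``data/table1.csv`` and guarded by a checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import PhaseParseError, RegimenParseError, TableValidationError
from .models import RegimenSpec, Trajectory, TreatmentRecord, VolumePhase
from .units import SECONDS_PER_DAY, SECONDS_PER_WEEK, days, weeks

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "treatment_id",
    "study_label",
    "cell_line",
    "inoculum",
    "dose_ug_per_ml",
    "regimen_text",
    "control_phases",
    "treated_phases",
)

#: SHA-256 of the packaged reference-table transcription.
FIXTURE_SHA256 = "9da6c0a1d3a80a68321be4780a34f6702c0bc197f70024101c3b4c64511af048"

_PHASE_RE = re.compile(
    r"^\s*(?P<v0>\d+(?:\.\d+)?)\s*->\s*(?P<v1>\d+(?:\.\d+)?)"
    r"\s*@\s*(?P<n>\d+(?:\.\d+)?)\s*(?P<unit>[dw])\s*$"
)

_UNIT_SECONDS = {"d": SECONDS_PER_DAY, "w": SECONDS_PER_WEEK}


def parse_phase_string(text: str, arm: str = "control") -> Trajectory:
    """Parse a ``;``-separated phase string into a :class:`Trajectory`.

    >>> t = parse_phase_string("0.1->1.2@3.5w")
    >>> t.phases[0].duration
    2116800.0
    """
    if not isinstance(text, str) or not text.strip():
        raise PhaseParseError("empty trajectory string")
    phases = []
    for token in text.split(";"):
        m = _PHASE_RE.match(token)
        if m is None:
            raise PhaseParseError(
                f"phase token {token.strip()!r} does not match 'v0->v1@Nu' "
                "(unit d or w)"
            )
        duration = float(m.group("n")) * _UNIT_SECONDS[m.group("unit")]
        try:
            phases.append(
                VolumePhase(
                    v_start=float(m.group("v0")),
                    v_end=float(m.group("v1")),
                    duration=duration,
                )
            )
        except Exception as exc:  # pydantic validation
            raise PhaseParseError(f"invalid phase {token.strip()!r}: {exc}") from exc
    return Trajectory(phases=tuple(phases), arm=arm)


def format_phase_string(trajectory: Trajectory) -> str:
    """Canonical phase string: integral weeks as ``Nw``, otherwise days."""

    def fmt(p: VolumePhase) -> str:
        if p.duration % SECONDS_PER_WEEK == 0:
            n, u = p.duration / SECONDS_PER_WEEK, "w"
        else:
            n, u = p.duration / SECONDS_PER_DAY, "d"
        return f"{p.v_start:.12g}->{p.v_end:.12g}@{n:.12g}{u}"

    return ";".join(fmt(p) for p in trajectory.phases)


# ---------------------------------------------------------------------------
# regimen grammar
# ---------------------------------------------------------------------------

_NUMBER_WORDS = {
    "one": 1, "two": 2, "three": 3, "four": 4, "five": 5, "six": 6,
    "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11, "twelve": 12,
}

_NUM = r"\d+(?:\.\d+)?"


def _count(word: str) -> int:
    w = word.strip().lower()
    if w in _NUMBER_WORDS:
        return _NUMBER_WORDS[w]
    if w.isdigit():
        return int(w)
    raise RegimenParseError(f"unrecognized dose count {word!r}")


def _day_list(text: str) -> list[float]:
    parts = re.split(r"\s*,\s*|\s+and\s+", text.strip())
    return [float(p) for p in parts if p]


def _rate_times(interval_s: float, duration_s: float) -> list[float]:
    """Evenly spaced times starting at 0, strictly inside the stated span."""
    out, t = [], 0.0
    while t < duration_s - 1e-9:
        out.append(t)
        t += interval_s
    return out


def parse_regimen(text: str, observation_span: float) -> RegimenSpec:
    """Parse a regimen description into an explicit injection schedule.

    Recognized phrasings (case-insensitive)::

        N mg/kg thrice weekly for W weeks
        K doses of N mg/kg on days a and b
        K doses of N mg/kg/week
        K doses of N mg/kg on D days
        N mg/kg every Gth day (total of K doses)
        N mg/kg on days a, b and c
        N mg/kg/week for W weeks
        N mg/kg/2 weeks for W weeks
        N mg/kg per injection twice a week for W weeks

    Rate phrasings place the first injection at therapy start and space
    uniformly. ``nominal_n_doses`` is the count implied by the phrasing
    (rate x duration for rate phrasings, hence possibly fractional).
    Injections after ``observation_span`` seconds are dropped with a
    warning; at least one must remain.
    """
    s = re.sub(r"\s+", " ", text.strip())
    s = re.sub(r"\bbody weight\b|\bgiven\b|\bi\.?v\.?(?=\s|$)", "", s, flags=re.I)
    s = re.sub(r"\s+", " ", s).strip()

    dose: float
    times: list[float]
    nominal: float

    if m := re.match(
        rf"^(?P<d>{_NUM}) mg/kg thrice weekly for (?P<w>{_NUM}) weeks?$", s, re.I
    ):
        dose = float(m["d"])
        dur = weeks(float(m["w"]))
        times = _rate_times(days(7 / 3), dur)
        nominal = 3 * float(m["w"])
    elif m := re.match(
        rf"^(?P<k>\w+) doses of (?P<d>{_NUM}) mg/kg on days? (?P<days>[\d., and]+)$",
        s, re.I,
    ):
        dose = float(m["d"])
        times = [days(x) for x in _day_list(m["days"])]
        nominal = float(_count(m["k"]))
        if len(times) != nominal:
            raise RegimenParseError(
                f"{text!r}: stated count {nominal:g} != {len(times)} listed days"
            )
    elif m := re.match(
        rf"^(?P<k>\w+) doses of (?P<d>{_NUM}) mg/kg/week$", s, re.I
    ):
        dose = float(m["d"])
        k = _count(m["k"])
        times = [weeks(i) for i in range(k)]
        nominal = float(k)
    elif m := re.match(
        rf"^(?P<k>\w+) doses of (?P<d>{_NUM}) mg/kg on (?P<n>{_NUM}) days$", s, re.I
    ):
        dose = float(m["d"])
        k = _count(m["k"])
        span = days(float(m["n"]))
        times = [span * i / (k - 1) for i in range(k)] if k > 1 else [0.0]
        nominal = float(k)
    elif m := re.match(
        rf"^(?P<d>{_NUM}) mg/kg every (?P<g>\d+)(?:st|nd|rd|th) day "
        rf"\(total of (?P<k>\w+) doses\)$",
        s, re.I,
    ):
        dose = float(m["d"])
        k = _count(m["k"])
        times = [days(float(m["g"]) * i) for i in range(k)]
        nominal = float(k)
    elif m := re.match(
        rf"^(?P<d>{_NUM}) mg/kg on days? (?P<days>[\d., and]+)$", s, re.I
    ):
        dose = float(m["d"])
        times = [days(x) for x in _day_list(m["days"])]
        nominal = float(len(times))
    elif m := re.match(
        rf"^(?P<d>{_NUM}) mg/kg/2 weeks for (?P<w>{_NUM}) weeks?$", s, re.I
    ):
        dose = float(m["d"])
        dur = weeks(float(m["w"]))
        times = _rate_times(weeks(2), dur)
        nominal = float(m["w"]) / 2
    elif m := re.match(
        rf"^(?P<d>{_NUM}) mg/kg/week for (?P<w>{_NUM}) weeks?$", s, re.I
    ):
        dose = float(m["d"])
        dur = weeks(float(m["w"]))
        times = _rate_times(weeks(1), dur)
        nominal = float(m["w"])
    elif m := re.match(
        rf"^(?P<d>{_NUM}) mg/kg per injection twice a week for (?P<w>{_NUM}) weeks?$",
        s, re.I,
    ):
        dose = float(m["d"])
        dur = weeks(float(m["w"]))
        times = _rate_times(days(3.5), dur)
        nominal = 2 * float(m["w"])
    else:
        raise RegimenParseError(
            f"unrecognized regimen phrasing {text!r}; supply explicit "
            "injection_times instead"
        )

    kept = [t for t in times if t <= observation_span + 1e-9]
    if len(kept) < len(times):
        logger.warning(
            "regimen %r: %d of %d injections fall after the %.3g-day "
            "observation span and were truncated",
            text, len(times) - len(kept), len(times),
            observation_span / SECONDS_PER_DAY,
        )
    if not kept:
        raise RegimenParseError(
            f"regimen {text!r}: no injection falls inside the observation span"
        )

    from .regimen import classify_schedule_from  # local import avoids cycle

    return RegimenSpec(
        dose_per_injection=dose,
        injection_times=tuple(kept),
        schedule_class=classify_schedule_from(kept, dose),
        nominal_n_doses=nominal,
        source_text=text,
    )


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def load_treatment_table(path: str | Path) -> list[TreatmentRecord]:
    """Load and validate a treatment-table CSV; one record per row."""
    df = pd.read_csv(path, dtype={"regimen_text": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")
    records: list[TreatmentRecord] = []
    for idx, row in df.iterrows():
        try:
            records.append(
                TreatmentRecord(
                    treatment_id=int(row["treatment_id"]),
                    study_label=str(row["study_label"]),
                    cell_line=str(row["cell_line"]),
                    inoculum=float(row["inoculum"]),
                    dose_ug_per_ml=float(row["dose_ug_per_ml"]),
                    regimen_text=str(row["regimen_text"]),
                    control=parse_phase_string(str(row["control_phases"]), "control"),
                    treated=parse_phase_string(str(row["treated_phases"]), "treated"),
                )
            )
        except Exception as exc:
            raise TableValidationError(f"row {idx} (file line {idx + 2}): {exc}") from exc
    return records


def records_to_frame(records: Iterable[TreatmentRecord]) -> pd.DataFrame:
    """Serialize records back to the CSV schema (inverse of loading)."""
    rows = [
        {
            "treatment_id": r.treatment_id,
            "study_label": r.study_label,
            "cell_line": r.cell_line,
            "inoculum": r.inoculum,
            "dose_ug_per_ml": r.dose_ug_per_ml,
            "regimen_text": r.regimen_text,
            "control_phases": format_phase_string(r.control),
            "treated_phases": format_phase_string(r.treated),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def fixture_path() -> Path:
    """Path of the packaged 14-row docetaxel reference table."""
    return Path(str(resources.files("dtec").joinpath("data/table1.csv")))


def verify_fixture(path: str | Path | None = None) -> bool:
    """Check the packaged table against its transcription checksum."""
    p = Path(path) if path is not None else fixture_path()
    digest = hashlib.sha256(p.read_bytes()).hexdigest()
    return digest == FIXTURE_SHA256


def load_table1() -> list[TreatmentRecord]:
    """Load the packaged reference table (14 records)."""
    if not verify_fixture():
        raise TableValidationError(
            "packaged reference table failed its transcription checksum"
        )
    return load_treatment_table(fixture_path())


def write_report(
    results: Sequence[dict],
    out_dir: str | Path,
    provenance: dict | None = None,
) -> tuple[Path, Path]:
    """Write per-record results to ``results.csv`` + ``provenance.json``.

    ``results`` is a sequence of flat dicts (one per treatment). Returns
    the two paths written. Raises on empty results; nothing is written in
    that case.
    """
    if not results:
        raise TableValidationError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "results.csv"
    json_path = out / "provenance.json"
    pd.DataFrame(list(results)).to_csv(csv_path, index=False)
    from . import __version__

    doc = {"software": "dtec", "version": __version__, "n_records": len(results)}
    doc.update(provenance or {})
    json_path.write_text(json.dumps(doc, indent=2, default=str) + "\n")
    return csv_path, json_path
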
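"""End-to-end analysis: table -> kinetics -> energies -> model -> report.

Failures are per-record: a malformed row or an unparseable regimen is
logged and reported in the summary without aborting the cohort.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .dose_response import audit_dose_column, cluster_identical, fit_dose_energy
from .energetics import dose_energy, growth_energy, histologic_grade
from .errors import DtecError, RecordError
from .io_tables import load_treatment_table, parse_regimen, write_report
from .kinetics import effective_kinetics
from .models import CriterionMode, RunConfig, TreatmentRecord, VirtualStrategy
from .regimen import efficiency_profile
from .units import SECONDS_PER_DAY

logger = logging.getLogger(__name__)


def analyze_record(
    record: TreatmentRecord,
    strategy: VirtualStrategy | str = VirtualStrategy.HALF_LIFE_EQUIVALENCE,
) -> dict:
    """Flat per-record result row: kinetics, energies, regimen columns.

    Regimen-dependent columns are left None when the regimen text is not
    parseable; energy columns never depend on the regimen.
    """
    strategy = VirtualStrategy(strategy)
    kin_c = effective_kinetics(record.control, strategy)
    kin_t = effective_kinetics(record.treated, strategy)
    hg_c = histologic_grade(kin_c.t_d, record.inoculum)
    hg_t = histologic_grade(kin_t.t_d, record.inoculum)
    de = dose_energy(record, strategy)
    row: dict = {
        "treatment_id": record.treatment_id,
        "cell_line": record.cell_line,
        "inoculum": record.inoculum,
        "dose_ug_per_ml": record.dose_ug_per_ml,
        "control_rate_per_s": kin_c.rate,
        "control_t_d_s": kin_c.t_d,
        "control_t_d_days": kin_c.t_d / SECONDS_PER_DAY,
        "treated_rate_per_s": kin_t.rate,
        "treated_t_d_s": kin_t.t_d,
        "treated_t_d_days": kin_t.t_d / SECONDS_PER_DAY,
        "virtual_growth_used": de.virtual_used,
        "virtual_strategy": strategy.value,
        "control_e_per_cell_emad": hg_c.e_per_cell,
        "treated_e_per_cell_emad": hg_t.e_per_cell,
        "control_hg_emad": hg_c.hg_emad,
        "control_hg_mev": hg_c.hg_mev,
        "treated_hg_emad": hg_t.hg_emad,
        "treated_hg_mev": hg_t.hg_mev,
        "e_dose_emad": de.e_dose_emad,
        "e_dose_mev": de.e_dose_mev,
    }
    try:
        spec = parse_regimen(record.regimen_text, record.treated.total_duration)
        audit = audit_dose_column(record, spec)
        row.update(
            {
                "schedule_class": spec.schedule_class.value,
                "n_injections": len(spec.injection_times),
                "dose_per_injection_mg_kg": spec.dose_per_injection,
                "cumulative_mg_per_kg": spec.cumulative_mg_per_kg,
                "dose_audit_consistent": audit.consistent,
                "dose_audit_rel_dev": audit.rel_deviation,
            }
        )
        for mode in CriterionMode:
            assessment = efficiency_profile(record, spec, mode, strategy)
            row[f"efficiency_{mode.value}"] = assessment.verdict
    except DtecError as exc:
        logger.warning("record %d: regimen columns skipped: %s", record.treatment_id, exc)
        row.update(
            {
                "schedule_class": None,
                "n_injections": None,
                "dose_per_injection_mg_kg": None,
                "cumulative_mg_per_kg": None,
                "dose_audit_consistent": None,
                "dose_audit_rel_dev": None,
                "efficiency_to_next_dose": None,
                "efficiency_from_start": None,
                "regimen_note": str(exc),
            }
        )
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write report files to the output directory.

    Writes ``results.csv``, ``clusters.json``, ``model.json`` and
    ``provenance.json``; returns a summary dict with output paths, failures
    and headline numbers.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    records = load_treatment_table(config.input_path)
    if not records:
        raise DtecError("input table contains no records")

    rows: list[dict] = []
    failures: list[dict] = []
    for rec in records:
        try:
            rows.append(analyze_record(rec, config.virtual_strategy))
        except DtecError as exc:
            err = RecordError(rec.treatment_id, exc)
            logger.error("%s", err)
            failures.append({"treatment_id": rec.treatment_id, "error": str(exc)})
    if not rows:
        raise DtecError("no record could be analyzed")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    e_doses = [(r["treatment_id"], r["e_dose_emad"]) for r in rows]
    clusters = cluster_identical(e_doses, config.cluster_tol)
    clusters_doc = {
        "rel_tol": config.cluster_tol,
        "clusters": [
            [{"treatment_id": i, "e_dose_emad": v} for i, v in c] for c in clusters
        ],
    }
    (out / "clusters.json").write_text(json.dumps(clusters_doc, indent=2) + "\n")

    if config.fit_subset is not None:
        fit_rows = [r for r in rows if r["treatment_id"] in set(config.fit_subset)]
    else:
        fit_rows = rows
    points = [(r["dose_ug_per_ml"], r["e_dose_emad"]) for r in fit_rows]
    model_doc: dict = {"fit_subset": sorted(r["treatment_id"] for r in fit_rows)}
    try:
        model = fit_dose_energy(points, through_origin=config.through_origin)
        model_doc["model"] = model.model_dump()
        also_origin = fit_dose_energy(points, through_origin=True)
        model_doc["through_origin_model"] = also_origin.model_dump()
    except DtecError as exc:
        model = None
        model_doc["error"] = str(exc)
    (out / "model.json").write_text(json.dumps(model_doc, indent=2) + "\n")

    provenance = {
        "input_path": str(config.input_path),
        "virtual_strategy": config.virtual_strategy.value,
        "criterion_mode": config.criterion_mode.value,
        "cluster_tol": config.cluster_tol,
        "through_origin": config.through_origin,
        "fit_subset": list(config.fit_subset) if config.fit_subset else None,
        "failures": failures,
        "version": __version__,
    }
    csv_path, json_path = write_report(rows, out, provenance)

    return {
        "results_csv": str(csv_path),
        "provenance_json": str(json_path),
        "clusters_json": str(out / "clusters.json"),
        "model_json": str(out / "model.json"),
        "n_records": len(rows),
        "n_failures": len(failures),
        "failures": failures,
        "largest_cluster_size": len(clusters[0]) if clusters else 0,
        "model": model.model_dump() if model is not None else None,
    }
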
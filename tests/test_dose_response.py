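"""Dose-energy clustering, regression, prediction and the dose audit."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from dtec import (
    TableValidationError,
    audit_dose_column,
    cluster_identical,
    dose_energy,
    fit_dose_energy,
    parse_regimen,
    predict_response,
)
from dtec.models import SyntheticCohortConfig
from dtec.synthetic_data import simulate_cohort
from dtec.units import SECONDS_PER_DAY as D


def brute_force_clusters(values, rel_tol):
    """Transitive closure of the pairwise tolerance relation, by enumeration."""
    n = len(values)
    adj = {i: set() for i in range(n)}
    for i, j in itertools.combinations(range(n), 2):
        a, b = values[i][1], values[j][1]
        denom = max(abs(a), abs(b))
        if (a == b) if denom == 0 else abs(a - b) / denom <= rel_tol:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(frozenset(values[k][0] for k in comp))
    return set(comps)


class TestClustering:
    def test_small_example(self):
        clusters = cluster_identical([(1, 1.0), (2, 1.04), (3, 2.0)], 0.05)
        assert [sorted(i for i, _ in c) for c in clusters] == [[1, 2], [3]]

    def test_all_equal_is_one_cluster(self):
        clusters = cluster_identical([(i, 5.0) for i in range(4)], 0.05)
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_dose_840_cohort_largest_cluster_has_three(self, table1):
        e_doses = [
            (r.treatment_id, dose_energy(r).e_dose_emad)
            for r in table1
            if r.dose_ug_per_ml == 840
        ]
        assert len(e_doses) == 5
        clusters = cluster_identical(e_doses, 0.05)
        assert len(clusters[0]) == 3
        assert sorted(i for i, _ in clusters[0]) == [7, 8, 9]

    @pytest.mark.parametrize("tol", [0.02, 0.05, 0.10])
    def test_result_insensitive_to_tolerance(self, table1, tol):
        e_doses = [
            (r.treatment_id, dose_energy(r).e_dose_emad)
            for r in table1
            if r.dose_ug_per_ml == 840
        ]
        assert len(cluster_identical(e_doses, tol)[0]) == 3

    def test_bad_tolerance_rejected(self):
        with pytest.raises(TableValidationError):
            cluster_identical([(1, 1.0)], 0.6)

    @settings(derandomize=True, max_examples=150)
    @given(
        values=st.lists(st.floats(-100, 100, allow_nan=False), min_size=1, max_size=8),
        tol=st.floats(0.01, 0.49),
    )
    def test_agrees_with_brute_force_transitive_closure(self, values, tol):
        items = list(enumerate(values))
        got = {frozenset(i for i, _ in c) for c in cluster_identical(items, tol)}
        assert got == brute_force_clusters(items, tol)


class TestFit:
    def test_exact_line_recovered(self):
        pts = [(x, 100.0 * x) for x in (10, 20, 30, 40)]
        m = fit_dose_energy(pts)
        assert m.slope == pytest.approx(100.0, rel=1e-12)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert m.pearson_r == pytest.approx(1.0)

    def test_two_points_flagged_underdetermined(self):
        m = fit_dose_energy([(1.0, 2.0), (2.0, 5.0)])
        assert m.underdetermined
        assert abs(m.pearson_r) == pytest.approx(1.0)

    def test_equal_doses_need_through_origin(self):
        pts = [(840.0, 1.0e5), (840.0, 1.1e5)]
        with pytest.raises(TableValidationError):
            fit_dose_energy(pts)
        m = fit_dose_energy(pts, through_origin=True)
        assert m.slope == pytest.approx(1.05e5 / 840, rel=1e-12)
        assert m.pearson_r is None

    def test_noiseless_synthetic_cohort_recovers_generator(self):
        cfg = SyntheticCohortConfig(
            n_records=8,
            control_t_d=7 * D,
            inoculum=1e6,
            dose_grid=tuple(100.0 * i for i in range(1, 9)),
            true_slope=175.0,
            true_intercept=0.0,
            noise_sigma=0.0,
            observation_span=14 * D,
            seed=0,
        )
        records, _ = simulate_cohort(cfg)
        pts = [(r.dose_ug_per_ml, dose_energy(r).e_dose_emad) for r in records]
        m = fit_dose_energy(pts)
        assert m.slope == pytest.approx(175.0, rel=1e-9)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_noisy_cohort_recovers_slope_within_ten_percent(self):
        cfg = SyntheticCohortConfig(
            n_records=20,
            control_t_d=7 * D,
            inoculum=1e6,
            dose_grid=tuple(50.0 * i for i in range(1, 21)),
            true_slope=175.0,
            true_intercept=0.0,
            noise_sigma=0.05,
            observation_span=14 * D,
            seed=1,
        )
        records, _ = simulate_cohort(cfg)
        pts = [(r.dose_ug_per_ml, dose_energy(r).e_dose_emad) for r in records]
        m = fit_dose_energy(pts)
        assert m.slope == pytest.approx(175.0, rel=0.10)


class TestPredict:
    def test_zero_dose_through_origin_returns_control(self):
        m = fit_dose_energy([(10.0, 1000.0), (20.0, 2000.0)], through_origin=True)
        pred = predict_response(m, 7 * D, 1e6, 0.0)
        assert pred.t_d == pytest.approx(7 * D, rel=1e-9)
        assert pred.fold_change == pytest.approx(2.0, rel=1e-9)  # default horizon

    def test_energy_increment_doubling_the_doubling_time(self):
        from dtec import growth_energy

        control_t_d, inoculum = 7 * D, 1e6
        delta = growth_energy(2 * control_t_d) - growth_energy(control_t_d)
        # a model whose E_Dose at dose=1 equals inoculum*delta
        m = fit_dose_energy(
            [(1.0, inoculum * delta), (2.0, 2 * inoculum * delta)], through_origin=True
        )
        pred = predict_response(m, control_t_d, inoculum, 1.0)
        assert pred.t_d == pytest.approx(2 * control_t_d, rel=1e-9)

    def test_self_consistency_on_dose_840_cohort(self, by_id):
        # fit through origin on three same-dose records, then predict the
        # held-in record from its own control kinetics
        from dtec import effective_kinetics

        pts = [(by_id[i].dose_ug_per_ml, dose_energy(by_id[i]).e_dose_emad) for i in (7, 8, 9)]
        m = fit_dose_energy(pts, through_origin=True)
        rec = by_id[9]
        control_t_d = effective_kinetics(rec.control).t_d
        pred = predict_response(m, control_t_d, rec.inoculum, 840.0)
        observed = effective_kinetics(rec.treated).t_d
        assert pred.t_d == pytest.approx(observed, rel=0.05)

    def test_round_trip_inverse_of_dose_energy_single_record(self, by_id):
        from dtec import effective_kinetics

        rec = by_id[8]
        de = dose_energy(rec)
        m = fit_dose_energy(
            [(rec.dose_ug_per_ml, de.e_dose_emad)] * 2, through_origin=True
        )
        pred = predict_response(
            m, effective_kinetics(rec.control).t_d, rec.inoculum, rec.dose_ug_per_ml
        )
        assert pred.t_d == pytest.approx(effective_kinetics(rec.treated).t_d, rel=1e-9)


class TestDoseAudit:
    @pytest.mark.parametrize(
        "tid, cumulative",
        [(2, 14.0), (6, 23.2), (5, 20.0), (1, 5.25)],
    )
    def test_consistent_rows(self, by_id, tid, cumulative):
        rec = by_id[tid]
        spec = parse_regimen(rec.regimen_text, rec.treated.total_duration)
        entry = audit_dose_column(rec, spec)
        assert entry.cumulative_mg_per_kg == pytest.approx(cumulative)
        assert entry.consistent

    def test_row_12_flagged(self, by_id):
        rec = by_id[12]
        spec = parse_regimen(rec.regimen_text, rec.treated.total_duration)
        entry = audit_dose_column(rec, spec)
        assert entry.expected_ug_per_ml == pytest.approx(2520.0)
        assert not entry.consistent

    def test_thirteen_of_fourteen_rows_consistent(self, table1):
        flags = {}
        for rec in table1:
            spec = parse_regimen(rec.regimen_text, rec.treated.total_duration)
            flags[rec.treatment_id] = audit_dose_column(rec, spec).consistent
        assert sum(flags.values()) == 13
        assert not flags[12]
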
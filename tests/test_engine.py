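"""Step mechanics: arrivals, treatment, completion, admissions, overflow,
discharge, and the engine's global invariants."""

import numpy as np
import pytest

from wardflow import (DISCHARGE, ConfigError, EventKind, default_config,
                      run_simulation)
from wardflow.engine import (SimulationState, advance_step, apply_overflow,
                             apply_treatment, check_invariants)
from wardflow.patients import Patient, WardRequirement

from conftest import CONST_LOS, make_config


def events_of(result, kind):
    return [e for e in result.events if e.kind == kind]


class TestRunBounds:
    def test_null_run(self, one_ward_config):
        one_ward_config.settings.max_steps = 0
        result = run_simulation(one_ward_config, seed=1)
        assert result.steps_run == 0
        assert result.events == []
        assert all(series == [] for series in result.occupancy.values())

    def test_invalid_config_refused_with_violations(self, one_ward_config):
        one_ward_config.wards[0].capacity = -3
        with pytest.raises(ConfigError, match="capacity"):
            run_simulation(one_ward_config, seed=1)

    def test_max_patients_stops_arrivals_then_drains(self, one_ward_config):
        one_ward_config.settings.max_patients = 4
        one_ward_config.settings.max_steps = 50
        result = run_simulation(one_ward_config, seed=1)
        assert result.totals["arrived"] == 4
        assert result.totals["discharged"] == 4
        assert result.steps_run < 50  # stopped early once drained


class TestSingleWardChain:
    def test_one_step_turnover(self, one_ward_config):
        """1 arrival/step, constant 1-step stay: every admitted patient is
        discharged exactly one step after admission."""
        result = run_simulation(one_ward_config, seed=1, check=True)
        assert len(events_of(result, EventKind.ARRIVAL)) == 10
        assert len(events_of(result, EventKind.ADMIT)) == 10
        admit_step = {e.patient_id: e.step for e in events_of(result, EventKind.ADMIT)}
        discharges = events_of(result, EventKind.DISCHARGE)
        assert len(discharges) == 9  # the step-9 admission is still in bed at cutoff
        for e in discharges:
            assert e.step == admit_step[e.patient_id] + 1

    def test_discharge_frees_bed_same_step(self):
        """With capacity 1 the bed freed by a discharge (phase 3) is refilled
        from the queue in the same step (phase 4), so occupancy stays 1."""
        config = make_config([{"id": "ed", "is_entry": True, "capacity": 1}],
                             {"ed": {DISCHARGE: 1.0}},
                             arrivals_min=1, arrivals_max=1, max_steps=10)
        result = run_simulation(config, seed=1, check=True)
        assert result.occupancy["ed"] == [1] * 10

    def test_identical_seed_gives_identical_logs(self):
        config = default_config()
        config.settings.max_steps = 100
        a = run_simulation(config, seed=7)
        b = run_simulation(config, seed=7)
        assert a.events == b.events
        assert a.event_log_hash() == b.event_log_hash()
        assert run_simulation(config, seed=8).event_log_hash() != a.event_log_hash()


class TestTwoWardChain:
    def test_transfer_cascades_admission_same_step(self, chain_config):
        """A completed occupant transfers to the free next ward and the
        patient queueing behind it is admitted in the same step."""
        result = run_simulation(chain_config, seed=1, check=True)
        transfers = events_of(result, EventKind.TRANSFER)
        assert transfers, "expected ed->w1 transfers"
        admits_by_step = {e.step: e for e in events_of(result, EventKind.ADMIT)}
        # at every step where a transfer frees the single ed bed, a queued
        # patient is admitted into ed within that same step
        for t in transfers:
            assert t.from_node == "ed" and t.to_node == "w1"
            assert t.step in admits_by_step

    def test_realised_sequence_equals_generated_pathway(self, chain_config):
        result = run_simulation(chain_config, seed=3)
        for p in result.patients.values():
            if not p.discharged:
                continue
            visited = [to for (_, kind, to) in p.history
                       if kind in (EventKind.ADMIT, EventKind.TRANSFER, EventKind.RETURN)]
            assert visited == [r.ward_id for r in p.pathway]

    def test_blocked_patient_waits_in_current_bed(self):
        """Completed patient whose next ward is full keeps its current bed."""
        config = make_config(
            [{"id": "ed", "is_entry": True, "capacity": 3},
             {"id": "w1", "capacity": 1, "los_lambda": 30.0}],
            {"ed": {"w1": 1.0}, "w1": {DISCHARGE: 1.0}},
            arrivals_min=1, arrivals_max=1, max_steps=6, max_patients=3)
        result = run_simulation(config, seed=1, check=True)
        # only one patient fits w1; the others finish ed treatment but stay put
        assert len(events_of(result, EventKind.TRANSFER)) == 1
        assert max(result.occupancy["ed"]) >= 2
        assert max(result.occupancy["w1"]) == 1


def _patient(pid, wards, pos=0, ward=None, queued_for=None, diverted=False,
             los=1, need=0.0, entry_step=0):
    reqs = [WardRequirement(w, los_required=los, need_required=need) for w in wards]
    return Patient(id=pid, arrival_step=0, pathway=reqs, path_position=pos,
                   ward=ward, queued_for=queued_for, diverted=diverted,
                   queue_entry_step=entry_step)


class TestTreatment:
    def make_ward_state(self, needs, resources, policy="even"):
        config = make_config(
            [{"id": "w", "is_entry": True, "capacity": 10,
              "resources": resources, "resource_policy": policy}],
            {"w": {DISCHARGE: 1.0}})
        state = SimulationState.initial(config)
        for pid, need in needs.items():
            p = _patient(pid, ["w"], ward="w", los=5, need=need)
            state.patients[pid] = p
            state.wards["w"].occupants.append(pid)
        return state

    def test_even_split_with_capping(self):
        state = self.make_ward_state({1: 5.0, 2: 2.0}, resources=10)
        apply_treatment(state.wards["w"], state.patients)
        assert state.patients[1].current_requirement().need_remaining == 0
        assert state.patients[2].current_requirement().need_remaining == 0

    def test_zero_resources_only_time_passes(self):
        state = self.make_ward_state({1: 5.0}, resources=0)
        apply_treatment(state.wards["w"], state.patients)
        req = state.patients[1].current_requirement()
        assert req.need_remaining == 5.0
        assert req.los_remaining == 4

    def test_boarding_patient_untouched(self):
        state = self.make_ward_state({1: 5.0}, resources=100)
        boarder = _patient(2, ["elsewhere"], ward="w", queued_for="elsewhere",
                           diverted=True, los=3, need=9.0)
        state.patients[2] = boarder
        state.wards["w"].occupants.append(2)
        apply_treatment(state.wards["w"], state.patients)
        req = boarder.current_requirement()
        assert req.need_remaining == 9.0 and req.los_remaining == 3
        assert state.patients[1].current_requirement().need_remaining == 0


class TestOverflow:
    def overflow_config(self):
        return make_config(
            [{"id": "ed", "is_entry": True, "capacity": 2},
             {"id": "w1", "capacity": 1, "los_lambda": 50.0},
             {"id": "spare", "capacity": 1, "allow_overflow": True}],
            {"ed": {"w1": 1.0}, "w1": {DISCHARGE: 1.0},
             "spare": {DISCHARGE: 1.0}},
            arrivals_min=1, arrivals_max=1, max_steps=8)

    def test_no_overflow_flag_means_no_divert(self):
        config = self.overflow_config()
        for w in config.wards:
            w.allow_overflow = False
        result = run_simulation(config, seed=1, check=True)
        assert events_of(result, EventKind.DIVERT) == []

    def test_divert_fills_overflow_bed_and_refills_source(self):
        """Two blocked patients in a full ward with one overflow bed free:
        exactly one diversion, and the freed bed is taken from the queue."""
        config = self.overflow_config()
        state = SimulationState.initial(config)
        # ed full with two completed patients blocked on w1; two more queueing
        for pid in (1, 2):
            p = _patient(pid, ["ed", "w1"], pos=1, ward="ed", queued_for="w1",
                         entry_step=0)
            state.patients[pid] = p
            state.wards["ed"].occupants.append(pid)
            state.wards["w1"].queue.append(pid)
        for pid in (3, 4):
            p = _patient(pid, ["ed"], queued_for="ed", entry_step=1)
            state.patients[pid] = p
            state.wards["ed"].queue.append(pid)
        state.arrived, state.step = 4, 2
        apply_overflow(state)
        diverts = [e for e in state.events if e.kind == EventKind.DIVERT]
        admits = [e for e in state.events if e.kind == EventKind.ADMIT]
        assert len(diverts) == 1 and diverts[0].to_node == "spare"
        assert len(admits) == 1 and admits[0].to_node == "ed"
        assert state.patients[diverts[0].patient_id].diverted is True
        assert state.wards["spare"].occupants == [diverts[0].patient_id]
        check_invariants(state)

    def test_diverted_patient_returns_and_resumes_pathway(self):
        config = self.overflow_config()
        config.settings.max_steps = 80
        config.settings.max_patients = 6
        result = run_simulation(config, seed=5, check=True)
        diverted_ids = {e.patient_id for e in events_of(result, EventKind.DIVERT)}
        assert diverted_ids, "scenario should produce boarding"
        returns = {e.patient_id for e in events_of(result, EventKind.RETURN)}
        for pid in diverted_ids:
            p = result.patients[pid]
            if p.discharged:
                assert pid in returns
                assert p.diverted is False
                visited = [to for (_, kind, to) in p.history
                           if kind in (EventKind.ADMIT, EventKind.TRANSFER,
                                       EventKind.RETURN)]
                assert visited == [r.ward_id for r in p.pathway]

    def test_no_discharge_while_diverted_or_unfinished(self):
        config = self.overflow_config()
        config.settings.max_steps = 80
        result = run_simulation(config, seed=5)
        for p in result.patients.values():
            if p.discharged:
                assert not p.diverted
                assert all(r.need_remaining <= 1e-9 and r.los_remaining == 0
                           for r in p.pathway)


class TestGlobalInvariants:
    def test_conservation_and_capacity_default_run(self):
        config = default_config()
        config.settings.max_steps = 200
        result = run_simulation(config, seed=13, check=True)
        for ward in config.wards:
            assert all(0 <= occ <= ward.capacity for occ in result.occupancy[ward.id])
            assert len(result.occupancy[ward.id]) == result.steps_run

    def test_realised_pathways_on_default_run(self):
        config = default_config()
        config.settings.max_steps = 300
        result = run_simulation(config, seed=21)
        discharged = [p for p in result.patients.values() if p.discharged]
        assert discharged
        for p in discharged:
            visited = [to for (_, kind, to) in p.history
                       if kind in (EventKind.ADMIT, EventKind.TRANSFER, EventKind.RETURN)]
            assert visited == [r.ward_id for r in p.pathway]

    def test_ample_capacity_gives_closed_form_durations(self):
        """With effectively unlimited beds and resources, queueing vanishes and
        every patient's hospital time equals the sum of its required stays."""
        config = make_config(
            [{"id": "ed", "is_entry": True, "capacity": 10**6,
              "resources": 10**9, "los_lambda": 3.0, "need_lambda": 5.0},
             {"id": "w1", "capacity": 10**6, "resources": 10**9,
              "los_lambda": 4.0, "need_lambda": 5.0}],
            {"ed": {"w1": 0.5, DISCHARGE: 0.5}, "w1": {DISCHARGE: 1.0}},
            arrivals_min=2, arrivals_max=4, max_steps=300, max_patients=200)
        result = run_simulation(config, seed=9, check=True)
        assert result.totals["discharged"] == 200
        for p in result.patients.values():
            assert p.discharge_step - p.arrival_step == p.total_los_required()

    def test_history_steps_non_decreasing(self):
        config = default_config()
        config.settings.max_steps = 150
        result = run_simulation(config, seed=2)
        for p in result.patients.values():
            steps = [s for (s, _, _) in p.history]
            assert steps == sorted(steps)
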
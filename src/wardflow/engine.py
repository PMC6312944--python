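"""The discrete-event core: advance a simulated hospital step by step.

Each step (one hour by default) executes a fixed sequence of sub-phases:

1. **arrivals** — new patients are generated and join the entry ward's
   (unbounded) queue;
2. **treatment** — every ward divides its per-step resource pool among
   its actively treated occupants under its resource policy, decrements
   need counters by the allocation and length-of-stay counters by one;
3. **completion** — occupants whose need and stay are both exhausted
   either advance to the next required ward's queue (remaining in their
   current bed until admitted elsewhere) or are discharged, freeing the
   bed immediately;
4. **admissions** — each ward fills free beds from its queue under its
   queue policy; admitted patients vacate any bed they were blocking;
5. **overflow** — wards that are full *and* have patients queueing may
   divert completed-but-blocked occupants into overflow-enabled wards
   with free beds ("boarding"); each freed bed is immediately offered to
   the ward's own queue;
6. **snapshot** — per-ward occupancy and queue lengths are recorded.

The fixed intra-step order lets a bed freed by a transfer or discharge
be refilled within the same step.  Boarding patients occupy a bed but
receive no treatment and make no length-of-stay progress; they must
return to their required pathway before discharge.  Wards are always
processed in configuration-file order and queue ties break by
(queue_entry_step, patient id), so a run is a pure function of
(config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import (DISCHARGE, EXTERNAL, ConfigError, HospitalConfig,
                     WardConfig, validate_config)
from .patients import EventKind, Patient, generate_patient, sample_arrivals
from .policies import QueueEntry, allocate_resources, order_queue

_NEED_TOL = 1e-9


@dataclass(frozen=True)
class Event:
    """One movement or arrival in the event log."""

    step: int
    patient_id: int
    kind: EventKind
    from_node: str
    to_node: str

    def __post_init__(self) -> None:
        if self.from_node == self.to_node:
            raise ValueError(f"degenerate event {self.kind} {self.from_node}->{self.to_node}")


@dataclass
class WardState:
    """Live state of one ward: who occupies its beds and who is queueing."""

    config: WardConfig
    occupants: list[int] = field(default_factory=list)
    queue: list[int] = field(default_factory=list)

    @property
    def free_beds(self) -> int:
        return self.config.capacity - len(self.occupants)


@dataclass
class SimulationState:
    """Mutable state of a run in progress."""

    config: HospitalConfig
    step: int = 0
    wards: dict[str, WardState] = field(default_factory=dict)
    patients: dict[int, Patient] = field(default_factory=dict)
    next_patient_id: int = 0
    arrived: int = 0
    admitted: int = 0
    discharged: int = 0
    events: list[Event] = field(default_factory=list)
    occupancy: dict[str, list[int]] = field(default_factory=dict)
    queue_lengths: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def initial(cls, config: HospitalConfig) -> "SimulationState":
        state = cls(config=config)
        for ward in config.wards:
            state.wards[ward.id] = WardState(config=ward)
            state.occupancy[ward.id] = []
            state.queue_lengths[ward.id] = []
        return state

    @property
    def entry_id(self) -> str:
        return self.config.entry_ward().id

    def in_system(self) -> int:
        return self.arrived - self.discharged

    def _record(self, kind: EventKind, patient: Patient, from_node: str, to_node: str) -> None:
        self.events.append(Event(self.step, patient.id, kind, from_node, to_node))
        patient.history.append((self.step, kind, to_node))


@dataclass
class SimulationResult:
    """A completed run: full event log, per-step series and final patients."""

    config: HospitalConfig
    seed: int
    events: list[Event]
    occupancy: dict[str, list[int]]
    queue_lengths: dict[str, list[int]]
    patients: dict[int, Patient]
    steps_run: int
    totals: dict[str, int]

    def event_log_hash(self) -> str:
        """SHA-256 of the canonical event log (regression / determinism checks)."""
        h = hashlib.sha256()
        for e in self.events:
            h.update(f"{e.step},{e.patient_id},{e.kind.value},{e.from_node},{e.to_node}\n".encode())
        return h.hexdigest()


def _do_arrivals(state: SimulationState, rng: np.random.Generator) -> None:
    settings = state.config.settings
    n = sample_arrivals(settings, rng)
    if settings.max_patients is not None:
        n = max(0, min(n, settings.max_patients - state.arrived))
    entry = state.entry_id
    for _ in range(n):
        patient = generate_patient(state.config, state.step, state.next_patient_id, rng)
        state.patients[patient.id] = patient
        state.next_patient_id += 1
        state.arrived += 1
        state.wards[entry].queue.append(patient.id)
        state.events.append(Event(state.step, patient.id, EventKind.ARRIVAL, EXTERNAL, entry))


def apply_treatment(ward_state: WardState, patients: dict[int, Patient],
                    rng: Optional[np.random.Generator] = None) -> None:
    """Allocate one step of the ward's resources and advance stay counters.

    Only actively treated occupants take part: boarding (diverted)
    patients and completed-but-blocked patients (already queueing for
    their next ward) receive no allocation and make no progress.  Unused
    resources do not carry over.
    """
    active = [patients[pid] for pid in ward_state.occupants
              if patients[pid].queued_for is None and not patients[pid].diverted]
    needs = {p.id: p.current_requirement().need_remaining
             for p in active if p.current_requirement().need_remaining > _NEED_TOL}
    if needs:
        alloc = allocate_resources(needs, ward_state.config.resources,
                                   ward_state.config.resource_policy)
        for p in active:
            given = alloc.get(p.id, 0.0)
            if given:
                req = p.current_requirement()
                req.need_remaining = max(0.0, req.need_remaining - given)
    for p in active:
        req = p.current_requirement()
        req.los_remaining = max(0, req.los_remaining - 1)


def process_completion(state: SimulationState) -> None:
    """Move finished occupants on: discharge, or queue for the next ward.

    A patient is finished when both counters of the current requirement
    are exhausted (treatment needs resources *and* time).  Discharge
    frees the bed at once; a patient heading to another ward keeps the
    current bed until admitted there (or diverted).
    """
    for ward_id in state.config.ward_ids():
        ward_state = state.wards[ward_id]
        for pid in list(ward_state.occupants):
            p = state.patients[pid]
            if p.queued_for is not None or p.diverted:
                continue
            req = p.current_requirement()
            if req.need_remaining > _NEED_TOL or req.los_remaining > 0:
                continue
            if p.path_position == len(p.pathway) - 1:
                ward_state.occupants.remove(pid)
                p.path_position += 1
                p.ward = None
                p.discharge_step = state.step
                state.discharged += 1
                state._record(EventKind.DISCHARGE, p, ward_id, DISCHARGE)
            else:
                p.path_position += 1
                nxt = p.pathway[p.path_position].ward_id
                p.queued_for = nxt
                p.queue_entry_step = state.step
                state.wards[nxt].queue.append(pid)


def _admit(state: SimulationState, pid: int, ward_id: str) -> None:
    """Move a queued patient into a free bed of ``ward_id``, vacating any
    bed it was blocking, and record the appropriate event kind."""
    p = state.patients[pid]
    ward_state = state.wards[ward_id]
    old = p.ward
    if old is None:
        kind = EventKind.ADMIT
        from_node = EXTERNAL
        state.admitted += 1
    else:
        state.wards[old].occupants.remove(pid)
        kind = EventKind.RETURN if p.diverted else EventKind.TRANSFER
        from_node = old
    ward_state.queue.remove(pid)
    ward_state.occupants.append(pid)
    p.ward = ward_id
    p.queued_for = None
    p.diverted = False
    state._record(kind, p, from_node, ward_id)


def _queue_entries(state: SimulationState, ward_state: WardState) -> list[QueueEntry]:
    entries = []
    for pid in ward_state.queue:
        p = state.patients[pid]
        entries.append(QueueEntry(pid, p.queue_entry_step,
                                  p.pathway[p.path_position].need_required))
    return entries


def _admit_queues(state: SimulationState) -> None:
    # Wards are served in configuration order; because an admission can
    # vacate a bed in an already-processed ward (a blocked patient moving
    # on), passes repeat until no admission happens, so every bed freed
    # this step can be refilled this step.
    while True:
        any_admitted = False
        for ward_id in state.config.ward_ids():
            ward_state = state.wards[ward_id]
            free = ward_state.free_beds
            if free <= 0 or not ward_state.queue:
                continue
            ordered = order_queue(_queue_entries(state, ward_state),
                                  ward_state.config.queue_policy)
            for entry in ordered[:free]:
                _admit(state, entry.patient_id, ward_id)
                any_admitted = True
        if not any_admitted:
            break


def apply_overflow(state: SimulationState) -> None:
    """Divert blocked occupants out of full wards that have a queue.

    While a ward is at capacity with a non-empty queue, its
    completed-but-blocked occupants are boarded, one at a time, into the
    first overflow-enabled ward (configuration order) with a free bed —
    never the ward they are actually queueing for, where a free bed
    means a plain admission instead.  Each freed bed is offered to the
    ward's own queue immediately.
    """
    for ward_id in state.config.ward_ids():
        ward_state = state.wards[ward_id]
        while ward_state.free_beds == 0 and ward_state.queue and ward_state.config.capacity > 0:
            blocked = sorted(
                (pid for pid in ward_state.occupants if state.patients[pid].queued_for is not None),
                key=lambda pid: (state.patients[pid].queue_entry_step, pid),
            )
            moved = False
            for pid in blocked:
                p = state.patients[pid]
                dest = next(
                    (w for w in state.config.ward_ids()
                     if w != ward_id and w != p.queued_for
                     and state.wards[w].config.allow_overflow
                     and state.wards[w].free_beds > 0),
                    None,
                )
                if dest is None:
                    continue
                ward_state.occupants.remove(pid)
                state.wards[dest].occupants.append(pid)
                p.ward = dest
                p.diverted = True  # stays in queued_for's queue, original entry step
                state._record(EventKind.DIVERT, p, ward_id, dest)
                moved = True
                break
            if not moved:
                break
            ordered = order_queue(_queue_entries(state, ward_state), ward_state.config.queue_policy)
            if ordered:
                _admit(state, ordered[0].patient_id, ward_id)


def _snapshot(state: SimulationState) -> None:
    for ward_id, ward_state in state.wards.items():
        state.occupancy[ward_id].append(len(ward_state.occupants))
        state.queue_lengths[ward_id].append(len(ward_state.queue))


def check_invariants(state: SimulationState) -> None:
    """Assert patient conservation and capacity bounds at a step boundary."""
    in_beds = sum(len(w.occupants) for w in state.wards.values())
    # queue members already occupying a bed (blocked/boarding patients whose
    # pathway revisits the entry ward) are counted with the beds
    entry_queue = sum(1 for pid in state.wards[state.entry_id].queue
                      if state.patients[pid].ward is None)
    assert state.arrived == state.discharged + in_beds + entry_queue, (
        f"conservation violated at step {state.step}: arrived={state.arrived} "
        f"discharged={state.discharged} in_beds={in_beds} entry_queue={entry_queue}")
    seen: set[int] = set()
    for ward_id, ward_state in state.wards.items():
        assert len(ward_state.occupants) <= ward_state.config.capacity, (
            f"ward {ward_id} over capacity at step {state.step}")
        for pid in ward_state.occupants:
            assert pid not in seen, f"patient {pid} occupies two beds at step {state.step}"
            seen.add(pid)


def advance_step(state: SimulationState, rng: np.random.Generator) -> SimulationState:
    """Execute one full simulation step (all six sub-phases) in place."""
    _do_arrivals(state, rng)
    for ward_id in state.config.ward_ids():
        apply_treatment(state.wards[ward_id], state.patients, rng)
    process_completion(state)
    _admit_queues(state)
    apply_overflow(state)
    _snapshot(state)
    state.step += 1
    return state


def run_simulation(config: HospitalConfig, seed: int, *,
                   validate: bool = True, check: bool = False) -> SimulationResult:
    """Run a hospital to completion and return the full result.

    The run advances until ``max_steps`` is reached, or — when
    ``max_patients`` is set — until arrivals have stopped and every
    in-flight patient has been discharged.  Identical (config, seed)
    pairs produce identical results.  ``check=True`` asserts the
    conservation and capacity invariants after every step.
    """
    if validate:
        violations = validate_config(config)
        if violations:
            raise ConfigError("refusing to run invalid config", violations)
    rng = np.random.default_rng(seed)
    state = SimulationState.initial(config)
    settings = config.settings
    while state.step < settings.max_steps:
        if (settings.max_patients is not None
                and state.arrived >= settings.max_patients
                and state.in_system() == 0):
            break
        advance_step(state, rng)
        if check:
            check_invariants(state)
    return SimulationResult(
        config=config,
        seed=seed,
        events=state.events,
        occupancy=state.occupancy,
        queue_lengths=state.queue_lengths,
        patients=state.patients,
        steps_run=state.step,
        totals={"arrived": state.arrived, "admitted": state.admitted,
                "discharged": state.discharged},
    )
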
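"""Virtual patient generation.

Each patient carries a required pathway — an ordered sequence of wards
produced by a random walk on the hospital's transition probability graph,
starting at the entry ward and ending when the absorbing DISCHARGE node
is drawn.  For every ward on the pathway the patient needs a Poisson
length of stay (clamped to at least one step, so every visit occupies a
bed) and a Poisson total resource need, both with per-ward means.

All randomness flows through a single ``numpy.random.Generator`` owned
by the run; nothing here seeds itself, so a run is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .config import DISCHARGE, HospitalConfig, SimulationSettings, TransitionGraph


class EventKind(str, Enum):
    ARRIVAL = "ARRIVAL"      # patient joins the entry ward's queue
    ADMIT = "ADMIT"          # entry queue -> bed in the entry ward
    TRANSFER = "TRANSFER"    # bed -> bed along the required pathway
    DIVERT = "DIVERT"        # bed -> bed in an off-pathway overflow ward (boarding)
    RETURN = "RETURN"        # boarding bed -> bed in the required ward
    DISCHARGE = "DISCHARGE"  # bed -> out of hospital


@dataclass
class WardRequirement:
    """What one pathway ward demands of a patient: a stay and a need."""

    ward_id: str
    los_required: int
    need_required: float
    los_remaining: int = -1
    need_remaining: float = -1.0

    def __post_init__(self) -> None:
        if self.los_remaining < 0:
            self.los_remaining = self.los_required
        if self.need_remaining < 0:
            self.need_remaining = float(self.need_required)


@dataclass
class Patient:
    """A virtual patient: required pathway, progress through it, and history.

    ``path_position`` indexes the requirement currently being worked on
    (or queued for); it equals ``len(pathway)`` once discharged.
    ``ward`` is the ward whose bed the patient physically occupies (None
    while in the entry queue or after discharge); ``queued_for`` is the
    ward the patient is waiting to enter, if any.  ``diverted`` marks a
    boarding patient occupying an off-pathway bed.
    """

    id: int
    arrival_step: int
    pathway: list[WardRequirement]
    path_position: int = 0
    ward: Optional[str] = None
    queued_for: Optional[str] = None
    queue_entry_step: int = -1
    diverted: bool = False
    discharge_step: Optional[int] = None
    history: list[tuple[int, EventKind, str]] = field(default_factory=list)

    @property
    def discharged(self) -> bool:
        return self.path_position >= len(self.pathway)

    def current_requirement(self) -> WardRequirement:
        return self.pathway[self.path_position]

    def total_los_required(self) -> int:
        return sum(r.los_required for r in self.pathway)


def sample_arrivals(settings: SimulationSettings, rng: np.random.Generator) -> int:
    """Number of patients arriving this step: uniform on [arrivals_min, arrivals_max]."""
    lo, hi = settings.arrivals_min, settings.arrivals_max
    if lo == hi:
        return lo
    return int(rng.integers(lo, hi + 1))


def generate_pathway(graph: TransitionGraph, entry: str, max_len: int,
                     rng: np.random.Generator) -> list[str]:
    """Random-walk a required ward sequence starting at ``entry``.

    Successors are drawn from each ward's outgoing probability row; the
    walk ends when DISCHARGE is drawn (DISCHARGE itself is not included)
    or is truncated after ``max_len`` wards, in which case the patient is
    simply discharged after the last generated ward.
    """
    pathway = [entry]
    current = entry
    while len(pathway) < max_len:
        row = graph.successors(current)
        targets = list(row)
        probs = np.fromiter((row[t] for t in targets), dtype=float, count=len(targets))
        nxt = targets[int(rng.choice(len(targets), p=probs / probs.sum()))]
        if nxt == DISCHARGE:
            break
        pathway.append(nxt)
        current = nxt
    return pathway


def generate_patient(config: HospitalConfig, arrival_step: int, patient_id: int,
                     rng: np.random.Generator) -> Patient:
    """Create one patient arriving at the entry ward at ``arrival_step``.

    Per pathway ward, ``los_required = max(1, Poisson(los_lambda))`` and
    ``need_required = Poisson(need_lambda)``; the two draws are
    independent.  The patient starts in the entry ward's queue.
    """
    entry = config.entry_ward().id
    walk = generate_pathway(config.graph, entry, config.settings.max_pathway_length, rng)
    requirements = []
    for ward_id in walk:
        ward = config.ward(ward_id)
        los = max(1, int(rng.poisson(ward.los_lambda)))
        need = float(rng.poisson(ward.need_lambda)) if ward.need_lambda > 0 else 0.0
        requirements.append(WardRequirement(ward_id=ward_id, los_required=los, need_required=need))
    patient = Patient(
        id=patient_id,
        arrival_step=arrival_step,
        pathway=requirements,
        queued_for=entry,
        queue_entry_step=arrival_step,
    )
    patient.history.append((arrival_step, EventKind.ARRIVAL, entry))
    return patient
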
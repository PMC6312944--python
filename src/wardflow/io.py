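"""File formats: event-log / occupancy CSVs, report JSON, run manifests.

All CSVs are UTF-8, comma-separated, with a header row and LF line
endings.  Schemas:

``events.csv``      step, patient_id, kind, from_node, to_node
``occupancy.csv``   step, ward, occupancy, queue_length
``network_edges.csv``  from, to, count

A saved event log plus the configuration is sufficient to regenerate
the analysis report exactly: :func:`reconstruct_result` replays the
movement events to rebuild per-step occupancy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx
import pandas as pd

from .analysis import AnalysisReport
from .config import HospitalConfig, dumps
from .engine import Event, SimulationResult
from .patients import EventKind

EVENT_COLUMNS = ["step", "patient_id", "kind", "from_node", "to_node"]
OCCUPANCY_COLUMNS = ["step", "ward", "occupancy", "queue_length"]


class SchemaError(ValueError):
    """A CSV file does not conform to its documented schema."""


def events_to_frame(events: list[Event]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.step, e.patient_id, e.kind.value, e.from_node, e.to_node) for e in events],
        columns=EVENT_COLUMNS,
    )


def write_events_csv(events: list[Event], path: Path) -> None:
    events_to_frame(events).to_csv(path, index=False, lineterminator="\n")


def read_events_csv(path: Path) -> list[Event]:
    try:
        frame = pd.read_csv(path, dtype={"step": int, "patient_id": int,
                                         "kind": str, "from_node": str, "to_node": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise SchemaError(f"unreadable event log {path}: {exc}") from exc
    if list(frame.columns) != EVENT_COLUMNS:
        raise SchemaError(f"event log columns {list(frame.columns)} != {EVENT_COLUMNS}")
    events = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            kind = EventKind(row.kind)
        except ValueError:
            raise SchemaError(f"unknown event kind {row.kind!r} at row {i}") from None
        events.append(Event(int(row.step), int(row.patient_id), kind,
                            str(row.from_node), str(row.to_node)))
    return events


def occupancy_to_frame(result: SimulationResult) -> pd.DataFrame:
    rows = []
    for ward_id in result.config.ward_ids():
        occ = result.occupancy[ward_id]
        queues = result.queue_lengths.get(ward_id, [0] * len(occ))
        for step, (o, q) in enumerate(zip(occ, queues)):
            rows.append((step, ward_id, o, q))
    rows.sort()
    return pd.DataFrame(rows, columns=OCCUPANCY_COLUMNS)


def write_occupancy_csv(result: SimulationResult, path: Path) -> None:
    occupancy_to_frame(result).to_csv(path, index=False, lineterminator="\n")


def read_occupancy_csv(path: Path) -> tuple[dict[str, list[int]], dict[str, list[int]], int]:
    """Return (occupancy, queue_lengths, steps_run) from an occupancy CSV."""
    try:
        frame = pd.read_csv(path)
    except (ValueError, pd.errors.ParserError) as exc:
        raise SchemaError(f"unreadable occupancy file {path}: {exc}") from exc
    if list(frame.columns) != OCCUPANCY_COLUMNS:
        raise SchemaError(f"occupancy columns {list(frame.columns)} != {OCCUPANCY_COLUMNS}")
    occupancy: dict[str, list[int]] = {}
    queues: dict[str, list[int]] = {}
    for row in frame.sort_values(["ward", "step"]).itertuples(index=False):
        occupancy.setdefault(row.ward, []).append(int(row.occupancy))
        queues.setdefault(row.ward, []).append(int(row.queue_length))
    steps_run = int(frame["step"].max()) + 1 if len(frame) else 0
    return occupancy, queues, steps_run


def write_network_csv(net: nx.DiGraph, path: Path) -> None:
    rows = sorted((u, v, d["count"]) for u, v, d in net.edges(data=True))
    pd.DataFrame(rows, columns=["from", "to", "count"]).to_csv(
        path, index=False, lineterminator="\n")


def write_network_graphml(net: nx.DiGraph, path: Path) -> None:
    nx.write_graphml(net, path)


def write_report_json(report: AnalysisReport, path: Path) -> None:
    path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")


def reconstruct_result(config: HospitalConfig, events: list[Event],
                       steps_run: int | None = None,
                       occupancy: dict[str, list[int]] | None = None,
                       queue_lengths: dict[str, list[int]] | None = None) -> SimulationResult:
    """Rebuild a :class:`SimulationResult` from a saved event log.

    If occupancy snapshots are not supplied they are replayed from the
    movement events (bed occupancy is fully determined by the log); the
    entry queue length is likewise replayed, other queue series default
    to zero since intra-queue membership is not evented.  ``steps_run``
    defaults to one past the last event step.
    """
    if steps_run is None:
        steps_run = (max(e.step for e in events) + 1) if events else 0
    if occupancy is None:
        occupancy = {w: [] for w in config.ward_ids()}
        queue_lengths = {w: [] for w in config.ward_ids()}
        entry = config.entry_ward().id
        loc: dict[int, str] = {}
        waiting_entry: set[int] = set()
        by_step: dict[int, list[Event]] = {}
        for e in events:
            by_step.setdefault(e.step, []).append(e)
        for step in range(steps_run):
            for e in by_step.get(step, ()):
                if e.kind == EventKind.ARRIVAL:
                    waiting_entry.add(e.patient_id)
                elif e.kind == EventKind.ADMIT:
                    waiting_entry.discard(e.patient_id)
                    loc[e.patient_id] = e.to_node
                elif e.kind in (EventKind.TRANSFER, EventKind.DIVERT, EventKind.RETURN):
                    loc[e.patient_id] = e.to_node
                elif e.kind == EventKind.DISCHARGE:
                    loc.pop(e.patient_id, None)
            counts = {w: 0 for w in occupancy}
            for ward in loc.values():
                counts[ward] += 1
            for w in occupancy:
                occupancy[w].append(counts[w])
                queue_lengths[w].append(len(waiting_entry) if w == entry else 0)
    totals = {
        "arrived": sum(1 for e in events if e.kind == EventKind.ARRIVAL),
        "admitted": sum(1 for e in events if e.kind == EventKind.ADMIT),
        "discharged": sum(1 for e in events if e.kind == EventKind.DISCHARGE),
    }
    return SimulationResult(config=config, seed=config.settings.seed, events=events,
                            occupancy=occupancy, queue_lengths=queue_lengths or {},
                            patients={}, steps_run=steps_run, totals=totals)


@dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    config_path: str
    config_sha256: str
    seed: int
    package_version: str
    created: str
    outputs: list[str]

    @classmethod
    def create(cls, config: HospitalConfig, config_path: str, seed: int,
               outputs: list[str]) -> "RunManifest":
        from . import __version__
        digest = hashlib.sha256(dumps(config).encode()).hexdigest()
        return cls(config_path=config_path, config_sha256=digest, seed=seed,
                   package_version=__version__,
                   created=datetime.now(timezone.utc).isoformat(),
                   outputs=outputs)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(vars(self), indent=2) + "\n")
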
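"""Post-run analysis: waiting times, occupancy, flow networks, journeys, costs.

Everything here is computed from a run's event log, configuration and
occupancy snapshots, never from engine internals, so the same report can
be regenerated later from saved CSV logs (see :mod:`wardflow.io`).

The analysis bundle mirrors what a hospital manager would ask of a run:

* performance against the A&E waiting-time target, with the full
  waiting-time distribution;
* ward occupancy and utilisation over time;
* the realised patient-flow network between wards, with degree,
  betweenness and closeness centralities to locate bottlenecks;
* the most common patient journeys with their duration statistics and
  the path-length distribution;
* headline statistics: operating cost, patient counts, unique journeys.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Optional

import networkx as nx

from .config import DISCHARGE, EXTERNAL
from .engine import SimulationResult
from .patients import EventKind

_MOVEMENT_KINDS = (EventKind.ADMIT, EventKind.TRANSFER, EventKind.DIVERT, EventKind.RETURN)
_EXIT_KINDS = (EventKind.TRANSFER, EventKind.DIVERT, EventKind.RETURN, EventKind.DISCHARGE)
#: Required-pathway admissions (boarding via DIVERT excluded).
_PATHWAY_KINDS = (EventKind.ADMIT, EventKind.TRANSFER, EventKind.RETURN)


@dataclass
class WaitingReport:
    """Per-patient A&E waits and performance against the target.

    A patient's wait is the step of its first exit from the entry ward
    (transfer, diversion or discharge) minus its arrival step — the
    arrival-to-admission/transfer/discharge semantics of the UK 4-hour
    target.  Patients still inside (or queueing for) the entry ward when
    the run ends are censored: excluded from the percentage, counted
    separately.
    """

    waits: dict[int, int]
    target: int
    censored: int
    pct_within_target: Optional[float]

    @property
    def measured(self) -> int:
        return len(self.waits)

    def histogram(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for w in sorted(self.waits.values()):
            counts[w] = counts.get(w, 0) + 1
        return counts


@dataclass
class NodeStatistics:
    """Centrality bundle for one node of the flow network."""

    in_degree: int
    out_degree: int
    weighted_in_degree: float
    weighted_out_degree: float
    betweenness: float
    closeness: float


@dataclass
class JourneyStats:
    """Duration summary for one unique path through the hospital."""

    path: tuple[str, ...]
    count: int
    min_duration: int
    max_duration: int
    median_duration: float


@dataclass
class AnalysisReport:
    """The full analysis bundle for one completed run."""

    basic: dict
    waiting: WaitingReport
    occupancy: dict[str, dict[str, list]]
    network_edges: dict[tuple[str, str], int]
    network_nodes: dict[str, NodeStatistics]
    journeys: list[JourneyStats]
    path_length_distribution: dict[int, int]

    def to_dict(self) -> dict:
        """JSON-serialisable form (stable key order for reproducible files)."""
        return {
            "basic": self.basic,
            "waiting": {
                "target": self.waiting.target,
                "measured": self.waiting.measured,
                "censored": self.waiting.censored,
                "pct_within_target": self.waiting.pct_within_target,
                "waits": {str(pid): w for pid, w in sorted(self.waiting.waits.items())},
                "histogram": {str(k): v for k, v in sorted(self.waiting.histogram().items())},
            },
            "occupancy": self.occupancy,
            "network": {
                "edges": [{"from": u, "to": v, "count": c}
                          for (u, v), c in sorted(self.network_edges.items())],
                "nodes": {node: vars(stats) for node, stats in sorted(self.network_nodes.items())},
            },
            "journeys": [
                {"path": list(j.path), "count": j.count, "min_duration": j.min_duration,
                 "max_duration": j.max_duration, "median_duration": j.median_duration}
                for j in self.journeys
            ],
            "path_length_distribution": {str(k): v
                                         for k, v in sorted(self.path_length_distribution.items())},
        }


def waiting_times(result: SimulationResult, target: Optional[int] = None) -> WaitingReport:
    """Compute per-patient A&E waits and the percentage within target."""
    if target is None:
        target = result.config.settings.waiting_time_target
    entry = result.config.entry_ward().id
    arrivals: dict[int, int] = {}
    exits: dict[int, int] = {}
    for e in result.events:
        if e.kind == EventKind.ARRIVAL:
            arrivals[e.patient_id] = e.step
        elif e.kind in _EXIT_KINDS and e.from_node == entry and e.patient_id not in exits:
            exits[e.patient_id] = e.step
    waits = {pid: exits[pid] - arrivals[pid] for pid in exits if pid in arrivals}
    censored = len(arrivals) - len(waits)
    if waits:
        pct = 100.0 * sum(1 for w in waits.values() if w <= target) / len(waits)
    else:
        pct = None
    return WaitingReport(waits=waits, target=target, censored=censored, pct_within_target=pct)


def occupancy_series(result: SimulationResult) -> dict[str, dict[str, list]]:
    """Per-ward occupancy snapshots plus derived utilisation (occupancy/capacity)."""
    out: dict[str, dict[str, list]] = {}
    for ward in result.config.wards:
        series = result.occupancy[ward.id]
        util = [occ / ward.capacity if ward.capacity else 0.0 for occ in series]
        out[ward.id] = {"occupancy": list(series), "utilisation": util}
    return out


def build_flow_network(result: SimulationResult) -> nx.DiGraph:
    """Realised patient-transfer network.

    One edge-count increment per movement event: ``EXTERNAL -> entry``
    per admission, ward-to-ward per transfer/diversion/return, and
    ``ward -> DISCHARGE`` per discharge.  All configured wards appear as
    nodes even if no flow touched them.
    """
    g = nx.DiGraph()
    g.add_nodes_from(result.config.ward_ids())
    g.add_node(EXTERNAL)
    g.add_node(DISCHARGE)
    for e in result.events:
        if e.kind in _MOVEMENT_KINDS or e.kind == EventKind.DISCHARGE:
            if g.has_edge(e.from_node, e.to_node):
                g[e.from_node][e.to_node]["count"] += 1
            else:
                g.add_edge(e.from_node, e.to_node, count=1)
    return g


def _connected_pair_counts(g: nx.DiGraph) -> dict[str, int]:
    """For each node v: number of ordered pairs (s, t), s != t != v, with a path s->t."""
    desc = {n: nx.descendants(g, n) for n in g}
    pairs = [(s, t) for s in g for t in desc[s]]
    counts = {}
    for v in g:
        counts[v] = sum(1 for s, t in pairs if s != v and t != v)
    return counts


def network_statistics(net: nx.DiGraph) -> dict[str, NodeStatistics]:
    """Degree, betweenness and closeness for every node of a flow network.

    Degrees are reported both unweighted (edge counts) and weighted
    (summed transfer counts).  Betweenness is directed shortest-path
    betweenness on the edge-presence graph, normalised per node by the
    number of connected ordered pairs not involving that node, so values
    lie in [0, 1] even on disconnected flow graphs.  Closeness is the
    harmonic closeness of incoming distances, normalised by (n - 1).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("no flow recorded")
    n = net.number_of_nodes()
    raw_btw = nx.betweenness_centrality(net, normalized=False)
    denom = _connected_pair_counts(net)
    harmonic = nx.harmonic_centrality(net)
    stats: dict[str, NodeStatistics] = {}
    for node in net:
        stats[node] = NodeStatistics(
            in_degree=net.in_degree(node),
            out_degree=net.out_degree(node),
            weighted_in_degree=float(net.in_degree(node, weight="count")),
            weighted_out_degree=float(net.out_degree(node, weight="count")),
            betweenness=raw_btw[node] / denom[node] if denom[node] else 0.0,
            closeness=harmonic[node] / (n - 1) if n > 1 else 0.0,
        )
    return stats


def journey_summary(result: SimulationResult) -> tuple[list[JourneyStats], dict[int, int]]:
    """Unique completed journeys with duration statistics, plus the
    path-length distribution.

    A journey is the ordered sequence of *required* wards a discharged
    patient actually visited (boarding wards are excluded); its duration
    is discharge step minus arrival step.  Journeys are sorted by
    descending count, ties alphabetically.  Patients still in hospital
    at run end are excluded.
    """
    arrivals: dict[int, int] = {}
    paths: dict[int, list[str]] = {}
    durations: dict[tuple[str, ...], list[int]] = {}
    for e in result.events:
        if e.kind == EventKind.ARRIVAL:
            arrivals[e.patient_id] = e.step
            paths[e.patient_id] = []
        elif e.kind in _PATHWAY_KINDS:
            paths[e.patient_id].append(e.to_node)
        elif e.kind == EventKind.DISCHARGE:
            key = tuple(paths[e.patient_id])
            durations.setdefault(key, []).append(e.step - arrivals[e.patient_id])
    journeys = [
        JourneyStats(path=path, count=len(ds), min_duration=min(ds),
                     max_duration=max(ds), median_duration=float(median(ds)))
        for path, ds in durations.items()
    ]
    journeys.sort(key=lambda j: (-j.count, j.path))
    lengths: dict[int, int] = {}
    for j in journeys:
        lengths[len(j.path)] = lengths.get(len(j.path), 0) + j.count
    return journeys, lengths


def basic_statistics(result: SimulationResult,
                     waiting: Optional[WaitingReport] = None,
                     journeys: Optional[list[JourneyStats]] = None) -> dict:
    """Headline numbers: operating cost, target performance, patient counts.

    The operating cost charges every ward for its full resource pool and
    bed stock at every step (capacity is paid for whether occupied or
    not): ``steps_run * sum_w(resources_w * resource_unit_cost +
    capacity_w * bed_unit_cost)``.
    """
    s = result.config.settings
    per_step = sum(w.resources * s.resource_unit_cost + w.capacity * s.bed_unit_cost
                   for w in result.config.wards)
    if waiting is None:
        waiting = waiting_times(result)
    if journeys is None:
        journeys, _ = journey_summary(result)
    n_arrived = sum(1 for e in result.events if e.kind == EventKind.ARRIVAL)
    n_discharged = sum(1 for e in result.events if e.kind == EventKind.DISCHARGE)
    return {
        "operating_cost": result.steps_run * per_step,
        "pct_within_target": waiting.pct_within_target,
        "n_patients": n_arrived,
        "n_discharged": n_discharged,
        "n_unique_journeys": len(journeys),
        "waiting_censored": waiting.censored,
    }


def analyze(result: SimulationResult) -> AnalysisReport:
    """Assemble the full analysis bundle for a completed run."""
    waiting = waiting_times(result)
    journeys, lengths = journey_summary(result)
    net = build_flow_network(result)
    nodes = network_statistics(net) if net.number_of_nodes() else {}
    edges = {(u, v): d["count"] for u, v, d in net.edges(data=True)}
    return AnalysisReport(
        basic=basic_statistics(result, waiting, journeys),
        waiting=waiting,
        occupancy=occupancy_series(result),
        network_edges=edges,
        network_nodes=nodes,
        journeys=journeys,
        path_length_distribution=lengths,
    )
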
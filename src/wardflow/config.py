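"""Hospital configuration: schema, validation, JSON (de)serialisation.

A hospital is described by a single JSON document with three sections:

``wards``
    a list of ward objects (beds, per-step resources, Poisson means for
    length of stay and resource need, queue/resource/overflow policies,
    and an ``is_entry`` flag marking the emergency department);
``graph``
    the ward-transition probability graph: for every ward, a row of
    outgoing probabilities over other wards and the reserved absorbing
    node ``"DISCHARGE"``, summing to one;
``settings``
    run bounds (maximum steps and/or patients), the per-step arrival
    bounds, the A&E waiting-time target (steps; one step is one hour by
    default), unit costs, and the random-walk length cap.

Validation never raises on semantic problems: :func:`validate_config`
returns a list of violations, each naming the offending JSON path and
the rule it breaks, so a front end can show them all at once.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import networkx as nx
from pydantic import BaseModel, ConfigDict, ValidationError

from . import policies

#: Reserved node id for the absorbing discharge state of the transition graph.
DISCHARGE = "DISCHARGE"
#: Pseudo-node for the world outside the hospital (used in event logs / flow networks).
EXTERNAL = "EXTERNAL"

_WARD_ID_RE = re.compile(r"^[a-z][a-z0-9_]*$")


class ConfigError(ValueError):
    """Raised when a configuration document cannot be loaded or is invalid."""

    def __init__(self, message: str, violations: Optional[list["Violation"]] = None):
        self.violations = violations or []
        if self.violations:
            message = message + "\n" + "\n".join(f"  - {v}" for v in self.violations)
        super().__init__(message)


@dataclass(frozen=True)
class Violation:
    """A single validation failure: where (JSON path) and which rule."""

    path: str
    rule: str

    def __str__(self) -> str:
        return f"{self.path}: {self.rule}"


class WardConfig(BaseModel):
    """One ward: its beds, per-step resource pool, stay/need distributions
    and management policies."""

    model_config = ConfigDict(extra="forbid")

    id: str
    name: str = ""
    capacity: int = 0
    resources: float = 0.0
    los_lambda: float = 1.0
    need_lambda: float = 0.0
    queue_policy: str = "chronological"
    resource_policy: str = "even"
    allow_overflow: bool = False
    is_entry: bool = False

    def model_post_init(self, _ctx) -> None:
        if not self.name:
            self.name = self.id.replace("_", " ").title()


class TransitionGraph(BaseModel):
    """Ward-transition probability graph.

    ``weights[from_ward][to_node]`` is the probability that a patient's
    random-walk pathway moves from ``from_ward`` to ``to_node`` (another
    ward or ``DISCHARGE``).  Each ward's row must sum to 1.
    """

    model_config = ConfigDict(extra="forbid")

    weights: dict[str, dict[str, float]]

    def successors(self, ward_id: str) -> dict[str, float]:
        return self.weights.get(ward_id, {})

    def node_ids(self) -> list[str]:
        nodes = list(self.weights)
        for row in self.weights.values():
            for target in row:
                if target not in nodes and target != DISCHARGE:
                    nodes.append(target)
        return nodes


class SimulationSettings(BaseModel):
    """Run bounds, arrival strain, waiting-time target and unit costs.

    ``max_steps`` is a hard step cap; ``max_patients`` (optional) stops
    arrivals once that many patients have entered, after which the run
    continues (still bounded by ``max_steps``) until in-flight patients
    drain.  Arrivals per step are uniform on
    ``[arrivals_min, arrivals_max]``.  One step corresponds to one hour
    by default, so the default ``waiting_time_target`` of 4 encodes the
    UK 4-hour A&E target.
    """

    model_config = ConfigDict(extra="forbid")

    max_steps: int = 720
    max_patients: Optional[int] = None
    arrivals_min: int = 0
    arrivals_max: int = 4
    waiting_time_target: int = 4
    seed: int = 0
    resource_unit_cost: float = 1.0
    bed_unit_cost: float = 2.0
    max_pathway_length: int = 20


class HospitalConfig(BaseModel):
    """Complete parameterisation of a simulated hospital and its run."""

    model_config = ConfigDict(extra="forbid")

    wards: list[WardConfig]
    graph: TransitionGraph
    settings: SimulationSettings = SimulationSettings()

    def ward_ids(self) -> list[str]:
        return [w.id for w in self.wards]

    def ward(self, ward_id: str) -> WardConfig:
        for w in self.wards:
            if w.id == ward_id:
                return w
        raise KeyError(ward_id)

    def entry_ward(self) -> WardConfig:
        entries = [w for w in self.wards if w.is_entry]
        if len(entries) != 1:
            raise ConfigError(f"expected exactly one entry ward, found {len(entries)}")
        return entries[0]


def validate_config(config: HospitalConfig) -> list[Violation]:
    """Check every semantic invariant; return all violations (empty list if valid)."""
    out: list[Violation] = []
    ids = config.ward_ids()

    seen: set[str] = set()
    for i, ward in enumerate(config.wards):
        path = f"wards[{i}]"
        if ward.id in seen:
            out.append(Violation(f"{path}.id", f"duplicate ward id {ward.id!r}"))
        seen.add(ward.id)
        if not _WARD_ID_RE.match(ward.id):
            out.append(Violation(f"{path}.id", f"ward id {ward.id!r} must be lowercase snake_case"))
        if ward.id in (DISCHARGE, EXTERNAL) or ward.id.lower() in ("discharge", "external"):
            out.append(Violation(f"{path}.id", f"{ward.id!r} is a reserved node id"))
        if ward.capacity < 0:
            out.append(Violation(f"{path}.capacity", "capacity must be >= 0"))
        if ward.resources < 0:
            out.append(Violation(f"{path}.resources", "resources must be >= 0"))
        if ward.los_lambda <= 0:
            out.append(Violation(f"{path}.los_lambda", "los_lambda must be > 0"))
        if ward.need_lambda < 0:
            out.append(Violation(f"{path}.need_lambda", "need_lambda must be >= 0"))
        try:
            policies.get_policy("queue", ward.queue_policy)
        except policies.PolicyError:
            out.append(Violation(f"{path}.queue_policy", f"unknown queue policy {ward.queue_policy!r}"))
        try:
            policies.get_policy("resource", ward.resource_policy)
        except policies.PolicyError:
            out.append(Violation(f"{path}.resource_policy", f"unknown resource policy {ward.resource_policy!r}"))

    n_entry = sum(1 for w in config.wards if w.is_entry)
    if n_entry != 1:
        out.append(Violation("wards", f"exactly one entry ward required, found {n_entry}"))

    id_set = set(ids)
    for from_id, row in config.graph.weights.items():
        gpath = f"graph.weights.{from_id}"
        if from_id == DISCHARGE:
            out.append(Violation(gpath, "DISCHARGE must have no outgoing edges"))
            continue
        if from_id not in id_set:
            out.append(Violation(gpath, f"unknown ward id {from_id!r}"))
            continue
        total = 0.0
        for to_id, p in row.items():
            if to_id != DISCHARGE and to_id not in id_set:
                out.append(Violation(f"{gpath}.{to_id}", f"unknown ward id {to_id!r}"))
            if to_id == from_id:
                out.append(Violation(f"{gpath}.{to_id}", "self-loop transitions are not allowed"))
            if not 0.0 <= p <= 1.0:
                out.append(Violation(f"{gpath}.{to_id}", f"probability {p} outside [0, 1]"))
            total += p
        if row and abs(total - 1.0) > 1e-9:
            out.append(Violation(gpath, f"outgoing probabilities of ward {from_id!r} sum to {total:.6g}, expected 1"))
    for ward_id in ids:
        row = config.graph.weights.get(ward_id)
        if not row:
            out.append(Violation(f"graph.weights.{ward_id}", f"ward {ward_id!r} has no outgoing probability row"))

    # every ward must be able to reach DISCHARGE (no absorbing cycle among wards)
    g = nx.DiGraph()
    g.add_node(DISCHARGE)
    for from_id, row in config.graph.weights.items():
        for to_id, p in row.items():
            if p > 0:
                g.add_edge(from_id, to_id)
    reaches = nx.ancestors(g, DISCHARGE) if g.has_node(DISCHARGE) else set()
    for ward_id in ids:
        if ward_id in config.graph.weights and ward_id not in reaches:
            out.append(Violation(f"graph.weights.{ward_id}", f"ward {ward_id!r} cannot reach DISCHARGE"))

    s = config.settings
    if s.max_steps < 0:
        out.append(Violation("settings.max_steps", "max_steps must be >= 0"))
    if s.max_patients is not None and s.max_patients < 0:
        out.append(Violation("settings.max_patients", "max_patients must be >= 0"))
    if s.arrivals_min < 0:
        out.append(Violation("settings.arrivals_min", "arrivals_min must be >= 0"))
    if s.arrivals_max < s.arrivals_min:
        out.append(Violation("settings.arrivals_max", "arrivals_max must be >= arrivals_min"))
    if s.waiting_time_target < 1:
        out.append(Violation("settings.waiting_time_target", "waiting_time_target must be >= 1"))
    if s.max_pathway_length < 1:
        out.append(Violation("settings.max_pathway_length", "max_pathway_length must be >= 1"))
    if s.resource_unit_cost < 0:
        out.append(Violation("settings.resource_unit_cost", "resource_unit_cost must be >= 0"))
    if s.bed_unit_cost < 0:
        out.append(Violation("settings.bed_unit_cost", "bed_unit_cost must be >= 0"))

    return out


def _strip_comment_keys(obj: Any) -> Any:
    """Drop keys starting with '_' so config files can carry inline notes."""
    if isinstance(obj, dict):
        return {k: _strip_comment_keys(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, list):
        return [_strip_comment_keys(v) for v in obj]
    return obj


def load_config(source: str | Path | dict) -> HospitalConfig:
    """Load and validate a hospital configuration.

    ``source`` may be a path to a JSON file, a JSON string, or an
    already-parsed dict.  Keys beginning with ``_`` are treated as
    comments and ignored.  Raises :class:`ConfigError` with the full
    list of violations if the document is malformed or invalid.
    """
    if isinstance(source, dict):
        raw: Any = source
    else:
        text = None
        if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("{")):
            path = Path(source)
            if not path.exists():
                raise ConfigError(f"config file not found: {path}")
            text = path.read_text()
        else:
            text = source
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed config: {exc}") from exc

    raw = _strip_comment_keys(raw)
    try:
        config = HospitalConfig.model_validate(raw)
    except ValidationError as exc:
        violations = [
            Violation(".".join(str(p) for p in err["loc"]) or "<root>", err["msg"])
            for err in exc.errors()
        ]
        raise ConfigError("invalid config", violations) from exc

    violations = validate_config(config)
    if violations:
        raise ConfigError("invalid config", violations)
    return config


def serialise(config: HospitalConfig) -> dict:
    """Serialise a config to a plain JSON-compatible dict (round-trips through load_config)."""
    return config.model_dump()


def dumps(config: HospitalConfig, indent: int = 2) -> str:
    return json.dumps(serialise(config), indent=indent)
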
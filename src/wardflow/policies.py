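"""Queue-ordering and resource-division policies behind a plugin registry.

Each ward makes two repeated decisions: which waiting patient to admit
into a free bed (queue policy) and how to split its per-step resource
pool among admitted patients (resource policy).  Three presets of each
are built in; arbitrary policies can be registered by name and then
referenced from a hospital configuration file.

Policy contracts
----------------
queue policy
    ``fn(entries: list[QueueEntry]) -> list[QueueEntry]`` returning a
    permutation of its input; the first entry is admitted first.
resource policy
    ``fn(needs: dict[int, float], total: float) -> dict[int, float]``
    returning per-patient allocations with ``0 <= alloc[i] <= needs[i]``
    and ``sum(alloc) <= total``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class QueueEntry:
    """A patient waiting for admission to a ward.

    ``need_at_destination`` is the patient's total resource need in the
    ward being queued for — the quantity the admitting ward can observe.
    """

    patient_id: int
    queue_entry_step: int
    need_at_destination: float


class PolicyError(ValueError):
    """Unknown or duplicate policy name."""


def _tiebreak(entry: QueueEntry) -> tuple[int, int]:
    return (entry.queue_entry_step, entry.patient_id)


def _queue_chronological(entries: list[QueueEntry]) -> list[QueueEntry]:
    return sorted(entries, key=_tiebreak)


def _queue_high_need_first(entries: list[QueueEntry]) -> list[QueueEntry]:
    return sorted(entries, key=lambda e: (-e.need_at_destination, *_tiebreak(e)))


def _queue_low_need_first(entries: list[QueueEntry]) -> list[QueueEntry]:
    return sorted(entries, key=lambda e: (e.need_at_destination, *_tiebreak(e)))


def _check_allocation_inputs(needs: dict[int, float], total: float) -> None:
    if total < 0:
        raise ValueError(f"resource pool must be non-negative, got {total}")
    for pid, need in needs.items():
        if need < 0:
            raise ValueError(f"negative need {need} for patient {pid}")


def _alloc_even(needs: dict[int, float], total: float) -> dict[int, float]:
    # Iterative water-filling: split the pool equally among patients with
    # unmet need, cap at need, redistribute the surplus, repeat.
    alloc = {pid: 0.0 for pid in needs}
    pool = float(total)
    active = [pid for pid in sorted(needs) if needs[pid] > 0]
    while pool > 1e-12 and active:
        share = pool / len(active)
        capped = False
        next_active = []
        for pid in active:
            gap = needs[pid] - alloc[pid]
            give = min(share, gap)
            alloc[pid] += give
            pool -= give
            if give < share - 1e-12:
                capped = True
            if needs[pid] - alloc[pid] > 1e-12:
                next_active.append(pid)
        active = next_active
        if not capped:
            break
    return alloc


def _alloc_greedy(needs: dict[int, float], total: float, descending: bool) -> dict[int, float]:
    alloc = {pid: 0.0 for pid in needs}
    pool = float(total)
    order = sorted(needs, key=lambda pid: (-needs[pid] if descending else needs[pid], pid))
    for pid in order:
        if pool <= 0:
            break
        give = min(needs[pid], pool)
        alloc[pid] = give
        pool -= give
    return alloc


def _alloc_high_need(needs: dict[int, float], total: float) -> dict[int, float]:
    return _alloc_greedy(needs, total, descending=True)


def _alloc_low_need(needs: dict[int, float], total: float) -> dict[int, float]:
    return _alloc_greedy(needs, total, descending=False)


_QUEUE_POLICIES = {
    "chronological": _queue_chronological,
    "high_need_first": _queue_high_need_first,
    "low_need_first": _queue_low_need_first,
}

_RESOURCE_POLICIES = {
    "even": _alloc_even,
    "high_need": _alloc_high_need,
    "low_need": _alloc_low_need,
}

_REGISTRIES = {"queue": _QUEUE_POLICIES, "resource": _RESOURCE_POLICIES}


def register_policy(kind: str, name: str, fn) -> None:
    """Register a custom policy so configs can reference it by name.

    ``kind`` is ``"queue"`` or ``"resource"``; ``fn`` must satisfy the
    corresponding contract documented at module level.  Re-registering
    an existing name raises :class:`PolicyError`.
    """
    if kind not in _REGISTRIES:
        raise PolicyError(f"unknown policy kind {kind!r}; expected 'queue' or 'resource'")
    registry = _REGISTRIES[kind]
    if name in registry:
        raise PolicyError(f"{kind} policy {name!r} is already registered")
    registry[name] = fn


def unregister_policy(kind: str, name: str) -> None:
    """Remove a previously registered custom policy (presets cannot be removed)."""
    if name in ("chronological", "high_need_first", "low_need_first", "even", "high_need", "low_need"):
        raise PolicyError(f"preset policy {name!r} cannot be removed")
    _REGISTRIES[kind].pop(name, None)


def list_policies(kind: str) -> list[str]:
    if kind not in _REGISTRIES:
        raise PolicyError(f"unknown policy kind {kind!r}")
    return list(_REGISTRIES[kind])


def get_policy(kind: str, name: str):
    try:
        return _REGISTRIES[kind][name]
    except KeyError:
        raise PolicyError(f"unknown {kind} policy {name!r}; registered: {list_policies(kind)}") from None


def order_queue(entries: list[QueueEntry], policy: str) -> list[QueueEntry]:
    """Order a ward's admission queue under a named queue policy.

    ``chronological`` admits in arrival-to-queue order (FIFO);
    ``high_need_first`` admits the patient with the largest resource need
    at the destination ward first; ``low_need_first`` the smallest.  All
    presets break ties by (queue_entry_step, patient_id) ascending, so
    the ordering is a deterministic permutation of the input.
    """
    return get_policy("queue", policy)(list(entries))


def allocate_resources(needs: dict[int, float], total: float, policy: str) -> dict[int, float]:
    """Divide a ward's per-step resource pool among its patients.

    ``even`` water-fills: the pool is split equally among patients with
    unmet need, capped at each patient's need, and any surplus is
    redistributed until the pool or all needs are exhausted.
    ``high_need`` serves patients in descending order of need, each up to
    its full need; ``low_need`` serves ascending.  Ties break by patient
    id.  Allocations are real-valued, never exceed need, and never
    overspend the pool.
    """
    _check_allocation_inputs(needs, total)
    return get_policy("resource", policy)(dict(needs), total)
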
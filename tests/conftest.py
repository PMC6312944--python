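"""Shared fixtures: tiny hand-traceable hospitals and random config factories."""

from __future__ import annotations

import numpy as np
import pytest

from wardflow import DISCHARGE, HospitalConfig

# A Poisson mean this small makes max(1, Poisson(lam)) a constant 1-step stay,
# which is what the hand-traceable configs below rely on.
CONST_LOS = 1e-9


def make_config(wards: list[dict], weights: dict[str, dict[str, float]],
                **settings) -> HospitalConfig:
    """Build a validated-shape config from terse ward dicts."""
    full_wards = []
    for w in wards:
        ward = {"los_lambda": CONST_LOS, "need_lambda": 0.0, "resources": 0.0,
                "capacity": 1, **w}
        full_wards.append(ward)
    doc = {"wards": full_wards, "graph": {"weights": weights},
           "settings": {"max_steps": 10, "arrivals_min": 0, "arrivals_max": 0,
                        **settings}}
    return HospitalConfig.model_validate(doc)


@pytest.fixture
def one_ward_config() -> HospitalConfig:
    """Smallest useful hospital: one entry ward straight to discharge,
    constant 1-step stay, no resource needs, one arrival per step."""
    return make_config(
        [{"id": "ed", "is_entry": True, "capacity": 5}],
        {"ed": {DISCHARGE: 1.0}},
        arrivals_min=1, arrivals_max=1, max_steps=10,
    )


@pytest.fixture
def chain_config() -> HospitalConfig:
    """Deterministic two-ward chain ed -> w1 -> discharge.

    w1 is listed before ed so that a bed freed by an ed->w1 transfer can
    be refilled from ed's queue within the same step.
    """
    return make_config(
        [{"id": "w1", "capacity": 1},
         {"id": "ed", "is_entry": True, "capacity": 1}],
        {"ed": {"w1": 1.0}, "w1": {DISCHARGE: 1.0}},
        arrivals_min=1, arrivals_max=1, max_steps=12,
    )


def make_random_config(rng: np.random.Generator, max_steps: int = 200) -> HospitalConfig:
    """A small random but always-valid hospital for property tests.

    2-4 wards; every ward keeps at least 5% probability of direct
    discharge so pathways stay short and DISCHARGE is always reachable.
    """
    n = int(rng.integers(2, 5))
    ids = [f"w{i}" for i in range(n)]
    wards = []
    for i, wid in enumerate(ids):
        wards.append({
            "id": wid,
            "is_entry": i == 0,
            "capacity": int(rng.integers(1, 11)),
            "resources": float(rng.integers(0, 21)),
            "los_lambda": float(rng.uniform(0.5, 5.0)),
            "need_lambda": float(rng.integers(0, 6)),
            "queue_policy": str(rng.choice(["chronological", "high_need_first", "low_need_first"])),
            "resource_policy": str(rng.choice(["even", "high_need", "low_need"])),
            "allow_overflow": bool(rng.random() < 0.4),
        })
    weights = {}
    for wid in ids:
        targets = [t for t in ids if t != wid] + [DISCHARGE]
        raw = rng.uniform(0.0, 1.0, size=len(targets))
        raw[-1] = max(raw[-1], 0.05)
        raw /= raw.sum()
        weights[wid] = {t: float(p) for t, p in zip(targets, raw)}
    arrivals_max = int(rng.integers(0, 4))
    return make_config(wards, weights, max_steps=max_steps,
                       arrivals_min=0, arrivals_max=arrivals_max)
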
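"""The shipped default hospital: an emergency department plus seven
specialist wards with a combined capacity of 220 beds.

The transition matrix, per-ward Poisson means and arrival bounds are
calibrated inventions (documented in docs/methods.md): they are chosen
to produce a typical range of patient journeys and, over a 720-step run
(one simulated month at hourly steps), roughly 1400 admissions.  Users
are expected to edit a copy of this configuration rather than trust any
single number in it as empirical.

Calibration sketch:

* arrivals per step uniform on [0, 4] (mean 2), so a 720-step run sees
  about 1440 arrivals, nearly all of which are admitted;
* the emergency department turns patients over quickly (mean stay about
  2 h) and routes 45% straight to discharge, 30% to acute assessment and
  the remainder thinly across the specialist wards;
* specialist wards discharge 85-100% of their patients directly, with
  small inter-ward probabilities, giving mostly short journeys and an
  occasional long multi-ward one;
* steady-state offered load per ward (inflow rate x mean stay) sits well
  below capacity, so the default hospital is comfortable — management
  experiments start from a system that works and can be stressed.
"""

from __future__ import annotations

from .config import DISCHARGE, HospitalConfig

_DEFAULT = {
    "wards": [
        # id, capacity, per-step resources, los_lambda (h), need_lambda
        {"id": "ed", "name": "Emergency Department", "capacity": 20, "resources": 60,
         "los_lambda": 2, "need_lambda": 4, "is_entry": True},
        {"id": "acute_assessment", "capacity": 40, "resources": 50,
         "los_lambda": 24, "need_lambda": 24},
        {"id": "surgery", "capacity": 25, "resources": 40,
         "los_lambda": 48, "need_lambda": 96, "allow_overflow": True},
        {"id": "cardiology", "capacity": 30, "resources": 30,
         "los_lambda": 72, "need_lambda": 72},
        {"id": "general_medicine", "capacity": 45, "resources": 40,
         "los_lambda": 96, "need_lambda": 96},
        {"id": "orthopaedics", "capacity": 20, "resources": 20,
         "los_lambda": 72, "need_lambda": 72},
        {"id": "respiratory", "capacity": 20, "resources": 20,
         "los_lambda": 72, "need_lambda": 72},
        {"id": "geriatrics", "capacity": 20, "resources": 15,
         "los_lambda": 96, "need_lambda": 48},
    ],
    "graph": {
        "weights": {
            "ed": {"acute_assessment": 0.30, DISCHARGE: 0.45, "surgery": 0.06,
                   "cardiology": 0.05, "general_medicine": 0.05, "orthopaedics": 0.04,
                   "respiratory": 0.03, "geriatrics": 0.02},
            "acute_assessment": {DISCHARGE: 0.55, "general_medicine": 0.15,
                                 "cardiology": 0.08, "respiratory": 0.08,
                                 "geriatrics": 0.08, "surgery": 0.03, "orthopaedics": 0.03},
            "surgery": {DISCHARGE: 0.85, "orthopaedics": 0.05,
                        "general_medicine": 0.05, "geriatrics": 0.05},
            "cardiology": {DISCHARGE: 0.90, "general_medicine": 0.05, "geriatrics": 0.05},
            "general_medicine": {DISCHARGE: 0.90, "geriatrics": 0.10},
            "orthopaedics": {DISCHARGE: 0.90, "general_medicine": 0.05, "geriatrics": 0.05},
            "respiratory": {DISCHARGE: 0.90, "general_medicine": 0.05, "geriatrics": 0.05},
            "geriatrics": {DISCHARGE: 1.0},
        }
    },
    "settings": {
        "max_steps": 720,          # one month of hourly steps
        "max_patients": None,
        "arrivals_min": 0,
        "arrivals_max": 4,         # uniform arrivals, mean 2 per step
        "waiting_time_target": 4,  # the UK 4-hour A&E target
        "seed": 0,
        "resource_unit_cost": 1.0,
        "bed_unit_cost": 2.0,
        "max_pathway_length": 20,
    },
}


def default_config() -> HospitalConfig:
    """Return a fresh copy of the default 220-bed, 8-ward hospital."""
    return HospitalConfig.model_validate(_DEFAULT)
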
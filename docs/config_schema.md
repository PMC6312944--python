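# Hospital configuration schema

One JSON document with three sections. Keys beginning with `_` are
comments and ignored by the loader. `wardflow init-config --out f.json`
emits the default hospital as a starting point; validation reports
*all* problems at once, each with its JSON path.

```json
{
  "wards": [
    {
      "id": "ed",
      "name": "Emergency Department",
      "capacity": 20,
      "resources": 60,
      "los_lambda": 2,
      "need_lambda": 4,
      "queue_policy": "chronological",
      "resource_policy": "even",
      "allow_overflow": false,
      "is_entry": true
    },
    {"id": "acute_assessment", "capacity": 40, "resources": 50,
     "los_lambda": 24, "need_lambda": 24}
  ],
  "graph": {
    "weights": {
      "ed": {"acute_assessment": 0.55, "DISCHARGE": 0.45},
      "acute_assessment": {"DISCHARGE": 1.0}
    }
  },
  "settings": {
    "max_steps": 720,
    "max_patients": null,
    "arrivals_min": 0,
    "arrivals_max": 4,
    "waiting_time_target": 4,
    "seed": 0,
    "resource_unit_cost": 1.0,
    "bed_unit_cost": 2.0,
    "max_pathway_length": 20
  }
}
```

## Wards

| field | type | default | meaning |
|---|---|---|---|
| `id` | string | required | lowercase snake_case key; `DISCHARGE`/`EXTERNAL` reserved |
| `name` | string | title-cased id | display name |
| `capacity` | int ≥ 0 | 0 | beds |
| `resources` | number ≥ 0 | 0 | treatment resource pool per step |
| `los_lambda` | number > 0 | 1 | Poisson mean length of stay (steps) |
| `need_lambda` | number ≥ 0 | 0 | Poisson mean total resource need |
| `queue_policy` | name | `chronological` | `chronological`, `high_need_first`, `low_need_first`, or registered |
| `resource_policy` | name | `even` | `even`, `high_need`, `low_need`, or registered |
| `allow_overflow` | bool | false | ward accepts boarding patients |
| `is_entry` | bool | false | exactly one ward must be the entry (A&E) |

## Graph

`graph.weights[from][to]` = transfer probability. Every ward needs an
outgoing row over other wards and/or `"DISCHARGE"`, summing to 1 within
1e-9; no self-loops; `DISCHARGE` has no outgoing row; every ward must be
able to reach `DISCHARGE`.

## Settings

`max_steps` is a hard cap (0 = null run). `max_patients` (nullable)
stops arrivals when reached; the run then drains. Arrivals per step are
uniform on `[arrivals_min, arrivals_max]`. `waiting_time_target` is in
steps (hours by default). Costs are charged per step per resource unit
and per bed.
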
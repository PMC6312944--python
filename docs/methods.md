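# Methods

## Model

wardflow is a fixed-increment discrete-event simulation: state is
updated once per step (one hour by default), not by a continuous-time
event calendar. Entities are virtual patients; resources are an
abstract per-ward, per-step pool standing in for staff, diagnostics and
consumables. The model deliberately has no patient covariates (age,
acuity classes), no diurnal arrival pattern and no elective/emergency
split — it is a teaching-scale abstraction of flow, not a forecasting
model.

### Patients

A patient is created on arrival with:

* a **required pathway**: a random walk on the transition digraph
  starting at the entry ward, absorbing at `DISCHARGE` (which is never
  part of the pathway). Walks are truncated at `max_pathway_length`
  (default 20) wards; a truncated patient is simply discharged after the
  last generated ward, which guarantees termination on graphs with
  cycles.
* per pathway ward, independent draws
  `los_required = max(1, Poisson(los_lambda))` and
  `need_required = Poisson(need_lambda)`. The clamp to ≥ 1 step means
  every ward visit occupies a bed for at least one step, keeping
  occupancy accounting well defined. Stay and need are assumed
  independent given the ward.

Arrivals per step are integer-uniform on `[arrivals_min, arrivals_max]`
— the bounds are the modelled quantity, and uniform is the least
committal distribution between them.

### Step phases

Each step runs six sub-phases in a fixed order:

1. arrivals join the (unbounded) entry-ward queue;
2. treatment: each ward divides its resource pool among actively
   treated occupants under its resource policy; need counters drop by
   the allocation (floor 0), stay counters by one. Unused resources do
   not carry over;
3. completion: occupants with `need_remaining = 0` **and**
   `los_remaining = 0` (treatment takes resources *and* time) either
   join the next required ward's queue — keeping their bed — or, on the
   final pathway ward, are discharged, freeing the bed immediately;
4. admissions: wards fill free beds from their queues under their queue
   policies. Wards are processed in configuration order, but passes
   repeat until no admission occurs, so a bed vacated by a transfer is
   refillable the same step regardless of ward ordering. Queue ties
   always break by (queue entry step, patient id);
5. overflow: a ward at capacity with a non-empty queue boards its
   completed-but-blocked occupants, one at a time, into the first
   overflow-enabled ward (configuration order) with a free bed — never
   the ward the patient is queueing for. Boarding patients keep their
   queue position and entry step; each freed bed is offered to the
   ward's own queue at once. Boarders consume a bed but receive no
   treatment and make no stay progress (diversion frees a bed; it does
   not treat), and a completed-but-blocked patient consumes no further
   resources (its need is already zero);
6. snapshot: per-ward occupancy and queue lengths are recorded.

Stopping: `max_steps` is a hard cap, always active (0 is a valid null
run). If `max_patients` is set, arrivals cease once reached and the run
continues until all in-flight patients drain or the cap hits.

All randomness flows from one `numpy.random.default_rng(seed)` owned by
the run; modules receive the stream and never seed themselves, so a run
is a pure function of (config, seed) and event logs are byte-identical
across repeats. Resource allocations are real-valued (need counters
accept fractional decrements) to avoid integer-rationing artefacts; the
need-exhaustion test uses a 1e-9 tolerance.

### Policies

Queue presets: `chronological` (FIFO), `high_need_first`,
`low_need_first`; "need" is the patient's `need_required` at the
destination ward — the quantity the admitting ward can observe — not
the remaining pathway total. Resource presets: `even` (iterative
water-filling with capping, so surplus from low-need patients is
redistributed and the pool is maximally used), `high_need`, `low_need`
(greedy in need order, ties by patient id). Custom policies register by
name (`register_policy`) and are then referable from config files; the
registry contract is this package's own design for an extension API.

## Analysis definitions

* **Waiting time**: step of the patient's first exit from the entry
  ward (transfer, diversion or discharge) minus arrival step — the
  arrival-to-admission/transfer/discharge semantics of the UK 4-hour
  A&E standard, not time-to-ED-admission. Patients still in (or
  queueing for) the ED at cutoff are censored: excluded from the
  percentage and reported as a count, avoiding truncation bias.
* **Flow network**: one edge-count increment per movement event;
  `EXTERNAL → entry` per admission, `ward → DISCHARGE` per discharge.
  Degrees are reported weighted (summed counts) and unweighted.
* **Centralities** use the unweighted edge-presence graph (transfer
  counts do not reweight shortest paths; weighted degrees are reported
  separately). Betweenness is directed shortest-path betweenness
  normalised per node by the number of connected ordered pairs not
  involving that node — on a directed path a→b→c this gives b exactly
  1, and values stay in [0, 1] on disconnected realised flow graphs,
  where the textbook (n−1)(n−2) normalisation does not reach 1.
  Closeness is harmonic closeness of incoming distances divided by
  (n−1), well defined on disconnected graphs. Both are cross-checked in
  the tests against a brute-force all-pairs path enumeration on graphs
  of ≤ 6 nodes.
* **Journeys**: the ordered required wards a discharged patient visited
  (boarding wards excluded); duration is discharge − arrival step;
  even-sized medians average the two central values.
* **Operating cost**: `steps_run × Σ_w (resources_w × resource_unit_cost
  + capacity_w × bed_unit_cost)` — capacity and resource pools are paid
  for whether used or not.

The whole analysis is computed from (config, event log, snapshots), so
`wardflow analyze` regenerates a run-time report exactly from saved
CSVs; bed occupancy can even be replayed from the event log alone.

## The default hospital

The shipped fixture is an emergency department plus seven specialist
wards (acute assessment, surgery, cardiology, general medicine,
orthopaedics, respiratory, geriatrics) with capacities
20/40/25/30/45/20/20/20 = 220 beds. The transition matrix, per-ward
λ values, arrival bounds and unit costs are **calibrated inventions**,
chosen once to produce a typical journey mix and a plausible monthly
throughput, not estimates from data:

* arrivals uniform on [0, 4] per step (mean 2/h), so a 720-step month
  sees ≈ 1440 arrivals and — because the default hospital has slack —
  ≈ 1430 emergency admissions;
* ED mean stay 2 h; specialist stays 24–96 h; ED routes 45% straight to
  discharge and 30% to acute assessment; specialist wards discharge
  85–100% directly with small inter-ward weights;
* offered load per ward (inflow × mean stay) sits at roughly 30–60% of
  capacity, so queues are short by default and management experiments
  can stress the system from a working baseline;
* surgery is the one overflow-enabled ward by default (surgical beds
  are a common pressure valve), so diversions are rare out of the box;
* unit costs 1.0 per resource unit and 2.0 per bed per step set a cost
  scale only; their ratio is the meaningful choice.

What passing tests on this fixture do **not** show: realism of any
particular number for a real hospital. The generator has no diurnal or
seasonal structure, no correlation between need and stay, and no
arrival dependence on occupancy, so absolute waiting-time percentages
transfer to real settings only qualitatively.

## Problem sizes used in the shipped checks

The test suite exercises hand-traceable 1–3-ward hospitals for exact
event sequences; 100 random 2–4-ward hospitals × 200 steps for
conservation/capacity invariants; n = 10 000 draws for Poisson-mean
recovery and the chi-square fit of first transitions (p > 0.001); 200
random ≤ 6-node digraphs against the brute-force centrality oracle;
1000 random allocation instances per policy; and 20 seeds × 720 steps
of the default hospital for the monthly-throughput figure. The
acceptance script reports the mean emergency admissions over those 20
months.

## Known limitations

* Intra-step phase order is a modelling choice; admissions-before-
  overflow means a diversion can happen one phase after a queue was
  served, and ward processing order can matter in pathological ties
  even though repeats-to-fixpoint removes the common cases.
* Boarding patients never progress; a long blockage of a popular ward
  can therefore park diverted patients indefinitely (they are released
  strictly by their required ward's queue policy).
* Queue-length series for non-entry wards are recorded by the engine
  but cannot be replayed from the event log alone (joining a queue is
  not an event); `analyze` without `--occupancy` reports them as zero
  and infers run length from the last event.
* The percentage-within-target is undefined (reported as null, not 0)
  when no patient completed an ED episode.
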
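"""Discrete-event trial engine: arrivals, allocation, reviews, deliveries.

One replicate interleaves, in time order, site activations (with initial
drug shipments), patient arrivals, weekly supply reviews, and shipment
deliveries, applying the configured IRT allocation rule at every attempt.
Simultaneous events are ordered ``DELIVERY < ARRIVAL < REVIEW`` so a review
always sees the day's post-dispensing stock.

Semantics of refusals and waiting, per patient (each tally at most once):

* A patient refused because the required kit type is missing while the site
  still holds other kits (FR0a/FR0b) is *sent home*; the patient returns
  and re-attempts randomization at each subsequent delivery to the site.
* A patient facing a completely empty site (FR0b/FR1a/FR1b) — or a
  returning sent-home patient whose re-attempt at a delivery fails — is
  *waitlisted* and keeps waiting in the site's FIFO queue.
* Recruitment stops the moment the target number of patients has been
  randomized; patients still queued become *not allocated*.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .randomization import (
    ASSIGNED,
    REFUSED,
    IRTConfig,
    RandomizationList,
    generate_permuted_block_list,
    next_assignment,
)
from .recruitment import RecruitmentModel, sample_sites
from .supply import (
    Shipment,
    SiteInventory,
    SupplyStrategy,
    deliver,
    dispense,
    initial_stock_on_activation,
    weekly_review,
)

# event-type priority for simultaneous events
_DELIVERY, _ARRIVAL, _REVIEW = 0, 1, 2

# patient statuses
RANDOMIZED = "RANDOMIZED"
SENT_HOME_THEN_RANDOMIZED = "SENT_HOME_THEN_RANDOMIZED"
WAITLISTED_THEN_RANDOMIZED = "WAITLISTED_THEN_RANDOMIZED"
NOT_ALLOCATED = "NOT_ALLOCATED"


@dataclass
class PatientRecord:
    __slots__ = (
        "patient_id", "site_id", "arrival_time", "status", "ever_sent_home",
        "ever_waitlisted", "forced", "backfill", "arm", "list_position",
        "randomization_time",
    )
    patient_id: int
    site_id: int
    arrival_time: float
    status: str
    ever_sent_home: bool
    ever_waitlisted: bool
    forced: bool
    backfill: bool
    arm: Optional[str]
    list_position: Optional[int]
    randomization_time: Optional[float]


class EventLog:
    """Append-only, time-ordered record of simulation events.

    Each event is ``(time, event_type, payload)`` with
    ``event_type`` in {ACTIVATION, ARRIVAL, REVIEW, DELIVERY, RANDOMIZATION,
    REFUSAL, WAITLIST, STOP}; exactly one STOP closes the log.
    """

    def __init__(self) -> None:
        self.events: list[tuple[float, str, dict]] = []
        self._last_t = -np.inf

    def add(self, t: float, kind: str, payload: dict) -> None:
        if t < self._last_t - 1e-9:
            raise ValueError("events must be appended in non-decreasing time order")
        self._last_t = max(self._last_t, t)
        self.events.append((t, kind, payload))

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def stop_time(self) -> Optional[float]:
        for t, kind, _ in reversed(self.events):
            if kind == "STOP":
                return t
        return None

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "event_type", "payload"])
            for t, kind, payload in self.events:
                w.writerow([t, kind, json.dumps(payload, sort_keys=True)])


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to reproduce one simulation cell from one seed."""

    n: int
    recruitment: RecruitmentModel
    supply: SupplyStrategy
    irt: IRTConfig
    label: str = ""
    block_size: int = 4
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("target sample size must be >= 1")
        if self.block_size <= 0 or self.block_size % 2:
            raise ValueError("block_size must be a positive even integer")


@dataclass
class TrialResult:
    """Event log, patient records and kit ledger for one replicate."""

    events: EventLog
    patients: list[PatientRecord]
    completion_time: Optional[float]
    n_randomized: int
    n_forced: int
    kits_shipped: int
    kits_dispensed: int
    kits_on_site: int
    kits_in_transit: int
    fr0a_zero_stock_seen: bool
    rlist: RandomizationList = None
    config: Optional[ScenarioConfig] = None


@dataclass(frozen=True)
class ScriptedScenario:
    """A fully deterministic worked example: explicit arrivals, a fixed
    randomization list, per-site initial stocks and scripted shipments.

    Bypasses all stochastic sampling; used to replay toy examples exactly.
    """

    list_arms: str                       # e.g. "AABBABBA"
    sites: Sequence[dict]                # {site_id, activation_time, initial_A, initial_B}
    arrivals: Sequence[dict]             # {time, site_id}
    shipments: Sequence[dict] = ()       # {site_id, order_time, delivery_time, qty_A, qty_B}
    block_size: int = 4
    n_target: Optional[int] = None       # default: number of scripted arrivals

    @classmethod
    def from_json(cls, path) -> "ScriptedScenario":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            list_arms=raw["list_arms"],
            sites=raw["sites"],
            arrivals=raw["arrivals"],
            shipments=raw.get("shipments", []),
            block_size=raw.get("block_size", 4),
            n_target=raw.get("n_target"),
        )


def fig2_script() -> ScriptedScenario:
    """The packaged toy worked example: one site, schedule |AABB|ABBA| (plus
    one spare block), initial kits (2 A, 3 B), eight sequential patients and
    one mid-stream re-supply delivery."""
    ref = resources.files("frsim.data").joinpath("toy_example.json")
    with resources.as_file(ref) as path:
        return ScriptedScenario.from_json(path)


class _Core:
    """Shared event-loop state for stochastic runs and scripted replays."""

    def __init__(
        self,
        rlist: RandomizationList,
        irt: IRTConfig,
        n_target: int,
        block_size: int,
    ) -> None:
        self.rlist = rlist
        self.irt = irt
        self.n_target = n_target
        self.block_size = block_size
        self.log = EventLog()
        self.patients: list[PatientRecord] = []
        self.queues: dict[int, list[PatientRecord]] = {}
        self.invs: dict[int, SiteInventory] = {}
        self.n_randomized = 0
        self.n_forced = 0
        self.kits_shipped = 0
        self.kits_dispensed = 0
        self.completion_time: Optional[float] = None
        self.fr0a_zero_stock_seen = False

    def _ensure_capacity(self) -> None:
        # keep at least one untouched block so a scan always finds both arms
        while self.rlist.n_untouched_tail < self.block_size and self.rlist._rng is not None:
            self.rlist.extend(1)

    def attempt(self, patient: PatientRecord, t: float, at_delivery: bool) -> bool:
        """One allocation attempt; returns True if the patient was randomized."""
        inv = self.invs[patient.site_id]
        self._ensure_capacity()
        decision = next_assignment(self.rlist, inv.stock, self.irt, self.n_forced)
        if decision.outcome == ASSIGNED:
            self.rlist.apply(decision)
            dispense(inv, decision.arm)
            self.kits_dispensed += 1
            if decision.forced:
                self.n_forced += 1
            patient.arm = decision.arm
            patient.list_position = decision.position
            patient.forced = decision.forced
            patient.backfill = decision.backfill
            patient.randomization_time = t
            if patient.ever_sent_home:
                patient.status = SENT_HOME_THEN_RANDOMIZED
            elif patient.ever_waitlisted:
                patient.status = WAITLISTED_THEN_RANDOMIZED
            else:
                patient.status = RANDOMIZED
            self.n_randomized += 1
            if self.irt.mode == "FR0a" and inv.total_stock == 0:
                self.fr0a_zero_stock_seen = True  # should be unreachable
            self.log.add(t, "RANDOMIZATION", {
                "patient": patient.patient_id, "site": patient.site_id,
                "arm": decision.arm, "position": decision.position,
                "forced": decision.forced, "backfill": decision.backfill,
                "crossed_out": sorted(decision.crossed_out_positions),
            })
            if self.n_randomized >= self.n_target:
                self.completion_time = t
            return True
        if decision.outcome == REFUSED:
            if at_delivery:
                # failed re-attempt of a returning sent-home patient
                if not patient.ever_waitlisted:
                    patient.ever_waitlisted = True
                    self.log.add(t, "WAITLIST", {"patient": patient.patient_id,
                                                 "site": patient.site_id})
            else:
                patient.ever_sent_home = True
                self.log.add(t, "REFUSAL", {"patient": patient.patient_id,
                                            "site": patient.site_id})
        else:  # NO_STOCK
            if not patient.ever_waitlisted:
                patient.ever_waitlisted = True
                self.log.add(t, "WAITLIST", {"patient": patient.patient_id,
                                             "site": patient.site_id})
        return False

    def on_arrival(self, patient: PatientRecord, t: float) -> None:
        self.log.add(t, "ARRIVAL", {"patient": patient.patient_id,
                                    "site": patient.site_id})
        if not self.attempt(patient, t, at_delivery=False):
            self.queues.setdefault(patient.site_id, []).append(patient)

    def on_delivery(self, shipment: Shipment, t: float) -> None:
        inv = self.invs[shipment.site_id]
        deliver(shipment, inv)
        self.log.add(t, "DELIVERY", {"site": shipment.site_id,
                                     "qty_A": shipment.qty.get("A", 0),
                                     "qty_B": shipment.qty.get("B", 0),
                                     "reason": shipment.reason})
        # serve the pending queue FIFO until empty or blocked
        queue = self.queues.get(shipment.site_id)
        while queue and self.n_randomized < self.n_target:
            if self.attempt(queue[0], t, at_delivery=True):
                queue.pop(0)
            else:
                break

    def pending_demand(self) -> dict:
        """Kits committed to waiting patients: the next q free positions'
        arms for a site with q patients queued (the queue is served in
        schedule order at the next delivery)."""
        demand: dict[int, dict[str, int]] = {}
        for site_id, queue in self.queues.items():
            if not queue:
                continue
            self._ensure_capacity()
            d = {"A": 0, "B": 0}
            for idx0, _ in zip(self.rlist.iter_free(), range(len(queue))):
                d[self.rlist.arm_at(idx0 + 1)] += 1
            demand[site_id] = d
        return demand

    def activate_site(self, site_id: int, t: float, inv: SiteInventory) -> None:
        self.invs[site_id] = inv
        shipped = inv.stock["A"] + inv.stock["B"]
        self.kits_shipped += shipped
        self.log.add(t, "ACTIVATION", {"site": site_id,
                                       "qty_A": inv.stock["A"],
                                       "qty_B": inv.stock["B"]})

    def order(self, shipment: Shipment) -> None:
        inv = self.invs[shipment.site_id]
        inv.in_transit.append(shipment)
        self.kits_shipped += sum(shipment.qty.values())

    def finish(self) -> TrialResult:
        if self.completion_time is not None:
            t_stop = self.completion_time
        elif self.log.events:
            t_stop = self.log.events[-1][0]
        else:
            t_stop = 0.0
        for queue in self.queues.values():
            for p in queue:
                p.status = NOT_ALLOCATED
        self.log.add(t_stop, "STOP", {"n_randomized": self.n_randomized})
        on_site = sum(inv.total_stock for inv in self.invs.values())
        in_transit = sum(
            sum(s.qty.values()) for inv in self.invs.values() for s in inv.in_transit
        )
        return TrialResult(
            events=self.log,
            patients=self.patients,
            completion_time=self.completion_time,
            n_randomized=self.n_randomized,
            n_forced=self.n_forced,
            kits_shipped=self.kits_shipped,
            kits_dispensed=self.kits_dispensed,
            kits_on_site=on_site,
            kits_in_transit=in_transit,
            fr0a_zero_stock_seen=self.fr0a_zero_stock_seen,
            rlist=self.rlist,
        )


def run_trial(config: ScenarioConfig, seed: Optional[int] = None) -> TrialResult:
    """Simulate one trial replicate.

    The master seed derives independent sub-streams for list generation,
    site sampling and arrivals, so different IRT configurations can be
    compared under common random numbers: with the same seed, the sites,
    the arrival stream and the randomization schedule are identical across
    configurations.
    """
    if seed is None:
        seed = config.seed
    if seed is None:
        raise ValueError("a seed is required (pass seed= or set config.seed)")
    if config.recruitment.n_sites < 1:
        raise ValueError("scenario must have at least one site")

    ss = np.random.SeedSequence(seed)
    ss_list, ss_sites, ss_arrivals = ss.spawn(3)

    n_blocks = int(np.ceil(1.5 * config.n / config.block_size))
    list_seed = int(ss_list.generate_state(1, dtype=np.uint32)[0])
    rlist = generate_permuted_block_list(n_blocks * config.block_size,
                                         config.block_size, list_seed)

    sites = sample_sites(config.recruitment, ss_sites)
    arr_rng = np.random.default_rng(ss_arrivals)

    core = _Core(rlist, config.irt, config.n, config.block_size)
    core.config = config

    # event heap: (time, priority, seq, payload)
    heap: list = []
    seq = 0
    for site in sites:
        inv = initial_stock_on_activation(config.supply, site)
        heapq.heappush(heap, (site.activation_time, _DELIVERY, seq, ("activate", site.site_id, inv)))
        seq += 1
    review_t = config.supply.review_interval
    heapq.heappush(heap, (review_t, _REVIEW, seq, None))
    seq += 1

    rate_of = {s.site_id: s.rate for s in sites}
    active: list[int] = []  # site ids with inventory, in activation order
    next_patient_id = 1

    while heap and core.n_randomized < config.n:
        t, kind, _, payload = heapq.heappop(heap)
        if kind == _DELIVERY:
            if payload[0] == "activate":
                _, site_id, inv = payload
                core.activate_site(site_id, t, inv)
                active.append(site_id)
                gap = arr_rng.exponential(1.0 / rate_of[site_id])
                heapq.heappush(heap, (t + gap, _ARRIVAL, seq, site_id))
                seq += 1
            else:
                core.on_delivery(payload[1], t)
        elif kind == _ARRIVAL:
            site_id = payload
            patient = PatientRecord(next_patient_id, site_id, t, NOT_ALLOCATED,
                                    False, False, False, False, None, None, None)
            next_patient_id += 1
            core.patients.append(patient)
            core.on_arrival(patient, t)
            if core.n_randomized < config.n:
                gap = arr_rng.exponential(1.0 / rate_of[site_id])
                heapq.heappush(heap, (t + gap, _ARRIVAL, seq, site_id))
                seq += 1
        else:  # _REVIEW
            orders = weekly_review((core.invs[s] for s in active), config.supply, t,
                                   pending_demand=core.pending_demand())
            core.log.add(t, "REVIEW", {
                "orders": [{"site": o.site_id, "qty_A": o.qty["A"], "qty_B": o.qty["B"]}
                           for o in orders]})
            for o in orders:
                core.order(o)
                heapq.heappush(heap, (o.delivery_time, _DELIVERY, seq, ("ship", o)))
                seq += 1
            review_t += config.supply.review_interval
            heapq.heappush(heap, (review_t, _REVIEW, seq, None))
            seq += 1

    result = core.finish()
    result.config = config
    return result


def replay_scripted(script: ScriptedScenario, irt: IRTConfig) -> TrialResult:
    """Replay a scripted scenario with the exact engine semantics but all
    randomness removed.  Scripted shipments replace weekly reviews."""
    arrivals = list(script.arrivals)
    for a, b in zip(arrivals, arrivals[1:]):
        if b["time"] < a["time"]:
            raise ValueError("scripted arrivals out of time order")
    n_target = script.n_target if script.n_target is not None else len(arrivals)

    rlist = RandomizationList(list(script.list_arms), script.block_size)
    core = _Core(rlist, irt, n_target, script.block_size)

    heap: list = []
    seq = 0
    for s in script.sites:
        inv = SiteInventory(s["site_id"],
                            {"A": int(s["initial_A"]), "B": int(s["initial_B"])}, [])
        heapq.heappush(heap, (float(s.get("activation_time", 0.0)), _DELIVERY, seq,
                              ("activate", s["site_id"], inv)))
        seq += 1
    for sh in script.shipments:
        shipment = Shipment(sh["site_id"],
                            {"A": int(sh.get("qty_A", 0)), "B": int(sh.get("qty_B", 0))},
                            float(sh["order_time"]), float(sh["delivery_time"]))
        heapq.heappush(heap, (shipment.delivery_time, _DELIVERY, seq, ("ship", shipment)))
        seq += 1
    # scripted orders enter the ledger (and in-transit) at their order times;
    # process those bookings time-ordered with everything else is unnecessary
    # since kits_shipped is a cumulative count
    pid = 1
    for a in arrivals:
        heapq.heappush(heap, (float(a["time"]), _ARRIVAL, seq, (pid, a["site_id"])))
        seq += 1
        pid += 1

    while heap and core.n_randomized < n_target:
        t, kind, _, payload = heapq.heappop(heap)
        if kind == _DELIVERY:
            if payload[0] == "activate":
                _, site_id, inv = payload
                core.activate_site(site_id, t, inv)
            else:
                shipment = payload[1]
                core.order(shipment)
                core.on_delivery(shipment, t)
        else:
            patient_id, site_id = payload
            if site_id not in core.invs:
                raise ValueError(f"arrival at site {site_id} before its activation")
            patient = PatientRecord(patient_id, site_id, t, NOT_ALLOCATED,
                                    False, False, False, False, None, None, None)
            core.patients.append(patient)
            core.on_arrival(patient, t)

    return core.finish()
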
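"""Per-site drug kit inventories, weekly re-supply reviews and shipments.

Each active site holds ``k_A(t)`` and ``k_B(t)`` kits.  Supply levels are
reviewed weekly (days 7, 14, ...): if an arm's stock is at or below the
trigger level ``Crit`` (the paper's inequality ``k_d(t) <= Crit`` is
inclusive), a re-supply order tops that arm up to its target level.  Each
triggered arm is topped up independently.  Shipments arrive after a fixed
lead time (2 days from the central depot, which is assumed unlimited).

By default an arm already covered by an in-transit shipment that would
restore it above the trigger is not re-ordered; with a 2-day lead and
weekly reviews this almost never binds, but it prevents double-shipping if
the lead time is configured longer than the review interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .recruitment import SiteProfile

ARMS = ("A", "B")


@dataclass(frozen=True)
class SupplyStrategy:
    """Initial stock, trigger level, re-supply targets and timing.

    ``initial`` kits per arm are shipped to a site upon its activation;
    thereafter weekly reviews top any arm with ``stock <= crit`` back up to
    ``target``.
    """

    initial: tuple[int, int]        # (k_A0, k_B0)
    crit: int                       # trigger level
    target: tuple[int, int]         # (k_A, k_B) re-supply levels
    review_interval: float = 7.0    # days
    lead_time: float = 2.0          # days
    ignore_in_transit: bool = False # if True, reviews look at on-site stock only
    queue_aware: bool = True        # reviews net out kits committed to waiting patients
    name: str = ""

    def __post_init__(self) -> None:
        if min(self.initial) < 0 or min(self.target) < 0 or self.crit < 0:
            raise ValueError("stocks and trigger must be non-negative")
        if not all(t > self.crit for t in self.target):
            raise ValueError("targets must exceed the trigger level")
        if self.review_interval <= 0 or self.lead_time < 0:
            raise ValueError("invalid review interval or lead time")


#: The three re-supply strategies compared in the simulation study.
LOW = SupplyStrategy((2, 2), 1, (2, 2), name="Low")
MEDIUM = SupplyStrategy((3, 3), 1, (4, 4), name="Medium")
HIGH = SupplyStrategy((4, 4), 2, (5, 5), name="High")
STRATEGIES = {"Low": LOW, "Medium": MEDIUM, "High": HIGH}


@dataclass(frozen=True)
class Shipment:
    site_id: int
    qty: dict  # arm -> kits
    order_time: float
    delivery_time: float
    reason: str = "resupply"  # "initial" | "resupply"

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.qty.values()) or sum(self.qty.values()) == 0:
            raise ValueError("shipment quantities must be >= 0 and not all zero")
        if self.delivery_time < self.order_time:
            raise ValueError("delivery before order")


@dataclass
class SiteInventory:
    site_id: int
    stock: dict = field(default_factory=lambda: {"A": 0, "B": 0})
    in_transit: list = field(default_factory=list)  # of Shipment

    def in_transit_qty(self, arm: str) -> int:
        return sum(s.qty.get(arm, 0) for s in self.in_transit)

    @property
    def total_stock(self) -> int:
        return self.stock["A"] + self.stock["B"]


def initial_stock_on_activation(strategy: SupplyStrategy, site: SiteProfile) -> SiteInventory:
    """Inventory a site holds at activation; the initial kits count toward
    total drug shipped."""
    return SiteInventory(
        site.site_id, {"A": strategy.initial[0], "B": strategy.initial[1]}, []
    )


def weekly_review(
    inventories: Iterable[SiteInventory],
    strategy: SupplyStrategy,
    t: float,
    pending_demand: Optional[dict] = None,
) -> list[Shipment]:
    """Run one supply review at time ``t`` over the given (active) sites.

    For each arm with (uncommitted) stock at or below the trigger, order the
    difference up to the target level, delivered after the lead time.  Sites
    with both arms above the trigger get no shipment.

    ``pending_demand`` maps site_id to per-arm kit counts already committed
    to patients waiting at the site for the next delivery (the IRT knows its
    own waitlist).  With ``strategy.queue_aware`` (the default) those kits
    are netted out of the stock the trigger inequality is applied to, so a
    delivery both serves the waiting patients and restores the target
    levels.  With no one waiting this reduces exactly to the plain
    stock-vs-trigger rule.
    """
    targets = {"A": strategy.target[0], "B": strategy.target[1]}
    orders: list[Shipment] = []
    for inv in inventories:
        demand = (pending_demand or {}).get(inv.site_id) if strategy.queue_aware else None
        qty = {}
        for arm in ARMS:
            covered = inv.stock[arm]
            if not strategy.ignore_in_transit:
                covered += inv.in_transit_qty(arm)
            if demand:
                covered -= demand.get(arm, 0)
            if covered <= strategy.crit:
                q = targets[arm] - covered
                if q > 0:
                    qty[arm] = q
        if qty:
            orders.append(
                Shipment(
                    inv.site_id,
                    {"A": qty.get("A", 0), "B": qty.get("B", 0)},
                    order_time=t,
                    delivery_time=t + strategy.lead_time,
                )
            )
    return orders


def deliver(shipment: Shipment, inventory: SiteInventory) -> SiteInventory:
    """Receive a shipment: move its kits from in-transit to on-site stock."""
    if shipment not in inventory.in_transit:
        raise ValueError("delivering a shipment unknown to this inventory")
    inventory.in_transit.remove(shipment)
    for arm, q in shipment.qty.items():
        inventory.stock[arm] += q
    return inventory


def dispense(inventory: SiteInventory, arm: str) -> SiteInventory:
    """Hand out one kit of ``arm``; exactly one kit per randomized patient."""
    if inventory.stock[arm] < 1:
        raise ValueError(f"cannot dispense arm {arm}: no stock on site")
    inventory.stock[arm] -= 1
    return inventory


def ledger_to_frame(shipments: Iterable[Shipment]) -> pd.DataFrame:
    """Shipment ledger: site_id, order_day, delivery_day, qty_A, qty_B, reason."""
    rows = [
        {
            "site_id": s.site_id,
            "order_day": s.order_time,
            "delivery_day": s.delivery_time,
            "qty_A": s.qty.get("A", 0),
            "qty_B": s.qty.get("B", 0),
            "reason": s.reason,
        }
        for s in shipments
    ]
    return pd.DataFrame(rows, columns=["site_id", "order_day", "delivery_day", "qty_A", "qty_B", "reason"])
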
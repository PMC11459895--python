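"""Central permuted-block randomization list and IRT allocation rules.

A multi-center trial with central (unstratified) randomization keeps one
common allocation schedule for all sites.  When the drug kit required by the
next position on the schedule is missing at the recruiting site, the
interactive response technology (IRT) can react in four ways:

``FR0a``
    No forced randomization.  The transaction is authorized only if *every*
    kit type is on site; otherwise the patient is refused.
``FR0b``
    No forced randomization, but only the kit for the next scheduled
    treatment needs to be available.
``FR1a``
    Forced randomization without backfilling: the patient takes the first
    free position whose treatment is available; skipped positions are
    crossed out and can never be used again.
``FR1b``
    Forced randomization with backfilling: skipped positions stay free and
    are filled by later patients once the kit is available (a backfill
    lands on the first free number and so is flagged, but not counted as a
    forced deviation).

The allocation rules are pure decision functions of the list state and the
site's kit availability; applying a decision to the list is a separate,
explicit step (:meth:`RandomizationList.apply`).
"""

from __future__ import annotations

import csv
from bisect import insort
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

ARMS: tuple[str, str] = ("A", "B")

# position states
FREE = "FREE"
USED = "USED"
CROSSED_OUT = "CROSSED_OUT"

# allocation outcomes
ASSIGNED = "ASSIGNED"
REFUSED = "REFUSED"
NO_STOCK = "NO_STOCK"

IRT_MODES: tuple[str, ...] = ("FR0a", "FR0b", "FR1a", "FR1b")


@dataclass(frozen=True)
class IRTConfig:
    """IRT allocation configuration.

    Parameters
    ----------
    mode
        One of ``FR0a``, ``FR0b``, ``FR1a``, ``FR1b``.
    forced_cap
        Optional maximum number of forced allocations.  Once the cap is
        reached, FR1a/FR1b behave like FR0b for subsequent calls.  Only
        meaningful for FR1a/FR1b.
    scramble_display_ids
        Present allocation numbers through a seeded random bijection so that
        out-of-order randomization does not reveal forced allocations.  A
        presentation-layer option only; never affects allocation logic.
    """

    mode: str
    forced_cap: Optional[int] = None
    scramble_display_ids: bool = False

    def __post_init__(self) -> None:
        if self.mode not in IRT_MODES:
            raise ValueError(f"unknown IRT mode {self.mode!r}; valid: {IRT_MODES}")
        if self.forced_cap is not None:
            if self.forced_cap < 0:
                raise ValueError("forced_cap must be non-negative")
            if self.mode not in ("FR1a", "FR1b"):
                raise ValueError("forced_cap is only meaningful for FR1a/FR1b")


@dataclass(frozen=True)
class AllocationDecision:
    """Outcome of one allocation attempt.

    ``position`` is the 1-based schedule position if assigned.  ``forced``
    marks an assignment that deviates from the lowest-index free position
    (possible only under FR1a/FR1b); ``backfill`` marks an FR1b assignment
    that fills a previously skipped position behind already-used ones (such
    an assignment follows the first-free-number rule and is not counted as
    a forced deviation, but is flagged separately).
    ``crossed_out_positions`` is non-empty only under FR1a; ``REFUSED``
    occurs only under FR0a/FR0b (or FR1 modes operating under an exhausted
    forced-allocation cap).
    """

    outcome: str
    position: Optional[int] = None
    arm: Optional[str] = None
    forced: bool = False
    backfill: bool = False
    crossed_out_positions: frozenset[int] = field(default_factory=frozenset)


class RandomizationList:
    """Permuted-block allocation schedule with per-position state.

    Positions are 1-based in the public API.  Internally the list keeps a
    *frontier* (lowest never-touched index) and a sorted list of *gaps*
    (free positions below the frontier, created by FR1b skips) so that
    scanning for the next free position is cheap even on long schedules.
    """

    def __init__(
        self,
        arms: Sequence[str],
        block_size: int,
        generator_seed: Optional[int] = None,
        _rng: Optional[np.random.Generator] = None,
    ) -> None:
        arms = list(arms)
        _validate_blocks(arms, block_size)
        self._arms = arms
        self._states = [FREE] * len(arms)
        self.block_size = int(block_size)
        self.generator_seed = generator_seed
        self._rng = _rng
        self._frontier = 0          # 0-based: everything >= frontier is untouched FREE
        self._gaps: list[int] = []  # sorted 0-based FREE positions < frontier

    # -- inspection ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._arms)

    def arm_at(self, position: int) -> str:
        """Treatment at a 1-based position."""
        return self._arms[position - 1]

    def state_at(self, position: int) -> str:
        return self._states[position - 1]

    @property
    def entries(self) -> list[tuple[int, str, str]]:
        """``(position, arm, state)`` triples, 1-based."""
        return [(i + 1, a, s) for i, (a, s) in enumerate(zip(self._arms, self._states))]

    def iter_free(self) -> Iterator[int]:
        """Yield 0-based free indices in increasing order."""
        yield from self._gaps
        yield from range(self._frontier, len(self._arms))

    @property
    def lowest_free(self) -> Optional[int]:
        """1-based lowest free position, or None if exhausted."""
        if self._gaps:
            return self._gaps[0] + 1
        if self._frontier < len(self._arms):
            return self._frontier + 1
        return None

    @property
    def n_free(self) -> int:
        return len(self._gaps) + len(self._arms) - self._frontier

    @property
    def n_untouched_tail(self) -> int:
        """Free positions at the untouched tail (always contains both arms
        while at least one full block remains)."""
        return len(self._arms) - self._frontier

    def counts(self) -> dict[str, int]:
        used = sum(1 for s in self._states if s == USED)
        crossed = sum(1 for s in self._states if s == CROSSED_OUT)
        return {USED: used, CROSSED_OUT: crossed, FREE: len(self._arms) - used - crossed}

    # -- mutation ------------------------------------------------------

    def apply(self, decision: AllocationDecision) -> None:
        """Commit an ``ASSIGNED`` decision: mark the position used and cross
        out any skipped positions.  Non-assignments are no-ops."""
        if decision.outcome != ASSIGNED:
            return
        i = decision.position - 1
        if self._states[i] != FREE:
            raise ValueError(f"position {decision.position} is not free")
        self._states[i] = USED
        crossed0 = {p - 1 for p in decision.crossed_out_positions}
        for c in crossed0:
            if self._states[c] != FREE:
                raise ValueError(f"cannot cross out non-free position {c + 1}")
            self._states[c] = CROSSED_OUT
        # maintain frontier / gaps
        if i < self._frontier:
            self._gaps.remove(i)
        else:
            for p in range(self._frontier, i):
                if self._states[p] == FREE:
                    insort(self._gaps, p)
            self._frontier = i + 1
        if crossed0:
            self._gaps = [g for g in self._gaps if g not in crossed0]

    def extend(self, extra_blocks: int) -> "RandomizationList":
        """Append ``extra_blocks`` freshly generated blocks in place.

        Uses the list's own generator state, so repeated extension
        reproduces exactly the schedule a single longer generation under the
        same seed would have produced.  Returns ``self``.
        """
        if extra_blocks < 1:
            raise ValueError("extra_blocks must be >= 1")
        if self._rng is None:
            raise ValueError("list has no generator state; cannot extend")
        new = _generate_blocks(self._rng, extra_blocks, self.block_size)
        self._arms.extend(new)
        self._states.extend([FREE] * len(new))
        return self

    # -- I/O -----------------------------------------------------------

    def display_ids(self, seed: int) -> dict[int, int]:
        """Seeded random bijection position -> display ID (scrambled
        allocation numbers; cosmetic, never used by allocation logic)."""
        rng = np.random.Generator(np.random.PCG64(seed))
        perm = rng.permutation(len(self._arms)) + 1
        return {i + 1: int(perm[i]) for i in range(len(self._arms))}

    def to_csv(self, path, display_seed: Optional[int] = None) -> None:
        """Export ``position, display_id, arm, state`` (bit-exact round trip)."""
        ids = self.display_ids(display_seed) if display_seed is not None else None
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["position", "display_id", "arm", "state"])
            for pos, arm, state in self.entries:
                w.writerow([pos, ids[pos] if ids else pos, arm, state])

    @classmethod
    def from_csv(cls, path, block_size: int = 4) -> "RandomizationList":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        rows.sort(key=lambda r: int(r["position"]))
        lst = cls([r["arm"] for r in rows], block_size)
        # replay states, recomputing frontier/gaps
        touched = [i for i, r in enumerate(rows) if r["state"] != FREE]
        lst._frontier = (max(touched) + 1) if touched else 0
        for i, r in enumerate(rows):
            if r["state"] in (USED, CROSSED_OUT):
                lst._states[i] = r["state"]
            elif i < lst._frontier:
                insort(lst._gaps, i)
        return lst


def _validate_blocks(arms: Sequence[str], block_size: int) -> None:
    if block_size <= 0 or block_size % 2:
        raise ValueError("block_size must be a positive even integer")
    if len(arms) % block_size:
        raise ValueError(
            f"list length {len(arms)} is not a multiple of block size {block_size}"
        )
    for a in arms:
        if a not in ARMS:
            raise ValueError(f"unknown arm {a!r}")


def _generate_blocks(rng: np.random.Generator, n_blocks: int, block_size: int) -> list[str]:
    half = block_size // 2
    base = np.array(["A"] * half + ["B"] * half)
    out: list[str] = []
    for _ in range(n_blocks):
        out.extend(rng.permutation(base).tolist())
    return out


def generate_permuted_block_list(
    n_positions: int, block_size: int, seed: int
) -> RandomizationList:
    """Generate a fresh permuted-block schedule of ``n_positions`` entries.

    Within every block of ``block_size`` consecutive positions each arm
    appears exactly ``block_size / 2`` times.  Deterministic given ``seed``;
    the returned list carries its generator state so it can later be
    extended seamlessly.
    """
    if block_size <= 0 or block_size % 2:
        raise ValueError("block_size must be a positive even integer")
    if n_positions <= 0 or n_positions % block_size:
        raise ValueError(
            f"n_positions must be a positive multiple of block_size "
            f"(got {n_positions} with block_size {block_size})"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    arms = _generate_blocks(rng, n_positions // block_size, block_size)
    return RandomizationList(arms, block_size, generator_seed=seed, _rng=rng)


def extend_list(lst: RandomizationList, extra_blocks: int) -> RandomizationList:
    """Append ``extra_blocks`` blocks to ``lst`` (see
    :meth:`RandomizationList.extend`)."""
    return lst.extend(extra_blocks)


def _check_availability(availability: Mapping[str, int]) -> tuple[int, int]:
    a, b = int(availability["A"]), int(availability["B"])
    if a < 0 or b < 0:
        raise ValueError("negative stock")
    return a, b


def next_assignment(
    lst: RandomizationList,
    availability: Mapping[str, int],
    config: IRTConfig,
    forced_so_far: int = 0,
) -> AllocationDecision:
    """Decide the allocation for the next patient given list state and the
    recruiting site's kit availability.

    Does not mutate ``lst``; commit an ``ASSIGNED`` decision with
    :meth:`RandomizationList.apply`.

    Rules (1-based positions; "lowest free" = smallest-index FREE position):

    * ``FR0a`` — refuse unless both arms have stock; else assign the lowest
      free position's treatment.
    * ``FR0b`` — assign the lowest free position if its treatment has stock;
      otherwise refuse, or report ``NO_STOCK`` if the site is empty.
    * ``FR1a`` — scan free positions upward, assign the first whose
      treatment has stock; skipped positions are crossed out; the patient is
      forced iff the assignment deviates from the lowest free position.
    * ``FR1b`` — same scan, but skipped positions stay free for backfilling;
      forced iff the assignment deviates from the lowest free position.  A
      pure backfill lands exactly on the lowest free position and therefore
      follows the first-free-number rule; it is flagged ``backfill`` rather
      than forced.

    With an exhausted forced-allocation cap, FR1a/FR1b behave as FR0b.
    """
    if len(lst) == 0:
        raise ValueError("empty randomization list")
    stock_a, stock_b = _check_availability(availability)
    lowest = lst.lowest_free
    if lowest is None:
        raise ValueError("randomization list has no free positions; extend it first")

    mode = config.mode
    if (
        mode in ("FR1a", "FR1b")
        and config.forced_cap is not None
        and forced_so_far >= config.forced_cap
    ):
        mode = "FR0b"

    total = stock_a + stock_b
    stock = {"A": stock_a, "B": stock_b}

    if mode == "FR0a":
        if stock_a == 0 or stock_b == 0:
            return AllocationDecision(REFUSED)
        return AllocationDecision(ASSIGNED, lowest, lst.arm_at(lowest))

    if mode == "FR0b":
        if stock[lst.arm_at(lowest)] > 0:
            return AllocationDecision(ASSIGNED, lowest, lst.arm_at(lowest))
        if total == 0:
            return AllocationDecision(NO_STOCK)
        return AllocationDecision(REFUSED)

    # FR1a / FR1b
    if total == 0:
        return AllocationDecision(NO_STOCK)
    skipped: list[int] = []
    assigned: Optional[int] = None
    for idx0 in lst.iter_free():
        pos = idx0 + 1
        if stock[lst.arm_at(pos)] > 0:
            assigned = pos
            break
        skipped.append(pos)
    if assigned is None:  # cannot happen while a full untouched block remains
        raise ValueError("no admissible free position; extend the list first")

    if mode == "FR1a":
        forced = assigned != lowest
        crossed = frozenset(skipped) if forced else frozenset()
        return AllocationDecision(ASSIGNED, assigned, lst.arm_at(assigned), forced,
                                  crossed_out_positions=crossed)

    forced = assigned != lowest
    backfill = (assigned - 1) < lst._frontier  # fills a gap behind used positions
    return AllocationDecision(ASSIGNED, assigned, lst.arm_at(assigned), forced, backfill)
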
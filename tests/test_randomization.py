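"""Permuted-block list generation and the four IRT allocation rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from frsim.randomization import (
    ASSIGNED,
    CROSSED_OUT,
    FREE,
    NO_STOCK,
    REFUSED,
    USED,
    AllocationDecision,
    IRTConfig,
    RandomizationList,
    extend_list,
    generate_permuted_block_list,
    next_assignment,
)

from .reference import ref_apply, ref_decide

MODES = ("FR0a", "FR0b", "FR1a", "FR1b")


def arms_of(lst):
    return "".join(a for _, a, _ in lst.entries)


# ---------------------------------------------------------------- generation


@pytest.mark.parametrize("n,bs", [(4, 4), (8, 4), (48, 4), (36, 6), (40, 2)])
def test_blocks_are_balanced_and_free(n, bs):
    lst = generate_permuted_block_list(n, bs, seed=7)
    arms = arms_of(lst)
    assert len(lst) == n
    for start in range(0, n, bs):
        block = arms[start : start + bs]
        assert block.count("A") == bs // 2 and block.count("B") == bs // 2
    assert all(state == FREE for _, _, state in lst.entries)
    # determinism
    assert arms == arms_of(generate_permuted_block_list(n, bs, seed=7))
    assert arms != arms_of(generate_permuted_block_list(n, bs, seed=8)) or n == 4


def test_worked_schedule_is_a_realization():
    # the worked example's first two blocks |AABB|ABBA| arise under seed 16
    assert arms_of(generate_permuted_block_list(8, 4, seed=16)) == "AABBABBA"


@pytest.mark.parametrize(
    "n,bs", [(10, 4), (0, 4), (-8, 4), (12, 3), (12, 0)]
)
def test_invalid_generation_arguments_rejected(n, bs):
    with pytest.raises(ValueError):
        generate_permuted_block_list(n, bs, seed=0)


def test_block_patterns_uniform_over_six_arrangements():
    """Each of the 6 possible AABB arrangements should occur ~1/6 of the
    time; chi-square over 10,000 generated blocks."""
    lst = generate_permuted_block_list(40_000, 4, seed=123)
    arms = arms_of(lst)
    blocks = [arms[i : i + 4] for i in range(0, 40_000, 4)]
    patterns = sorted({"".join(p) for p in itertools.permutations("AABB")})
    assert len(patterns) == 6
    counts = [blocks.count(p) for p in patterns]
    assert sum(counts) == 10_000
    assert stats.chisquare(counts).pvalue > 1e-3


# ----------------------------------------------------------------- extension


def test_extension_preserves_prefix_and_matches_one_shot():
    one_shot = generate_permuted_block_list(24, 4, seed=5)
    grown = generate_permuted_block_list(8, 4, seed=5)
    prefix = arms_of(grown)
    extend_list(grown, 1)
    assert arms_of(grown)[:8] == prefix
    for _ in range(3):
        extend_list(grown, 1)
    assert len(grown) == 24
    assert arms_of(grown) == arms_of(one_shot)
    # extended region keeps block composition
    arms = arms_of(grown)
    for start in range(0, 24, 4):
        assert arms[start : start + 4].count("A") == 2


def test_extension_requires_generator_state():
    lst = RandomizationList("AABB", 4)
    with pytest.raises(ValueError):
        lst.extend(1)


# ------------------------------------------------------- allocation examples


def make_list(arms, used=(), crossed=()):
    lst = RandomizationList(list(arms), 4)
    for pos in used:
        lst.apply(AllocationDecision(ASSIGNED, pos, arms[pos - 1]))
    for pos in crossed:
        lst._states[pos - 1] = CROSSED_OUT  # direct, for test setup only
        if pos - 1 in lst._gaps:
            lst._gaps.remove(pos - 1)
    return lst


def test_fr0a_refuses_when_one_arm_out():
    lst = make_list("AABBABBA", used=(1, 2))
    d = next_assignment(lst, {"A": 0, "B": 3}, IRTConfig("FR0a"))
    assert d.outcome == REFUSED and not d.forced


def test_fr1a_forces_and_crosses_out_skipped_position():
    lst = make_list("AABBABBA", used=(1, 2, 3, 4))
    d = next_assignment(lst, {"A": 0, "B": 1}, IRTConfig("FR1a"))
    assert (d.outcome, d.position, d.arm, d.forced) == (ASSIGNED, 6, "B", True)
    assert d.crossed_out_positions == {5}
    lst.apply(d)
    assert lst.state_at(5) == CROSSED_OUT and lst.state_at(6) == USED


def test_fr1b_backfills_skipped_position():
    lst = make_list("AABBABBA", used=(1, 2, 3, 4, 6))
    d = next_assignment(lst, {"A": 4, "B": 4}, IRTConfig("FR1b"))
    assert (d.outcome, d.position, d.arm) == (ASSIGNED, 5, "A")
    assert d.backfill and not d.forced  # follows the first-free-number rule
    lst.apply(d)
    assert lst.state_at(5) == USED


def test_fr1b_skip_is_forced_but_frontier_assignment_is_not():
    lst = make_list("AABBABBA", used=(1, 2, 3, 4))
    d = next_assignment(lst, {"A": 0, "B": 2}, IRTConfig("FR1b"))
    assert (d.position, d.forced, d.backfill) == (6, True, False)
    lst.apply(d)
    assert lst.state_at(5) == FREE  # stays available for backfilling


@pytest.mark.parametrize("mode", MODES)
def test_full_availability_follows_schedule(mode):
    lst = make_list("AABBABBA")
    d = next_assignment(lst, {"A": 5, "B": 5}, IRTConfig(mode))
    assert (d.outcome, d.position, d.arm, d.forced) == (ASSIGNED, 1, "A", False)


def test_no_stock_outcomes():
    lst = make_list("AABBABBA")
    assert next_assignment(lst, {"A": 0, "B": 0}, IRTConfig("FR0b")).outcome == NO_STOCK
    assert next_assignment(lst, {"A": 0, "B": 0}, IRTConfig("FR1a")).outcome == NO_STOCK
    # FR0a classifies an empty site as a plain refusal (all-kits check fails)
    assert next_assignment(lst, {"A": 0, "B": 0}, IRTConfig("FR0a")).outcome == REFUSED


def test_negative_stock_and_empty_list_rejected():
    lst = make_list("AABBABBA")
    with pytest.raises(ValueError):
        next_assignment(lst, {"A": -1, "B": 2}, IRTConfig("FR0b"))
    with pytest.raises(ValueError):
        next_assignment(RandomizationList([], 4), {"A": 1, "B": 1}, IRTConfig("FR0b"))


def test_exhausted_cap_reverts_to_next_kit_rule():
    lst = make_list("AABBABBA", used=(1, 2, 3, 4))
    cfg = IRTConfig("FR1a", forced_cap=2)
    d = next_assignment(lst, {"A": 0, "B": 1}, cfg, forced_so_far=2)
    assert d.outcome == REFUSED  # FR0b behaviour: scheduled arm missing
    d = next_assignment(lst, {"A": 0, "B": 1}, cfg, forced_so_far=1)
    assert d.outcome == ASSIGNED and d.forced


def test_irt_config_validation():
    with pytest.raises(ValueError):
        IRTConfig("FR2x")
    with pytest.raises(ValueError):
        IRTConfig("FR0a", forced_cap=3)
    with pytest.raises(ValueError):
        IRTConfig("FR1a", forced_cap=-1)


# ---------------------------------------------------- exhaustive oracle check


def two_block_lists():
    blocks = sorted({"".join(p) for p in itertools.permutations("AABB")})
    for b1, b2 in itertools.product(blocks, blocks):
        yield b1 + b2


STOCK_STATES = [{"A": 1, "B": 1}, {"A": 0, "B": 2}, {"A": 2, "B": 0}, {"A": 0, "B": 0}]


@pytest.mark.parametrize("mode", MODES)
def test_matches_brute_force_oracle_on_all_small_instances(mode):
    """Drive every 8-position two-block schedule through every length-4
    availability sequence and compare decisions and list states against an
    independent flat-scan implementation of the rules."""
    cfg = IRTConfig(mode)
    for arms in two_block_lists():
        for seq in itertools.product(range(4), repeat=4):
            lst = RandomizationList(list(arms), 4)
            ref_states = [FREE] * 8
            for k in seq:
                stock = STOCK_STATES[k]
                try:
                    expected = ref_decide(list(arms), ref_states, stock, mode)
                except ValueError:
                    # exhausted schedule: production must refuse identically
                    with pytest.raises(ValueError):
                        next_assignment(lst, stock, cfg)
                    break
                got = next_assignment(lst, stock, cfg)
                assert got.outcome == expected[0]
                if got.outcome == ASSIGNED:
                    assert (got.position, got.arm, got.forced) == expected[1:4]
                    assert set(got.crossed_out_positions) == expected[4]
                    lst.apply(got)
                    ref_apply(ref_states, expected)
                assert [s for _, _, s in lst.entries] == ref_states


# ------------------------------------------------------------ property tests


@st.composite
def list_and_stocks(draw):
    n_blocks = draw(st.integers(1, 5))
    seed = draw(st.integers(0, 10_000))
    stocks = draw(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 3)),
            min_size=1, max_size=2 * n_blocks,
        )
    )
    return n_blocks, seed, stocks


@given(list_and_stocks())
def test_unforced_modes_never_force_and_forcing_modes_never_refuse(params):
    n_blocks, seed, stocks = params
    for mode in MODES:
        lst = generate_permuted_block_list(4 * n_blocks, 4, seed)
        cfg = IRTConfig(mode)
        for a, b in stocks:
            if lst.n_untouched_tail < 4:
                break
            d = next_assignment(lst, {"A": a, "B": b}, cfg)
            if mode in ("FR0a", "FR0b"):
                assert not d.forced
            if mode in ("FR1a", "FR1b") and a + b > 0:
                assert d.outcome == ASSIGNED
            lst.apply(d)


@given(st.integers(0, 10_000), st.integers(1, 6))
def test_unlimited_stock_reduces_every_mode_to_the_schedule(seed, n_blocks):
    schedules = []
    for mode in MODES:
        lst = generate_permuted_block_list(4 * n_blocks, 4, seed)
        seq = []
        for _ in range(4 * n_blocks):
            d = next_assignment(lst, {"A": 99, "B": 99}, IRTConfig(mode))
            assert not d.forced
            lst.apply(d)
            seq.append((d.position, d.arm))
        schedules.append(seq)
        assert [p for p, _ in seq] == list(range(1, 4 * n_blocks + 1))
    assert all(s == schedules[0] for s in schedules)


@given(st.integers(0, 10_000))
def test_fr1b_backfilled_blocks_end_balanced(seed):
    """Skip-then-backfill trajectories keep |#A - #B| = 0 once every
    skipped position is filled and a whole number of blocks is used."""
    lst = generate_permuted_block_list(8, 4, seed)
    cfg = IRTConfig("FR1b")
    assigned = []
    # drain A availability to force skips, then restore it
    for stock in [{"A": 9, "B": 9}] * 2 + [{"A": 0, "B": 9}] * 2 + [{"A": 9, "B": 9}] * 4:
        d = next_assignment(lst, stock, cfg)
        lst.apply(d)
        assigned.append(d.arm)
    assert len(assigned) == 8
    assert assigned.count("A") == assigned.count("B") == 4
    assert lst.counts()[USED] == 8  # used positions equal patients assigned


def test_fr1a_consumes_used_plus_crossed():
    lst = generate_permuted_block_list(16, 4, seed=3)
    cfg = IRTConfig("FR1a")
    stocks = [{"A": 9, "B": 9}, {"A": 0, "B": 9}, {"A": 9, "B": 0}, {"A": 9, "B": 9}]
    patients = 0
    for stock in stocks:
        d = next_assignment(lst, stock, cfg)
        lst.apply(d)
        patients += 1
    counts = lst.counts()
    assert counts[USED] == patients
    frontier_consumed = max(p for p, _, s in lst.entries if s != FREE)
    assert counts[USED] + counts[CROSSED_OUT] == frontier_consumed


# ------------------------------------------------------------------- CSV I/O


def test_csv_round_trip_is_bit_exact(tmp_path):
    lst = generate_permuted_block_list(16, 4, seed=11)
    for stock in [{"A": 9, "B": 9}, {"A": 0, "B": 9}, {"A": 9, "B": 9}]:
        lst.apply(next_assignment(lst, stock, IRTConfig("FR1a")))
    path = tmp_path / "schedule.csv"
    lst.to_csv(path)
    back = RandomizationList.from_csv(path, block_size=4)
    assert back.entries == lst.entries
    assert back.lowest_free == lst.lowest_free


def test_scrambled_display_ids_are_a_seeded_bijection(tmp_path):
    lst = generate_permuted_block_list(16, 4, seed=11)
    ids = lst.display_ids(seed=99)
    assert sorted(ids.values()) == list(range(1, 17))
    assert ids == lst.display_ids(seed=99)
    assert ids != lst.display_ids(seed=100)
    # scrambling is presentation-only: the exported arms/states are unchanged
    plain, scrambled = tmp_path / "a.csv", tmp_path / "b.csv"
    lst.to_csv(plain)
    lst.to_csv(scrambled, display_seed=99)
    cols = lambda p: [r.rsplit(",")[2:] for r in p.read_text().splitlines()]
    assert cols(plain) == cols(scrambled)
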
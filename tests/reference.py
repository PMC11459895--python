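"""Independent brute-force reference for the four IRT allocation rules.

Operates directly on flat ``(arm, state)`` lists with a literal transcription
of each rule — no frontier/gap caching — so it can serve as an oracle for the
production implementation on small instances.
"""

FREE, USED, CROSSED = "FREE", "USED", "CROSSED_OUT"


def ref_decide(arms, states, stock, mode):
    """Return (outcome, position, arm, forced, crossed_positions) with
    1-based positions, or refusal markers, by direct scanning."""
    free = [i for i, s in enumerate(states) if s == FREE]
    if not free:
        raise ValueError("no free positions")
    lowest = free[0]
    total = stock["A"] + stock["B"]

    if mode == "FR0a":
        if stock["A"] == 0 or stock["B"] == 0:
            return ("REFUSED", None, None, False, set())
        return ("ASSIGNED", lowest + 1, arms[lowest], False, set())

    if mode == "FR0b":
        if stock[arms[lowest]] > 0:
            return ("ASSIGNED", lowest + 1, arms[lowest], False, set())
        if total == 0:
            return ("NO_STOCK", None, None, False, set())
        return ("REFUSED", None, None, False, set())

    # FR1a / FR1b
    if total == 0:
        return ("NO_STOCK", None, None, False, set())
    chosen = None
    skipped = []
    for i in free:
        if stock[arms[i]] > 0:
            chosen = i
            break
        skipped.append(i)
    if chosen is None:
        raise ValueError("list exhausted")
    forced = chosen != lowest
    crossed = {i + 1 for i in skipped} if (mode == "FR1a" and forced) else set()
    return ("ASSIGNED", chosen + 1, arms[chosen], forced, crossed)


def ref_apply(states, decision):
    outcome, pos, _arm, _forced, crossed = decision
    if outcome != "ASSIGNED":
        return
    states[pos - 1] = USED
    for c in crossed:
        states[c - 1] = CROSSED
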
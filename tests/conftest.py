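import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_script():
    from frsim import fig2_script

    return fig2_script()


#: Per-patient expected outcomes of the packaged single-site worked example,
#: per IRT mode: (patient_id, arm, list_position, forced, ever_sent_home).
#: Patients 1-2 draw down drug A; 3-5 face an A stock-out; a (2A, 2B)
#: delivery lands between patients 5 and 6.
TOY_EXPECTED = {
    # all-kit check: 3-5 sent home, randomized at the delivery into positions
    # 3-5 (B,B,A); 6-8 proceed as scheduled (B,B,A)
    "FR0a": [
        (1, "A", 1, False, False), (2, "A", 2, False, False),
        (3, "B", 3, False, True), (4, "B", 4, False, True),
        (5, "A", 5, False, True), (6, "B", 6, False, False),
        (7, "B", 7, False, False), (8, "A", 8, False, False),
    ],
    # next-kit check: only patient 5 refused; fills position 5 at delivery
    "FR0b": [
        (1, "A", 1, False, False), (2, "A", 2, False, False),
        (3, "B", 3, False, False), (4, "B", 4, False, False),
        (5, "A", 5, False, True), (6, "B", 6, False, False),
        (7, "B", 7, False, False), (8, "A", 8, False, False),
    ],
    # forcing without backfill: patient 5 forced past position 5 (crossed
    # out); the schedule then continues at position 7, consuming a 9th
    "FR1a": [
        (1, "A", 1, False, False), (2, "A", 2, False, False),
        (3, "B", 3, False, False), (4, "B", 4, False, False),
        (5, "B", 6, True, False), (6, "B", 7, False, False),
        (7, "A", 8, False, False), (8, "A", 9, False, False),
    ],
    # forcing with backfill: patient 5 forced to position 6; patient 6
    # backfills position 5 (flagged backfill, not a forced deviation)
    "FR1b": [
        (1, "A", 1, False, False), (2, "A", 2, False, False),
        (3, "B", 3, False, False), (4, "B", 4, False, False),
        (5, "B", 6, True, False), (6, "A", 5, False, False),
        (7, "B", 7, False, False), (8, "A", 8, False, False),
    ],
}
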
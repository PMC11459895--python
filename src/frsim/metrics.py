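"""Operating characteristics per replicate and Monte Carlo summaries.

Seven characteristics are computed from each replicate's event log and
patient records:

* ``imbalance`` — |#A − #B| among randomized patients at stop (reported as
  a non-negative magnitude);
* ``prop_forced`` — forced allocations / target n;
* ``prop_sent_home`` — distinct patients refused for a missing kit type,
  divided by the *target* sample size n;
* ``n_waitlisted`` — distinct patients who ever waited for a delivery;
* ``n_not_allocated`` — patients still waiting when recruitment completed;
* ``overage`` — (total kits shipped − n) / n, the ideal amount being one
  kit per randomized patient (n/2 per arm);
* ``completion_time`` — day of the n-th randomization.

Across replicates, summaries report the mean, the sample SD (n−1
denominator), the 90% upper-limit half-width 1.645·SD, and quantiles
(including the 90th percentile of the forced count, used to size a
forced-allocation cap).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import NOT_ALLOCATED, ScenarioConfig, TrialResult

HALF_WIDTH_Z = 1.645  # error-bar convention: 90% upper confidence limit


@dataclass(frozen=True)
class OperatingCharacteristics:
    imbalance: int
    prop_forced: float
    prop_sent_home: float
    n_waitlisted: int
    n_not_allocated: int
    overage: float
    completion_time: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRICS = [f.name for f in fields(OperatingCharacteristics)]


def compute_operating_characteristics(
    log, patients, config: ScenarioConfig
) -> OperatingCharacteristics:
    """Compute the seven characteristics exactly from one replicate's event
    log and patient records."""
    if log.stop_time is None:
        raise ValueError("replicate did not reach STOP")
    n = config.n
    n_a = sum(1 for p in patients if p.arm == "A")
    n_b = sum(1 for p in patients if p.arm == "B")
    n_forced = sum(1 for p in patients if p.forced)
    n_sent_home = sum(1 for p in patients if p.ever_sent_home)
    n_waitlisted = sum(1 for p in patients if p.ever_waitlisted)
    n_not_allocated = sum(1 for p in patients if p.status == NOT_ALLOCATED)

    shipped = 0
    completion = None
    n_randomized = 0
    for t, kind, payload in log:
        if kind == "ACTIVATION":
            shipped += payload["qty_A"] + payload["qty_B"]
        elif kind == "REVIEW":
            shipped += sum(o["qty_A"] + o["qty_B"] for o in payload["orders"])
        elif kind == "RANDOMIZATION":
            n_randomized += 1
            if n_randomized == n:
                completion = t
    if completion is None:
        completion = log.stop_time

    return OperatingCharacteristics(
        imbalance=abs(n_a - n_b),
        prop_forced=n_forced / n,
        prop_sent_home=n_sent_home / n,
        n_waitlisted=n_waitlisted,
        n_not_allocated=n_not_allocated,
        overage=(shipped - n) / n,
        completion_time=completion,
    )


def characteristics_of(result: TrialResult, config: Optional[ScenarioConfig] = None
                       ) -> OperatingCharacteristics:
    """Convenience wrapper taking a :class:`TrialResult`."""
    cfg = config if config is not None else result.config
    if cfg is None:
        raise ValueError("no scenario config attached to the result")
    return compute_operating_characteristics(result.events, result.patients, cfg)


def conservation_audit(result: TrialResult) -> dict:
    """Kit-conservation check for one replicate: every kit shipped is
    either dispensed, on site, or in transit at stop; kits dispensed equal
    the number of randomized patients."""
    balanced = (
        result.kits_shipped
        == result.kits_dispensed + result.kits_on_site + result.kits_in_transit
    )
    return {
        "balanced": balanced,
        "dispensed_equals_randomized": result.kits_dispensed == result.n_randomized,
        "shipped": result.kits_shipped,
        "dispensed": result.kits_dispensed,
        "on_site": result.kits_on_site,
        "in_transit": result.kits_in_transit,
    }


@dataclass
class MonteCarloSummary:
    """Monte Carlo summary over replicates.

    ``table`` has one row per characteristic with columns mean, sd,
    half_width (= 1.645·SD exactly), and the 10/50/90% quantiles.
    ``replicates`` keeps the per-replicate values; ``forced_count_q90`` is
    the empirical 90th percentile of the forced count.
    """

    table: pd.DataFrame
    replicates: pd.DataFrame
    n_reps: int
    n_target: Optional[int] = None
    degenerate_sd: bool = False  # single replicate: SD reported as 0

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    @property
    def forced_count_q90(self) -> float:
        if self.n_target is None:
            raise ValueError("target n unknown; cannot convert proportions to counts")
        return float(np.quantile(self.replicates["prop_forced"] * self.n_target, 0.9))

    def frac_forced_below_cap(self, cap: int) -> float:
        """Fraction of replicates whose forced count stays at or below a
        prospective forced-allocation cap."""
        if self.n_target is None:
            raise ValueError("target n unknown; cannot convert proportions to counts")
        counts = np.rint(self.replicates["prop_forced"] * self.n_target)
        return float(np.mean(counts <= cap))


def summarize_monte_carlo(
    ocs: Sequence[OperatingCharacteristics],
    n_target: Optional[int] = None,
) -> MonteCarloSummary:
    """Means, SDs (n−1), 1.645·SD half-widths and quantiles per
    characteristic.  A single replicate yields SD = 0 with
    ``degenerate_sd=True``."""
    ocs = list(ocs)
    if not ocs:
        raise ValueError("no replicates to summarize")
    reps = pd.DataFrame([oc.as_dict() for oc in ocs])
    degenerate = len(ocs) < 2
    sd = reps.std(ddof=1).fillna(0.0) if not degenerate else reps.iloc[0] * 0.0
    table = pd.DataFrame(
        {
            "mean": reps.mean(),
            "sd": sd,
            "half_width": HALF_WIDTH_Z * sd,
            "q10": reps.quantile(0.10),
            "q50": reps.quantile(0.50),
            "q90": reps.quantile(0.90),
        }
    )
    return MonteCarloSummary(table, reps, len(ocs), n_target, degenerate)
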
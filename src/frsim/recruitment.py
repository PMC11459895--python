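"""Poisson-gamma patient recruitment across study sites.

Site ``i`` activates at ``u_i ~ Uniform(0, W)`` and thereafter recruits
patients as a homogeneous Poisson process with rate ``lambda_i``, where the
per-site rates are i.i.d. ``Gamma(shape=alpha, rate=beta)`` (density
``beta^alpha / Gamma(alpha) * x^(alpha-1) * exp(-beta*x)``), so
``E[lambda] = alpha/beta`` and ``Var[lambda] = alpha/beta**2``.  Sites
follow a competitive recruitment policy: there is no per-site cap, and the
merged arrival stream is consumed until the trial engine stops recruitment.

Time unit is days throughout; one month is taken as 30 days, so "activated
during the first 4 months" means ``W = 120`` days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 30.0


@dataclass(frozen=True)
class RecruitmentModel:
    """Poisson-gamma recruitment hyperparameters.

    ``n_sites`` centers activate uniformly over ``[0, activation_window]``
    days; per-site recruitment rates (patients/day) are
    ``Gamma(shape=alpha, rate=beta)``.
    """

    n_sites: int
    alpha: float
    beta: float
    activation_window: float = 4 * DAYS_PER_MONTH

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("gamma shape and rate must be positive")
        if self.activation_window < 0:
            raise ValueError("activation_window must be >= 0")

    @property
    def mean_rate(self) -> float:
        """Mean recruitment rate per site per day, m = alpha / beta."""
        return self.alpha / self.beta


@dataclass(frozen=True)
class SiteProfile:
    site_id: int
    activation_time: float  # days
    rate: float             # patients / day

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("site rate must be positive")
        if self.activation_time < 0:
            raise ValueError("activation time must be >= 0")


def sample_sites(model: RecruitmentModel, seed) -> list[SiteProfile]:
    """Draw activation times and recruitment rates for all sites.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    rates = rng.gamma(shape=model.alpha, scale=1.0 / model.beta, size=model.n_sites)
    activations = rng.uniform(0.0, model.activation_window, size=model.n_sites)
    # gamma(shape<1) can underflow to 0.0 at double precision; nudge to the
    # smallest positive normal so downstream exponential waits stay finite
    rates = np.maximum(rates, np.finfo(float).tiny)
    return [
        SiteProfile(i, float(activations[i]), float(rates[i]))
        for i in range(model.n_sites)
    ]


def arrivals_for_site(profile: SiteProfile, rng: np.random.Generator) -> Iterator[float]:
    """Unbounded stream of arrival times (days) for one site.

    A homogeneous Poisson process of rate ``profile.rate`` starting at the
    activation time: no arrivals before activation, i.i.d. exponential
    inter-arrival gaps afterwards.
    """
    t = profile.activation_time
    mean_gap = 1.0 / profile.rate
    while True:
        t += rng.exponential(mean_gap)
        yield t


def sites_to_frame(sites: list[SiteProfile]) -> pd.DataFrame:
    """Site table: site_id, activation_day, rate_per_day."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "activation_day": [s.activation_time for s in sites],
            "rate_per_day": [s.rate for s in sites],
        }
    )


def sites_to_csv(sites: list[SiteProfile], path) -> None:
    sites_to_frame(sites).to_csv(path, index=False)
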
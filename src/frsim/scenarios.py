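"""Scenario presets, configuration I/O and Monte Carlo grid orchestration.

The study design compares 12 approaches — four IRT configurations (FR0a,
FR0b, FR1a, FR1b) crossed with three re-supply strategies (Low, Medium,
High) — under three recruitment scenarios:

* ``base``   — per-site rates Gamma(1.2, 16), mean 0.075 patients/site/day;
* ``slower`` — Gamma(1.2, 28), mean 0.3 patients/site/week;
* ``faster`` — Gamma(1.2, 5), mean 1.68 patients/site/week;

each at two trial sizes: 500 patients across 80 sites (default) or 100
patients across 16 sites (suffix ``_small``).  Site activation is uniform
over the first 4 months (120 days) in every scenario.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .engine import ScenarioConfig, run_trial
from .metrics import METRICS, MonteCarloSummary, characteristics_of, summarize_monte_carlo
from .randomization import IRT_MODES, IRTConfig
from .recruitment import RecruitmentModel
from .supply import STRATEGIES, SupplyStrategy

_BETAS = {"base": 16.0, "slower": 28.0, "faster": 5.0}
_SIZES = {"": (500, 80), "_small": (100, 16)}

#: label -> (n, N, alpha, beta, activation window days)
PRESETS: dict[str, tuple] = {
    f"{scen}{suffix}": (n, N, 1.2, beta, 120.0)
    for scen, beta in _BETAS.items()
    for suffix, (n, N) in _SIZES.items()
}


def preset_config(
    scenario: str,
    irt_mode: str,
    supply: str | SupplyStrategy,
    forced_cap: Optional[int] = None,
    seed: Optional[int] = None,
) -> ScenarioConfig:
    """Build the :class:`ScenarioConfig` for one cell of the study grid."""
    if scenario not in PRESETS:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {sorted(PRESETS)}")
    if irt_mode not in IRT_MODES:
        raise ValueError(f"unknown IRT mode {irt_mode!r}; valid: {list(IRT_MODES)}")
    if isinstance(supply, str):
        if supply not in STRATEGIES:
            raise ValueError(f"unknown supply strategy {supply!r}; valid: {sorted(STRATEGIES)}")
        supply = STRATEGIES[supply]
    n, n_sites, alpha, beta, window = PRESETS[scenario]
    return ScenarioConfig(
        n=n,
        recruitment=RecruitmentModel(n_sites, alpha, beta, window),
        supply=supply,
        irt=IRTConfig(irt_mode, forced_cap=forced_cap),
        label=scenario,
        seed=seed,
    )


def derive_seed(master_seed: int, scenario: str, rep: int) -> int:
    """Per-replicate seed, a pure function of (master seed, scenario, rep).

    Independent of execution order or worker count, and *shared across IRT
    modes and supply strategies* so approaches are compared under common
    random numbers.  Kept below 2**31.
    """
    scen_idx = sorted(PRESETS).index(scenario)
    ss = np.random.SeedSequence([int(master_seed), scen_idx, int(rep)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_cell(
    scenario: str,
    irt_mode: str,
    supply: str | SupplyStrategy,
    n_reps: int,
    master_seed: int,
    forced_cap: Optional[int] = None,
    progress: bool = False,
) -> MonteCarloSummary:
    """Monte Carlo over one (scenario, IRT mode, supply strategy) cell."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = preset_config(scenario, irt_mode, supply, forced_cap=forced_cap)
    reps: Iterable[int] = range(n_reps)
    if progress:
        from tqdm import tqdm

        reps = tqdm(reps, desc=f"{scenario}/{irt_mode}/{getattr(supply, 'name', supply)}",
                    leave=False)
    ocs = []
    for rep in reps:
        result = run_trial(config, derive_seed(master_seed, scenario, rep))
        ocs.append(characteristics_of(result, config))
    return summarize_monte_carlo(ocs, n_target=config.n)


def run_grid(
    scenarios: Sequence[str],
    irt_modes: Sequence[str],
    supply_strategies: Sequence[str],
    n_reps: int,
    master_seed: int,
    progress: bool = False,
) -> pd.DataFrame:
    """Full factorial of the study grid; one row per cell with mean, SD and
    quantiles of every operating characteristic.  Reproducible from the
    master seed alone."""
    rows = []
    for scenario in scenarios:
        for mode in irt_modes:
            for strat in supply_strategies:
                summ = run_cell(scenario, mode, strat, n_reps, master_seed,
                                progress=progress)
                row = {"scenario": scenario, "irt_mode": mode, "supply": strat,
                       "n_reps": summ.n_reps}
                for m in METRICS:
                    row[f"{m}_mean"] = summ.table.loc[m, "mean"]
                    row[f"{m}_sd"] = summ.table.loc[m, "sd"]
                    row[f"{m}_q90"] = summ.table.loc[m, "q90"]
                row["forced_count_q90"] = summ.forced_count_q90
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- config I/O

_TOP_KEYS = {"n", "n_sites", "alpha", "beta", "activation_window_days",
             "irt_mode", "supply", "forced_cap", "seed"}
_SUPPLY_KEYS = {"initial_A", "initial_B", "crit", "target_A", "target_B",
                "review_days", "lead_days"}


def load_config(path) -> ScenarioConfig:
    """Read a scenario configuration from a YAML or JSON file.

    Exactly the documented keys are required; missing or extra keys are
    rejected by name.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    missing = _TOP_KEYS - raw.keys()
    extra = raw.keys() - _TOP_KEYS
    if missing:
        raise ValueError(f"missing config key(s): {sorted(missing)}")
    if extra:
        raise ValueError(f"unknown config key(s): {sorted(extra)}")
    sup = raw["supply"]
    s_missing = _SUPPLY_KEYS - sup.keys()
    s_extra = sup.keys() - _SUPPLY_KEYS
    if s_missing:
        raise ValueError(f"missing supply key(s): {sorted(s_missing)}")
    if s_extra:
        raise ValueError(f"unknown supply key(s): {sorted(s_extra)}")
    strategy = SupplyStrategy(
        (int(sup["initial_A"]), int(sup["initial_B"])),
        int(sup["crit"]),
        (int(sup["target_A"]), int(sup["target_B"])),
        float(sup["review_days"]),
        float(sup["lead_days"]),
    )
    cap = raw["forced_cap"]
    return ScenarioConfig(
        n=int(raw["n"]),
        recruitment=RecruitmentModel(int(raw["n_sites"]), float(raw["alpha"]),
                                     float(raw["beta"]),
                                     float(raw["activation_window_days"])),
        supply=strategy,
        irt=IRTConfig(raw["irt_mode"], forced_cap=None if cap is None else int(cap)),
        seed=None if raw["seed"] is None else int(raw["seed"]),
    )


def write_config(config: ScenarioConfig, path) -> None:
    """Write a scenario configuration; ``load_config(write_config(c)) == c``."""
    payload = {
        "n": config.n,
        "n_sites": config.recruitment.n_sites,
        "alpha": config.recruitment.alpha,
        "beta": config.recruitment.beta,
        "activation_window_days": config.recruitment.activation_window,
        "irt_mode": config.irt.mode,
        "supply": {
            "initial_A": config.supply.initial[0],
            "initial_B": config.supply.initial[1],
            "crit": config.supply.crit,
            "target_A": config.supply.target[0],
            "target_B": config.supply.target[1],
            "review_days": config.supply.review_interval,
            "lead_days": config.supply.lead_time,
        },
        "forced_cap": config.irt.forced_cap,
        "seed": config.seed,
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def write_results(table: pd.DataFrame, path, manifest: Optional[dict] = None) -> None:
    """Write a results table as CSV plus a JSON run-manifest for provenance."""
    path = Path(path)
    table.to_csv(path, index=False)
    if manifest is not None:
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
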
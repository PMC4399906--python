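"""Power-study harness: rejection rates of GWSS methods over scenario grids.

For each scenario, ``n_replicates`` datasets are simulated; every method is
run on the *same* datasets and the same permutation streams (common random
numbers), so power differences between methods are not inflated by
simulation noise.  A cell is the rejection proportion p-hat = #{p <= alpha}
/ R, reported with its Monte-Carlo standard error sqrt(p-hat(1-p-hat)/R).

Seeding: a master seed spawns one child stream per (scenario, replicate)
via ``numpy.random.SeedSequence``, so any cell — and any single replicate —
is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .gwss_test import permutation_test, resolve_method
from .simulate import ScenarioSpec, sample_case_control

__all__ = ["StudyConfig", "PowerTable", "run_replicates", "run_cell", "run_study"]


@dataclass
class StudyConfig:
    """A scenario x method grid with replication settings.

    Defaults mirror the reference study design: 1000 replicates, 500
    permutations per test, alpha = 0.05.  Scaled-down desk presets
    (e.g. 300 replicates / 200 permutations) trade Monte-Carlo precision
    for runtime; standard errors make the trade explicit.
    """

    scenarios: Dict[str, ScenarioSpec]
    methods: List[str]
    n_replicates: int = 1000
    n_permutations: int = 500
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1 or self.n_permutations < 1:
            raise ValueError("replicates and permutations must be >= 1")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        for m in self.methods:
            resolve_method(m)


@dataclass
class PowerTable:
    """Method x scenario rejection proportions with standard errors."""

    power: pd.DataFrame  # rows: methods, cols: scenario labels
    se: pd.DataFrame
    n_replicates: int
    n_permutations: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: method, scenario, power, se, replicates."""
        rows = []
        for m in self.power.index:
            for s in self.power.columns:
                rows.append({"method": m, "scenario": s,
                             "power": self.power.loc[m, s],
                             "se": self.se.loc[m, s],
                             "n_replicates": self.n_replicates,
                             "n_permutations": self.n_permutations,
                             "alpha": self.alpha})
        return pd.DataFrame(rows)


def _scenario_seed_seq(master_seed: int, scenario_label: str) -> np.random.SeedSequence:
    # stable per-label entropy so adding scenarios does not shift streams
    digest = hashlib.sha256(scenario_label.encode()).digest()[:8]
    return np.random.SeedSequence([master_seed, int.from_bytes(digest, "little")])


def run_replicates(spec: ScenarioSpec, methods, n_replicates: int,
                   n_permutations: int, seed_seq=None, seed: int = 0,
                   progress=None):
    """p-values of each method over replicate datasets of one scenario.

    Returns a DataFrame (replicate x method) of permutation p-values; all
    methods see identical datasets and permutation streams.
    """
    methods = [resolve_method(m) for m in methods]
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(n_replicates)
    pvals = {m.name: np.empty(n_replicates) for m in methods}
    for r in range(n_replicates):
        rng = np.random.default_rng(children[r])
        ds = sample_case_control(spec, rng=rng)
        res = permutation_test(ds.genotypes, ds.phenotype, methods,
                               n_permutations=n_permutations, rng=rng)
        for name, tr in res.items():
            pvals[name][r] = tr.p_value
        if progress is not None:
            progress(r + 1, n_replicates)
    return pd.DataFrame(pvals)


def run_cell(spec: ScenarioSpec, method, config: StudyConfig,
             scenario_label: str = "scenario"):
    """Rejection proportion and SE of one method in one scenario."""
    df = run_replicates(spec, [method], config.n_replicates,
                        config.n_permutations,
                        seed_seq=_scenario_seed_seq(config.master_seed, scenario_label))
    name = resolve_method(method).name
    rej = float((df[name] <= config.alpha).mean())
    se = float(np.sqrt(rej * (1.0 - rej) / config.n_replicates))
    return rej, se


def _cell_key(config: StudyConfig, label: str) -> str:
    spec = config.scenarios[label]
    payload = json.dumps({"scenario": asdict(spec), "label": label,
                          "methods": sorted(config.methods),
                          "R": config.n_replicates, "B": config.n_permutations,
                          "seed": config.master_seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_study(config: StudyConfig, cache_dir: Optional[str] = None,
              progress=None, save_pvalues: Optional[str] = None) -> PowerTable:
    """Run the full method x scenario grid.

    ``cache_dir`` caches per-scenario p-value archives keyed by a config
    hash, making long grids resumable; ``save_pvalues`` additionally writes
    the per-replicate p-values (audit trail) as CSV per scenario.
    """
    power = pd.DataFrame(index=[resolve_method(m).name for m in config.methods],
                         columns=list(config.scenarios), dtype=float)
    se = power.copy()
    for label, spec in config.scenarios.items():
        df = None
        cache_file = None
        if cache_dir is not None:
            cache_file = Path(cache_dir) / f"cell-{label}-{_cell_key(config, label)}.csv"
            if cache_file.exists():
                df = pd.read_csv(cache_file)
        if df is None:
            df = run_replicates(
                spec, config.methods, config.n_replicates, config.n_permutations,
                seed_seq=_scenario_seed_seq(config.master_seed, label),
                progress=(lambda r, R, _l=label: progress(_l, r, R)) if progress else None,
            )
            if cache_file is not None:
                cache_file.parent.mkdir(parents=True, exist_ok=True)
                df.to_csv(cache_file, index=False)
        if save_pvalues is not None:
            out = Path(save_pvalues)
            out.mkdir(parents=True, exist_ok=True)
            df.to_csv(out / f"pvalues-{label}.csv", index=False)
        for m in power.index:
            rej = float((df[m] <= config.alpha).mean())
            power.loc[m, label] = rej
            se.loc[m, label] = float(np.sqrt(rej * (1.0 - rej) / config.n_replicates))
    return PowerTable(power=power, se=se, n_replicates=config.n_replicates,
                      n_permutations=config.n_permutations, alpha=config.alpha)
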
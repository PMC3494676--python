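"""Scenario configuration, replicate loop, and summary tables.

A scenario is: found a base population of N individuals containing
``n_exogenous`` foreigners, let them mate at random for ``admix_generations``
generations, then apply a marker-guided management strategy for
``manage_generations`` generations (selection/contributions followed by
Hungarian minimum-coancestry mating).  Per-generation metrics are
recorded for every replicate; scenario summaries report the mean and
standard error across replicates of final-generation NR and F.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .genome import GeneticMap
from .management import (
    DistanceObjective,
    SASchedule,
    optimize_contributions_sa,
    truncation_plan,
)
from .markers import make_panel
from .mating import min_coancestry_matings
from .metrics import MetricsRecord, measure
from .population import admix_generation, breed, found_population

__all__ = ["ScenarioConfig", "run_replicate", "run_scenario", "table2_grid", "table3_grid"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulated scenario.

    ``strategy`` is ``marker_count`` (native-allele truncation, for
    diagnostic-style panels) or ``distance`` (simulated-annealing
    contribution optimization against ``distance_kind``).  ``cap`` limits
    offspring per parent (None, 5 or 10 in the study design).
    """

    N: int = 100
    n_exogenous: int = 10
    admix_generations: int = 5
    manage_generations: int = 10
    scheme: str = "diagnostic"
    n_markers: int = 20
    native_allele_freq: float | None = None
    strategy: str = "marker_count"
    distance_kind: str = "kl"
    cap: int | None = None
    map_length: float = 20.0
    n_loci: int = 2000
    replicates: int = 20
    base_seed: int = 0
    sa_schedule: SASchedule = field(default_factory=SASchedule)

    def __post_init__(self) -> None:
        if self.strategy not in ("marker_count", "distance"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.cap is not None and self.cap < 1:
            raise ValueError("cap must be >= 1")

    def with_seed(self, base_seed: int) -> "ScenarioConfig":
        return replace(self, base_seed=base_seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sa_schedule"] = asdict(self.sa_schedule)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sa_schedule" in d:
            d["sa_schedule"] = SASchedule(**d["sa_schedule"])
        return cls(**d)


def _records_to_frame(records: list[MetricsRecord], replicate: int) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "replicate": replicate,
            "generation": [r.generation for r in records],
            "nr": [r.nr for r in records],
            "mean_f": [r.mean_f for r in records],
            "mean_coancestry": [r.mean_coancestry for r in records],
            "obs_homozygosity": [r.obs_homozygosity for r in records],
            "ne": [r.ne for r in records],
            "n_contributing_parents": [r.n_contributing_parents for r in records],
        }
    )
    return df


def run_replicate(cfg: ScenarioConfig, replicate_index: int) -> pd.DataFrame:
    """Simulate one replicate; deterministic given (cfg, replicate_index).

    The replicate RNG is seeded with ``base_seed + replicate_index``.
    Returns the per-generation metrics table.
    """
    rng = np.random.default_rng(cfg.base_seed + replicate_index)
    panel = make_panel(cfg.scheme, cfg.n_markers, cfg.native_allele_freq)
    gmap = GeneticMap(cfg.map_length, cfg.n_loci, cfg.n_markers)
    pop, ped = found_population(cfg.N, cfg.n_exogenous, panel, gmap, rng)
    records = [measure(pop, ped)]
    for _ in range(cfg.admix_generations):
        pop = admix_generation(pop, ped, gmap, rng)
        records.append(measure(pop, ped, f_prev=records[-1].mean_f))
    objective = DistanceObjective(cfg.distance_kind, panel.native_freqs)
    for _ in range(cfg.manage_generations):
        if cfg.strategy == "marker_count":
            plan = truncation_plan(pop, panel, cfg.cap, rng)
        else:
            plan = optimize_contributions_sa(
                pop, objective, cfg.cap, rng, schedule=cfg.sa_schedule
            )
        kin = ped.kinship(pop.ids[plan.sire_idx], pop.ids[plan.dam_idx])
        matings = min_coancestry_matings(plan, kin, rng)
        pop = breed(pop, ped, matings.sire_idx, matings.dam_idx, gmap, rng)
        records.append(
            measure(pop, ped, f_prev=records[-1].mean_f, n_contributing=plan.n_contributing)
        )
    return _records_to_frame(records, replicate_index)


def run_scenario(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Run all replicates of a scenario.

    Returns the long per-generation table and a summary row with the mean
    and standard error across replicates of final-generation NR and F.
    """
    frames = [run_replicate(cfg, r) for r in range(cfg.replicates)]
    long = pd.concat(frames, ignore_index=True)
    final = long[long.generation == long.generation.max()]
    n = len(final)
    summary = pd.Series(
        {
            "nr_mean": final.nr.mean(),
            "nr_se": final.nr.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "f_mean": final.mean_f.mean(),
            "f_se": final.mean_f.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "replicates": n,
        }
    )
    return long, summary


def table2_grid(
    base_seed: int = 0,
    replicates: int = 20,
    freqs: tuple[float, ...] = (0.7, 0.8, 0.9, 0.95, 0.99),
    n_exo_levels: tuple[int, ...] = (10, 20, 30, 40, 50),
) -> list[ScenarioConfig]:
    """Scenario grid for the diagnostic-like frequency sweep.

    20 biallelic markers with native-allele frequency f in natives and
    0.5 in the exogenous population, truncation management, no cap.
    """
    return [
        ScenarioConfig(
            scheme="extra_diagnostic_like",
            native_allele_freq=f,
            n_exogenous=ne,
            strategy="marker_count",
            replicates=replicates,
            base_seed=base_seed,
        )
        for f in freqs
        for ne in n_exo_levels
    ]


def table3_grid(
    base_seed: int = 0,
    replicates: int = 20,
    schemes: tuple[str, ...] = ("diagnostic", "diagnostic_like", "non_diagnostic"),
    caps: tuple[int | None, ...] = (None, 10, 5),
    n_exo_levels: tuple[int, ...] = (10, 20, 30, 40, 50),
) -> list[ScenarioConfig]:
    """Scenario grid comparing marker schemes under offspring caps.

    Non-diagnostic panels are managed by KL-distance minimization; the
    biallelic schemes by native-allele truncation.
    """
    out = []
    for scheme in schemes:
        strategy = "distance" if scheme == "non_diagnostic" else "marker_count"
        for cap in caps:
            for ne in n_exo_levels:
                out.append(
                    ScenarioConfig(
                        scheme=scheme,
                        strategy=strategy,
                        distance_kind="kl",
                        cap=cap,
                        n_exogenous=ne,
                        replicates=replicates,
                        base_seed=base_seed,
                    )
                )
    return out


def run_grid(configs: list[ScenarioConfig]) -> pd.DataFrame:
    """Run a list of scenarios; one tidy summary row per scenario."""
    rows = []
    for cfg in configs:
        _, summary = run_scenario(cfg)
        row = {
            "scheme": cfg.scheme,
            "strategy": cfg.strategy,
            "cap": cfg.cap,
            "n_exogenous": cfg.n_exogenous,
            "native_allele_freq": cfg.native_allele_freq,
            **summary.to_dict(),
        }
        rows.append(row)
    return pd.DataFrame(rows)
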
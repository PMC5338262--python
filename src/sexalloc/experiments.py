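"""Scenario builders and the replicate runner.

Each builder returns a :class:`ScenarioSpec` encoding one of the standard
experimental designs: the ten-species resource ladder followed over 2,000
generations, the community-size sweep with 1,000 species, seed-dispersal
limitation, and the two-type heterogeneous environment.  A ``scale`` argument
divides both the community size N and the deme count D, preserving the deme
capacity and hence every species' initial density per pollen-dispersal area,
so scaled runs probe the same mating ecology at desk size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import (
    EnvironmentMap,
    SimulationConfig,
    SimulationResult,
    SpeciesTable,
    run_simulation,
)

__all__ = [
    "ScenarioSpec",
    "ReplicateBatch",
    "resource_ladder_community",
    "community_size_sweep",
    "seed_dispersal_limited",
    "heterogeneous_environment",
    "run_replicates",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A named, fully parameterised experiment with replicate count."""

    name: str
    config: SimulationConfig
    species_table: SpeciesTable
    env: EnvironmentMap
    n_replicates: int = 1
    record_every: int = 1

    def replicate_seeds(self) -> list[int]:
        """Deterministic per-replicate seeds: master seed + replicate index."""
        return [self.config.rng_seed + r for r in range(self.n_replicates)]


@dataclass
class ReplicateBatch:
    """Results of running every replicate of a scenario."""

    spec: ScenarioSpec
    results: list[SimulationResult]
    seeds: list[int]

    @property
    def final_richness(self) -> np.ndarray:
        return np.array([r.final_richness for r in self.results])

    @property
    def mean_richness(self) -> float:
        return float(self.final_richness.mean())

    @property
    def sd_richness(self) -> float:
        return float(self.final_richness.std(ddof=1)) if len(self.results) > 1 else 0.0


def _check_scale(total: int, scale: int, what: str) -> int:
    if scale < 1 or total % scale != 0:
        raise ValueError(f"scale={scale} does not divide {what}={total}")
    return total // scale


def resource_ladder_community(
    scale: int = 1,
    generations: int = 2000,
    mutation_rate: float = 1e-3,
    mutation_model: str = "uniform",
    seed: int = 0,
    n_replicates: int = 1,
    record_every: int = 1,
) -> ScenarioSpec:
    """Ten species on a resource ladder 2.0, 1.9, ..., 1.1 in a homogeneous
    environment with the fully global seed lottery.

    At scale 1 the community holds 10^6 individuals in 10^4 demes of 100;
    ``scale`` divides N and D jointly, keeping deme capacity (and thus each
    species' initial density) fixed.
    """
    n = _check_scale(10**6, scale, "N=10^6")
    d = _check_scale(10**4, scale, "D=10^4")
    cfg = SimulationConfig(
        n_individuals=n,
        n_demes=d,
        n_species=10,
        generations=generations,
        mutation_rate=mutation_rate,
        mutation_model=mutation_model,
        rng_seed=seed,
    )
    return ScenarioSpec(
        name="resource_ladder_community",
        config=cfg,
        species_table=SpeciesTable.ladder(10, hi=2.0, lo=1.1),
        env=EnvironmentMap.homogeneous(d),
        n_replicates=n_replicates,
        record_every=record_every,
    )


def community_size_sweep(
    total_n_grid=(10**4, 3 * 10**4, 10**5, 3 * 10**5),
    n_species: int = 1000,
    generations: int = 10000,
    n_replicates: int = 100,
    deme_capacity: int = 100,
    mutation_rate: float = 1e-3,
    mutation_model: str = "uniform",
    seed: int = 0,
    record_every: int = 100,
    resource_model: str = "ladder",
    rng: np.random.Generator | None = None,
) -> list[ScenarioSpec]:
    """One scenario per community size N: 1,000 species with resources
    spaced evenly from 2 down to 1.001, run to measure how final richness
    grows with the space available.

    ``resource_model="normal"`` instead draws resources from a normal
    distribution (mean 1.5, SD 0.25).
    """
    if resource_model == "ladder":
        table = SpeciesTable.ladder(n_species, hi=2.0, lo=1.001)
    elif resource_model == "normal":
        table = SpeciesTable.normal(n_species, rng=rng)
    else:
        raise ValueError("resource_model must be 'ladder' or 'normal'")
    specs = []
    for n in total_n_grid:
        if n % deme_capacity != 0:
            raise ValueError(f"N={n} is not divisible by deme capacity {deme_capacity}")
        d = n // deme_capacity
        cfg = SimulationConfig(
            n_individuals=n,
            n_demes=d,
            n_species=n_species,
            generations=generations,
            mutation_rate=mutation_rate,
            mutation_model=mutation_model,
            rng_seed=seed,
        )
        specs.append(
            ScenarioSpec(
                name=f"community_size_sweep_N{n}",
                config=cfg,
                species_table=table,
                env=EnvironmentMap.homogeneous(d),
                n_replicates=n_replicates,
                record_every=record_every,
            )
        )
    return specs


def seed_dispersal_limited(
    d: float = 0.01,
    scale: int = 1,
    n_species: int = 1000,
    generations: int = 10000,
    mutation_rate: float = 1e-3,
    mutation_model: str = "uniform",
    seed: int = 0,
    n_replicates: int = 1,
    record_every: int = 100,
) -> ScenarioSpec:
    """Seed dispersal restricted to a neighbourhood nested inside the pollen
    dispersal area: pollen areas hold 10^3 individuals and seed
    neighbourhoods 10^2, with long-distance dispersal probability ``d``.

    ``d = 1`` recovers the fully global lottery of the base model.
    """
    n = _check_scale(10**6, scale, "N=10^6")
    n_demes = _check_scale(10**3, scale, "D=10^3")
    cfg = SimulationConfig(
        n_individuals=n,
        n_demes=n_demes,
        n_species=n_species,
        generations=generations,
        mutation_rate=mutation_rate,
        mutation_model=mutation_model,
        long_distance_prob=d,
        seed_neighborhood_capacity=100,
        rng_seed=seed,
    )
    return ScenarioSpec(
        name="seed_dispersal_limited",
        config=cfg,
        species_table=SpeciesTable.ladder(n_species, hi=2.0, lo=1.001),
        env=EnvironmentMap.homogeneous(n_demes),
        n_replicates=n_replicates,
        record_every=record_every,
    )


def heterogeneous_environment(
    scale: int = 1,
    n_species: int = 1000,
    generations: int = 10000,
    mutation_rate: float = 1e-3,
    mutation_model: str = "uniform",
    seed: int = 0,
    n_replicates: int = 1,
    record_every: int = 100,
    deme_capacity: int = 100,
    long_distance_prob: float = 1.0,
    seed_neighborhood_capacity: int | None = None,
) -> ScenarioSpec:
    """Two environment types with exactly reversed resource rankings.

    Three quarters of the demes are the primary type (resources 2 down to
    1.001 along the species index); the remaining quarter reverses that
    ranking, so the species that is poorest in the primary environment is
    richest in the secondary one.  Other parameters follow the
    community-size sweep (deme capacity 100, 10^6 individuals at scale 1).
    Seed-dispersal limitation can be combined in via ``long_distance_prob``
    (with pollen areas of ``deme_capacity`` and seed neighbourhoods of
    ``seed_neighborhood_capacity`` individuals, as in the dispersal-limited
    scenario).
    """
    n = _check_scale(10**6, scale, "N=10^6")
    if n % deme_capacity != 0:
        raise ValueError(
            f"N={n} is not divisible by deme_capacity={deme_capacity}"
        )
    d = n // deme_capacity
    if d % 4 != 0:
        raise ValueError(f"number of demes D={d} must be divisible by 4")
    cfg = SimulationConfig(
        n_individuals=n,
        n_demes=d,
        n_species=n_species,
        generations=generations,
        mutation_rate=mutation_rate,
        mutation_model=mutation_model,
        long_distance_prob=long_distance_prob,
        seed_neighborhood_capacity=seed_neighborhood_capacity,
        rng_seed=seed,
    )
    return ScenarioSpec(
        name="heterogeneous_environment",
        config=cfg,
        species_table=SpeciesTable.reversed_pair(n_species, hi=2.0, lo=1.001),
        env=EnvironmentMap.two_types(d, fraction_primary=0.75),
        n_replicates=n_replicates,
        record_every=record_every,
    )


def run_replicates(spec: ScenarioSpec, progress: bool = False) -> ReplicateBatch:
    """Run all replicates of a scenario with deterministic per-replicate
    seeds (master + r) and collect their results."""
    results: list[SimulationResult] = []
    seeds = spec.replicate_seeds()
    for r, s in enumerate(seeds):
        cfg = replace(spec.config, rng_seed=s)
        try:
            res = run_simulation(
                cfg,
                species_table=spec.species_table,
                env=spec.env,
                record_every=spec.record_every,
            )
        except Exception as err:  # report the failing seed, then abort
            raise RuntimeError(
                f"replicate {r} of scenario {spec.name!r} failed with seed {s}"
            ) from err
        results.append(res)
        if progress:
            print(
                f"[{spec.name}] replicate {r + 1}/{len(seeds)} "
                f"(seed {s}): richness {res.final_richness}"
            )
    return ReplicateBatch(spec=spec, results=results, seeds=seeds)
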
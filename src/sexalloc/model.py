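"""Individual-based model of sex-allocation evolution in a plant community.

The community holds a fixed total of ``N`` haploid annual individuals arranged
in ``D`` equally sized local populations (demes); a deme is the pollen
dispersal area.  Each individual carries a heritable allocation gene
``g in (0, 1)`` and belongs to one of ``S`` species.  A species receives a
species-specific resource amount ``R`` (possibly depending on the deme's
environment type); ``g * R`` goes to seeds and ``(1 - g) * R`` to pollen.

One generation:

1. every seed is fertilised by a pollen grain drawn from the conspecific
   pollen pool of the mother's deme (selfing included, so a lone conspecific
   self-fertilises with certainty);
2. the ``N`` adults of the next generation are drawn by lottery from the
   community-wide seed pool, i.e. mothers are sampled with probability
   proportional to seed output ``g * R`` (with limited seed dispersal a slot
   recruits from its local seed neighbourhood instead, except for a small
   long-distance fraction ``d``);
3. each offspring inherits ``g`` from its mother or father with probability
   1/2 and mutates with probability ``mu`` per generation;
4. all adults die (annuals, no seed bank).

Seed output is treated as a continuous sampling weight and survivors are
independent weighted draws — exact in the large-seed-number limit of a
multinomial lottery over a discrete seed pool.

Individuals are stored in slot order: individual ``i`` occupies slot ``i`` and
slot ``i`` belongs to deme ``i // deme_capacity``.  This makes deme occupancy
exactly ``deme_capacity`` everywhere by construction, and makes seed
neighbourhoods contiguous slot blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SpeciesTable",
    "EnvironmentMap",
    "CommunityState",
    "SimulationResult",
    "init_community",
    "maternal_seed_weights",
    "paternal_pollen_weights",
    "mutate_genes",
    "sample_parents",
    "step_generation",
    "run_simulation",
    "census",
]

_OPEN_LO = np.nextafter(0.0, 1.0)
_OPEN_HI = np.nextafter(1.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulation run.

    Parameters
    ----------
    n_individuals : int
        Total community size ``N``, fixed over generations.
    n_demes : int
        Number of local populations ``D`` (pollen dispersal areas). Must
        divide ``N`` exactly.
    n_species : int
        Number of species ``S`` at initialisation.
    generations : int
        Number of generation updates to run.
    mutation_rate : float
        Per-locus, per-generation mutation probability (default 0.001).
    mutation_model : str
        ``"uniform"`` replaces the gene with a fresh Uniform(0, 1) draw;
        ``"perturbation"`` adds Normal(0, sigma) noise reflected back into
        (0, 1).
    mutation_sigma : float
        Kernel width for the perturbation model (default 0.05).
    long_distance_prob : float
        Probability ``d`` that a recruitment slot draws its mother from the
        whole community; ``1.0`` is the fully global seed lottery of the base
        model.  With ``d < 1`` the remaining slots recruit from their local
        seed neighbourhood.
    seed_neighborhood_capacity : int or None
        Number of slots per seed-dispersal neighbourhood (required when
        ``d < 1``; must divide the deme capacity).
    rng_seed : int
        Master seed for the run's random number generator.
    """

    n_individuals: int
    n_demes: int
    n_species: int
    generations: int
    mutation_rate: float = 1e-3
    mutation_model: str = "uniform"
    mutation_sigma: float = 0.05
    long_distance_prob: float = 1.0
    seed_neighborhood_capacity: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_demes < 1:
            raise ValueError("n_individuals and n_demes must be positive")
        if self.n_individuals % self.n_demes != 0:
            raise ValueError(
                f"n_individuals={self.n_individuals} is not divisible by "
                f"n_demes={self.n_demes}"
            )
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.mutation_model not in ("uniform", "perturbation"):
            raise ValueError(
                "mutation_model must be 'uniform' or 'perturbation'"
            )
        if not 0.0 <= self.long_distance_prob <= 1.0:
            raise ValueError("long_distance_prob must lie in [0, 1]")
        if self.long_distance_prob < 1.0:
            c = self.seed_neighborhood_capacity
            if c is None:
                raise ValueError(
                    "seed_neighborhood_capacity is required when "
                    "long_distance_prob < 1"
                )
            if c < 1 or self.deme_capacity % c != 0:
                raise ValueError(
                    f"seed_neighborhood_capacity={c} must divide "
                    f"deme_capacity={self.deme_capacity}"
                )

    @property
    def deme_capacity(self) -> int:
        """Individuals per deme, ``N / D``."""
        return self.n_individuals // self.n_demes


@dataclass(frozen=True)
class SpeciesTable:
    """Species-specific resource amounts per environment type.

    ``resources`` has shape ``(n_env_types, n_species)``; all entries are
    strictly positive.
    """

    resources: np.ndarray

    def __post_init__(self) -> None:
        r = np.atleast_2d(np.asarray(self.resources, dtype=float))
        if np.any(r <= 0):
            raise ValueError("all resource amounts must be positive")
        object.__setattr__(self, "resources", r)

    @property
    def n_species(self) -> int:
        return self.resources.shape[1]

    @property
    def n_env_types(self) -> int:
        return self.resources.shape[0]

    @classmethod
    def ladder(cls, n_species: int, hi: float = 2.0, lo: float = 1.1) -> "SpeciesTable":
        """Linear resource ladder from ``hi`` down to ``lo`` at equal steps."""
        return cls(np.linspace(hi, lo, n_species)[None, :])

    @classmethod
    def reversed_pair(cls, n_species: int, hi: float = 2.0, lo: float = 1.001) -> "SpeciesTable":
        """Two environment types with exactly reversed resource rankings."""
        a = np.linspace(hi, lo, n_species)
        return cls(np.vstack([a, a[::-1]]))

    @classmethod
    def normal(
        cls,
        n_species: int,
        mean: float = 1.5,
        sd: float = 0.25,
        rng: np.random.Generator | None = None,
        min_resource: float = 0.05,
    ) -> "SpeciesTable":
        """Resources drawn from a normal distribution, floored at a small
        positive value to keep every amount valid."""
        rng = np.random.default_rng() if rng is None else rng
        r = np.maximum(rng.normal(mean, sd, n_species), min_resource)
        return cls(r[None, :])


@dataclass(frozen=True)
class EnvironmentMap:
    """Environment type of each deme (index into SpeciesTable rows)."""

    deme_env: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.deme_env, dtype=np.int64)
        if e.ndim != 1 or np.any(e < 0):
            raise ValueError("deme_env must be a 1-D vector of type indices")
        object.__setattr__(self, "deme_env", e)

    @property
    def n_demes(self) -> int:
        return self.deme_env.shape[0]

    @classmethod
    def homogeneous(cls, n_demes: int) -> "EnvironmentMap":
        return cls(np.zeros(n_demes, dtype=np.int64))

    @classmethod
    def two_types(cls, n_demes: int, fraction_primary: float = 0.75) -> "EnvironmentMap":
        """First ``fraction_primary`` of demes are type 0, the rest type 1."""
        n_a = round(n_demes * fraction_primary)
        if not 0 < n_a < n_demes:
            raise ValueError("fraction_primary must split the demes non-trivially")
        env = np.zeros(n_demes, dtype=np.int64)
        env[n_a:] = 1
        return cls(env)


@dataclass
class CommunityState:
    """Per-individual arrays for one generation, in slot order."""

    species: np.ndarray  # int, [N]
    deme: np.ndarray  # int, [N]; deme of slot i is i // deme_capacity
    g: np.ndarray  # float in (0,1), [N]
    generation: int = 0

    @property
    def n_individuals(self) -> int:
        return self.species.shape[0]

    def validate(self, config: SimulationConfig) -> None:
        n = config.n_individuals
        if not (self.species.shape == self.deme.shape == self.g.shape == (n,)):
            raise ValueError("state vectors must all have length N")
        if np.any((self.g <= 0.0) | (self.g >= 1.0)):
            raise ValueError("allocation genes must lie strictly in (0, 1)")
        counts = np.bincount(self.deme, minlength=config.n_demes)
        if np.any(counts != config.deme_capacity):
            raise ValueError("every deme must hold exactly deme_capacity individuals")
        if np.any((self.species < 0) | (self.species >= config.n_species)):
            raise ValueError("species ids out of range")


def _slot_demes(config: SimulationConfig) -> np.ndarray:
    return np.arange(config.n_individuals, dtype=np.int64) // config.deme_capacity


def init_community(
    config: SimulationConfig,
    species_table: SpeciesTable | None = None,
    rng: np.random.Generator | None = None,
) -> CommunityState:
    """Random initial community: ``g ~ Uniform(0,1)``, species equiprobable,
    individuals shuffled into deme slots sequentially."""
    if species_table is not None and species_table.n_species != config.n_species:
        raise ValueError("species_table width does not match n_species")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.n_individuals
    species = rng.integers(0, config.n_species, n, dtype=np.int64)
    g = _open_uniform(rng, n)
    perm = rng.permutation(n)
    return CommunityState(
        species=species[perm], deme=_slot_demes(config), g=g[perm], generation=0
    )


def _open_uniform(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform draws on the open interval (0, 1)."""
    x = rng.random(size)
    while True:  # rng.random() can return exactly 0.0; resample those
        zero = x == 0.0
        if not zero.any():
            return x
        x[zero] = rng.random(int(zero.sum()))


def _resources_of(
    state: CommunityState, species_table: SpeciesTable, env: EnvironmentMap
) -> np.ndarray:
    return species_table.resources[env.deme_env[state.deme], state.species]


def maternal_seed_weights(
    state: CommunityState, species_table: SpeciesTable, env: EnvironmentMap
) -> np.ndarray:
    """Unnormalised seed output ``g * R`` per individual (lottery weight)."""
    return state.g * _resources_of(state, species_table, env)


def paternal_pollen_weights(
    state: CommunityState, species_table: SpeciesTable, env: EnvironmentMap
) -> dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]:
    """Normalised pollen weights per (deme, species) mating group.

    Returns a dict mapping ``(deme, species)`` to ``(member_indices, probs)``
    where ``probs`` is proportional to ``(1 - g) * R`` and sums to one over
    the group.  Groups with no members are absent.  This is the reference
    (enumerative) form of the father distribution; :func:`sample_parents`
    draws from the same distribution vectorised.
    """
    r = _resources_of(state, species_table, env)
    v = (1.0 - state.g) * r
    out: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    key = state.deme.astype(np.int64) * np.int64(np.max(state.species) + 1) + state.species
    order = np.argsort(key, kind="stable")
    ksort = key[order]
    bounds = np.flatnonzero(np.r_[True, ksort[1:] != ksort[:-1], True])
    for a, b in zip(bounds[:-1], bounds[1:]):
        members = order[a:b]
        w = v[members]
        out[(int(state.deme[members[0]]), int(state.species[members[0]]))] = (
            members,
            w / w.sum(),
        )
    return out


def mutate_genes(
    g_values: np.ndarray,
    mutation_rate: float,
    rng: np.random.Generator,
    model: str = "uniform",
    sigma: float = 0.05,
) -> np.ndarray:
    """Mutate allocation genes in place-free fashion.

    Each entry mutates independently with probability ``mutation_rate``.
    ``"uniform"`` replaces the value with a fresh Uniform(0, 1) draw from the
    open interval; ``"perturbation"`` adds Normal(0, sigma) noise and reflects
    the result back into (0, 1).  Output values are strictly inside (0, 1).
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    out = np.array(g_values, dtype=float, copy=True)
    if mutation_rate == 0.0 or out.size == 0:
        return out
    mask = rng.random(out.shape[0]) < mutation_rate
    k = int(mask.sum())
    if k == 0:
        return out
    if model == "uniform":
        out[mask] = _open_uniform(rng, k)
    elif model == "perturbation":
        x = out[mask] + rng.normal(0.0, sigma, k)
        x = np.abs(x) % 2.0  # reflect at 0 and 1 (period-2 fold)
        x = np.where(x > 1.0, 2.0 - x, x)
        out[mask] = np.clip(x, _OPEN_LO, _OPEN_HI)
    else:
        raise ValueError("model must be 'uniform' or 'perturbation'")
    return out


def _weighted_draw(cumw: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Indices drawn with probability proportional to weights, given the
    cumulative weight vector and uniforms in [0, 1)."""
    idx = np.searchsorted(cumw, u * cumw[-1], side="right")
    return np.minimum(idx, cumw.shape[0] - 1)


def _global_mother_draw(cumw: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """``size`` i.i.d. weighted draws from the whole community.

    Equivalent to per-slot independent lottery draws: the sorted order
    statistics of the target uniforms are generated directly from exponential
    spacings, resolved against the cumulative weights by a linear merge, and
    then shuffled back into random slot order.
    """
    from ._kernels import merge_sample_sorted

    spacing = rng.standard_exponential(size + 1)
    cum = np.cumsum(spacing)
    targets = (cum[:size] / cum[size]) * cumw[-1]
    sorted_draws = np.empty(size, dtype=np.int64)
    merge_sample_sorted(cumw, targets, sorted_draws)
    return sorted_draws[rng.permutation(size)]


def sample_parents(
    state: CommunityState,
    config: SimulationConfig,
    species_table: SpeciesTable,
    env: EnvironmentMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a (mother, father) pair of parent indices for each of the N
    recruitment slots of the next generation.

    Mothers are weighted by seed output ``g * R``; under the global lottery
    (``d = 1``) every slot draws from the whole community, otherwise a slot
    draws locally from its seed neighbourhood except with probability ``d``.
    The father of each seed is drawn from the mother's (deme, species) pollen
    pool with weight ``(1 - g) * R``; a lone conspecific selfs with
    certainty.
    """
    from ._kernels import segment_weighted_draw

    n = config.n_individuals
    r = _resources_of(state, species_table, env)
    w = state.g * r
    cw = np.cumsum(w)

    d = config.long_distance_prob
    if d >= 1.0:
        mothers = _global_mother_draw(cw, n, rng)
    else:
        cap = config.seed_neighborhood_capacity
        mothers = np.empty(n, dtype=np.int64)
        global_slot = rng.random(n) < d
        n_global = int(global_slot.sum())
        if n_global:
            mothers[global_slot] = _weighted_draw(cw, rng.random(n_global))
        local = np.flatnonzero(~global_slot)
        if local.size:
            # slot's seed neighbourhood = contiguous block of cap slots
            nb = local // cap
            lo = nb * cap
            hi = lo + cap
            m = np.empty(local.size, dtype=np.int64)
            segment_weighted_draw(cw, lo, hi, rng.random(local.size), m)
            mothers[local] = m

    # father: weighted draw within the mother's (deme, species) pollen group
    v = (1.0 - state.g) * r
    s = np.int64(config.n_species)
    key = state.deme.astype(np.int64) * s + state.species
    order = np.argsort(key, kind="stable")
    cv = np.cumsum(v[order])
    counts = np.bincount(key, minlength=int(config.n_demes * s))
    ends = np.cumsum(counts)
    starts = ends - counts
    mkey = key[mothers]
    pos = np.empty(n, dtype=np.int64)
    segment_weighted_draw(cv, starts[mkey], ends[mkey], rng.random(n), pos)
    fathers = order[pos]
    return mothers, fathers


def step_generation(
    state: CommunityState,
    config: SimulationConfig,
    species_table: SpeciesTable,
    env: EnvironmentMap,
    rng: np.random.Generator,
) -> CommunityState:
    """One full generation update: fertilisation, lottery recruitment,
    inheritance, mutation.  Returns a new state with exactly N individuals."""
    mothers, fathers = sample_parents(state, config, species_table, env, rng)
    n = config.n_individuals
    from_mother = rng.random(n) < 0.5
    g_off = np.where(from_mother, state.g[mothers], state.g[fathers])
    g_off = mutate_genes(
        g_off,
        config.mutation_rate,
        rng,
        model=config.mutation_model,
        sigma=config.mutation_sigma,
    )
    return CommunityState(
        species=state.species[mothers],
        deme=_slot_demes(config),
        g=g_off,
        generation=state.generation + 1,
    )


def census(state: CommunityState, n_species: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-species abundance and mean allocation gene (NaN when extinct)."""
    counts = np.bincount(state.species, minlength=n_species)
    gsum = np.bincount(state.species, weights=state.g, minlength=n_species)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_g = np.where(counts > 0, gsum / np.maximum(counts, 1), np.nan)
    return counts, mean_g


@dataclass
class SimulationResult:
    """Outcome of a run: recorded trajectory plus the final state."""

    trajectory: pd.DataFrame  # columns: generation, species_id, abundance, mean_g
    final_state: CommunityState
    config: SimulationConfig

    @property
    def final_census(self) -> np.ndarray:
        return np.bincount(self.final_state.species, minlength=self.config.n_species)

    @property
    def final_richness(self) -> int:
        return int((self.final_census > 0).sum())


def run_simulation(
    config: SimulationConfig,
    species_table: SpeciesTable | None = None,
    env: EnvironmentMap | None = None,
    rng: np.random.Generator | None = None,
    record_every: int = 1,
    stop_on_single_species: bool = False,
) -> SimulationResult:
    """Run ``config.generations`` generation updates from a random start.

    Records a per-species census (abundance, mean g) at generation 0, every
    ``record_every`` generations, and at the final generation.  Extinct
    species remain in the bookkeeping with abundance 0.
    """
    if species_table is None:
        species_table = SpeciesTable(np.ones((1, config.n_species)))
    if env is None:
        env = EnvironmentMap.homogeneous(config.n_demes)
    if env.n_demes != config.n_demes:
        raise ValueError("environment map length must equal n_demes")
    if species_table.n_env_types <= int(env.deme_env.max()):
        raise ValueError("species_table lacks rows for some environment types")
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    if record_every < 1:
        raise ValueError("record_every must be >= 1")

    state = init_community(config, species_table, rng)
    gens: list[int] = []
    counts_rows: list[np.ndarray] = []
    meang_rows: list[np.ndarray] = []

    def record(st: CommunityState) -> None:
        c, m = census(st, config.n_species)
        gens.append(st.generation)
        counts_rows.append(c)
        meang_rows.append(m)

    record(state)
    for _ in range(config.generations):
        state = step_generation(state, config, species_table, env, rng)
        t = state.generation
        if t % record_every == 0 or t == config.generations:
            record(state)
        if stop_on_single_species:
            if np.all(state.species == state.species[0]):
                if t % record_every != 0 and t != config.generations:
                    record(state)
                break

    s_ids = np.arange(config.n_species)
    trajectory = pd.DataFrame(
        {
            "generation": np.repeat(gens, config.n_species),
            "species_id": np.tile(s_ids, len(gens)),
            "abundance": np.concatenate(counts_rows),
            "mean_g": np.concatenate(meang_rows),
        }
    )
    return SimulationResult(trajectory=trajectory, final_state=state, config=config)
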
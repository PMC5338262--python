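"""Individual-based model: initialisation, weights, mutation, and the
one-generation update with its conservation and closure invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sexalloc import (
    CommunityState,
    EnvironmentMap,
    SimulationConfig,
    SpeciesTable,
    init_community,
    maternal_seed_weights,
    mutate_genes,
    paternal_pollen_weights,
    run_simulation,
    sample_parents,
    step_generation,
)
from sexalloc.summaries import richness_over_time


class TestConfigValidation:
    def test_rejects_indivisible_community(self):
        with pytest.raises(ValueError, match="divisible"):
            SimulationConfig(n_individuals=101, n_demes=10, n_species=2, generations=1)

    def test_rejects_no_species(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_individuals=100, n_demes=10, n_species=0, generations=1)

    def test_local_dispersal_requires_nested_neighbourhoods(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                n_individuals=1000, n_demes=10, n_species=2, generations=1,
                long_distance_prob=0.1, seed_neighborhood_capacity=30,
            )

    def test_deme_capacity(self):
        cfg = SimulationConfig(n_individuals=10**4, n_demes=100, n_species=1, generations=0)
        assert cfg.deme_capacity == 100


class TestInitCommunity:
    def test_species_counts_near_equal(self):
        cfg = SimulationConfig(n_individuals=10**5, n_demes=10**3, n_species=10,
                               generations=0, rng_seed=3)
        state = init_community(cfg)
        counts = np.bincount(state.species, minlength=10)
        expected = cfg.n_individuals / 10
        sd = np.sqrt(cfg.n_individuals * 0.1 * 0.9)
        assert np.all(np.abs(counts - expected) < 4 * sd)

    def test_single_species_degenerate(self):
        cfg = SimulationConfig(n_individuals=200, n_demes=2, n_species=1,
                               generations=0, rng_seed=0)
        state = init_community(cfg)
        assert np.all(state.species == 0)

    def test_initial_genes_uniform(self):
        cfg = SimulationConfig(n_individuals=10**4, n_demes=100, n_species=10,
                               generations=0, rng_seed=11)
        state = init_community(cfg)
        assert stats.kstest(state.g, "uniform").pvalue > 1e-3

    def test_demes_filled_to_capacity(self):
        cfg = SimulationConfig(n_individuals=300, n_demes=6, n_species=3,
                               generations=0, rng_seed=0)
        state = init_community(cfg)
        state.validate(cfg)


class TestSeedAndPollenWeights:
    def test_maternal_weight_arithmetic(self, small_setup):
        config, table, env, state = small_setup
        state.g[:] = 0.5
        w = maternal_seed_weights(state, table, env)
        r = table.resources[0, state.species]
        assert np.allclose(w, 0.5 * r)
        # species resources 2.0 vs 1.0 -> weight ratio exactly 2
        w0 = w[state.species == 0][0]
        w1 = w[state.species == 1][0]
        assert w0 / w1 == pytest.approx(2.0)

    def test_heterogeneous_environment_resource_lookup(self):
        cfg = SimulationConfig(n_individuals=40, n_demes=4, n_species=2,
                               generations=0, rng_seed=1)
        table = SpeciesTable.reversed_pair(2, hi=2.0, lo=1.0)
        env = EnvironmentMap.two_types(4, fraction_primary=0.75)
        state = init_community(cfg, table, np.random.default_rng(1))
        w = maternal_seed_weights(state, table, env)
        # species 0 gets R=2 in type-A demes and R=1 in the type-B deme
        sp0 = state.species == 0
        in_b = env.deme_env[state.deme] == 1
        assert np.allclose(w[sp0 & ~in_b], state.g[sp0 & ~in_b] * 2.0)
        assert np.allclose(w[sp0 & in_b], state.g[sp0 & in_b] * 1.0)

    def test_lone_conspecific_selfs_with_certainty(self):
        cfg = SimulationConfig(n_individuals=4, n_demes=2, n_species=2,
                               generations=0, mutation_rate=0.0, rng_seed=0)
        table = SpeciesTable.ladder(2, 2.0, 1.0)
        env = EnvironmentMap.homogeneous(2)
        state = CommunityState(
            species=np.array([0, 1, 1, 1]),
            deme=np.array([0, 0, 1, 1]),
            g=np.array([0.3, 0.6, 0.2, 0.9]),
        )
        groups = paternal_pollen_weights(state, table, env)
        members, probs = groups[(0, 0)]
        assert list(members) == [0] and probs[0] == pytest.approx(1.0)

    def test_pollen_weights_proportional_to_male_allocation(self):
        state = CommunityState(
            species=np.zeros(3, dtype=int),
            deme=np.zeros(3, dtype=int),
            g=np.array([0.2, 0.5, 0.9]),
        )
        table = SpeciesTable(np.array([[2.0]]))
        env = EnvironmentMap.homogeneous(1)
        _, probs = paternal_pollen_weights(state, table, env)[(0, 0)]
        raw = np.array([1.6, 1.0, 0.2])  # (1-g) * R
        assert np.allclose(probs, raw / raw.sum())


class TestMutation:
    def test_zero_rate_is_identity(self, rng):
        g = rng.uniform(0.01, 0.99, 1000)
        assert np.array_equal(mutate_genes(g, 0.0, rng), g)

    def test_full_replacement_is_uniform(self, rng):
        g = np.full(10**5, 0.123)
        out = mutate_genes(g, 1.0, rng)
        assert stats.kstest(out, "uniform").pvalue > 1e-3

    def test_mutated_fraction_binomial(self, rng):
        n, mu = 10**6, 1e-3
        g = np.full(n, 0.5)
        out = mutate_genes(g, mu, rng)
        frac = np.mean(out != 0.5)
        sd = np.sqrt(mu * (1 - mu) / n)
        assert abs(frac - mu) < 4 * sd

    def test_perturbation_stays_in_open_interval(self, rng):
        g = np.concatenate([np.full(500, 0.001), np.full(500, 0.999)])
        out = mutate_genes(g, 1.0, rng, model="perturbation", sigma=0.3)
        assert np.all((out > 0.0) & (out < 1.0))

    def test_rejects_invalid_rate(self, rng):
        with pytest.raises(ValueError):
            mutate_genes(np.array([0.5]), 1.5, rng)

    @given(
        mu=st.floats(min_value=0.0, max_value=1.0),
        model=st.sampled_from(["uniform", "perturbation"]),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(deadline=None, max_examples=50)
    def test_output_always_strictly_inside_unit_interval(self, mu, model, seed):
        r = np.random.default_rng(seed)
        g = r.uniform(1e-12, 1 - 1e-12, 200)
        out = mutate_genes(g, mu, r, model=model, sigma=0.5)
        assert np.all((out > 0.0) & (out < 1.0))


class TestStepGeneration:
    def test_conservation_and_closure(self, small_setup):
        config, table, env, state = small_setup
        rng = np.random.default_rng(42)
        mothers, fathers = sample_parents(state, config, table, env, rng)
        # father always conspecific and co-demic with the mother
        assert np.array_equal(state.species[mothers], state.species[fathers])
        assert np.array_equal(state.deme[mothers], state.deme[fathers])
        new = step_generation(state, config, table, env, rng)
        new.validate(config)
        assert new.generation == state.generation + 1
        # offspring species comes from the mother's side only
        assert set(np.unique(new.species)) <= set(np.unique(state.species))

    def test_genes_stay_in_open_interval_over_generations(self, small_setup):
        config, table, env, state = small_setup
        config = dataclasses.replace(config, mutation_rate=0.05,
                                     mutation_model="perturbation")
        rng = np.random.default_rng(0)
        for _ in range(20):
            state = step_generation(state, config, table, env, rng)
            assert np.all((state.g > 0.0) & (state.g < 1.0))

    def test_single_individual_obligate_selfing(self):
        cfg = SimulationConfig(n_individuals=1, n_demes=1, n_species=1,
                               generations=0, mutation_rate=0.0, rng_seed=0)
        table = SpeciesTable(np.array([[1.5]]))
        env = EnvironmentMap.homogeneous(1)
        state = CommunityState(species=np.array([0]), deme=np.array([0]),
                               g=np.array([0.42]))
        rng = np.random.default_rng(0)
        new = step_generation(state, cfg, table, env, rng)
        assert new.g[0] == pytest.approx(0.42)

    def test_neutral_symmetry_of_species_shares(self):
        # equal resources, identical g, no mutation: expected share unchanged
        shares = []
        for rep in range(200):
            cfg = SimulationConfig(n_individuals=1000, n_demes=10, n_species=2,
                                   generations=0, mutation_rate=0.0, rng_seed=rep)
            table = SpeciesTable(np.ones((1, 2)))
            env = EnvironmentMap.homogeneous(10)
            state = init_community(cfg, table, np.random.default_rng(rep))
            state.g[:] = 0.5
            new = step_generation(state, cfg, table, env,
                                  np.random.default_rng(10_000 + rep))
            shares.append(np.mean(new.species == 0))
        grand = np.mean(shares)
        init_share = np.mean(
            [np.mean(init_community(
                SimulationConfig(n_individuals=1000, n_demes=10, n_species=2,
                                 generations=0, rng_seed=rep)).species == 0)
             for rep in range(200)]
        )
        se = np.sqrt(0.25 / 1000 / 200) + np.sqrt(0.25 / 1000 / 200)
        assert abs(grand - init_share) < 4 * se

    def test_local_seed_dispersal_confines_mothers(self):
        cfg = SimulationConfig(n_individuals=400, n_demes=2, n_species=2,
                               generations=0, mutation_rate=0.0,
                               long_distance_prob=0.0,
                               seed_neighborhood_capacity=50, rng_seed=5)
        table = SpeciesTable.ladder(2, 2.0, 1.0)
        env = EnvironmentMap.homogeneous(2)
        state = init_community(cfg, table, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        mothers, _ = sample_parents(state, cfg, table, env, rng)
        slots = np.arange(400)
        assert np.array_equal(mothers // 50, slots // 50)


class TestRunSimulation:
    def test_zero_generations_records_initial_census_only(self):
        cfg = SimulationConfig(n_individuals=100, n_demes=2, n_species=4,
                               generations=0, rng_seed=1)
        res = run_simulation(cfg)
        assert res.trajectory["generation"].unique().tolist() == [0]
        assert res.trajectory["abundance"].sum() == 100

    def test_single_species_richness_constant(self):
        cfg = SimulationConfig(n_individuals=200, n_demes=2, n_species=1,
                               generations=20, rng_seed=1)
        res = run_simulation(cfg)
        rich = richness_over_time(res.trajectory)
        assert np.all(rich["richness"] == 1)

    def test_richness_non_increasing_and_total_conserved(self):
        # many species in a tiny community: extinctions certain
        cfg = SimulationConfig(n_individuals=200, n_demes=4, n_species=50,
                               generations=150, rng_seed=2)
        res = run_simulation(cfg, species_table=SpeciesTable.ladder(50, 2.0, 1.1))
        totals = res.trajectory.groupby("generation")["abundance"].sum()
        assert np.all(totals == 200)
        rich = richness_over_time(res.trajectory)["richness"].to_numpy()
        assert np.all(np.diff(rich) <= 0)
        assert rich[-1] < 50  # extinctions actually happened

    def test_determinism_same_seed(self):
        cfg = SimulationConfig(n_individuals=300, n_demes=3, n_species=5,
                               generations=30, rng_seed=9)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.trajectory.equals(b.trajectory)
        assert np.array_equal(a.final_state.g, b.final_state.g)

    def test_stop_on_single_species(self):
        cfg = SimulationConfig(n_individuals=50, n_demes=1, n_species=10,
                               generations=500, rng_seed=4)
        res = run_simulation(cfg, stop_on_single_species=True)
        if res.final_richness == 1:
            assert res.final_state.generation <= 500
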
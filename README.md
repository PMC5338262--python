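# sexalloc

Individual-based simulation and closed-form theory of how the **evolution of
sex allocation** lets many competing plant species co-occur without niche
differentiation.

## The problem

In lottery competition for space, the species with the largest
species-specific resource amount `R` should exclude all others. But in
sexual organisms only the female part of reproduction (seeds) contributes to
population growth, and the optimal split between seeds and pollen depends on
density. For a local mating population (pollen dispersal area) of `n`
conspecifics, the evolutionarily stable female allocation is Hamilton's

    s = (n + 1) / (2n),

falling from 1 for an isolated, self-fertilising founder to 1/2 in large
mating populations. A rare species is absent from some pollen dispersal
areas, so `n` must be replaced by the mean of a zero-truncated Poisson
distribution, giving the ES allocation as a function of density `λ`
(expected conspecifics per area):

    s(λ) = (λ + 1 − e^(−λ)) / (2λ).

Rare species therefore evolve female-biased allocation, which boosts their
per-capita seed output `R·s` and buffers them against exclusion; common
species drift toward equal allocation, capping their growth. The simulator
demonstrates this negative density-dependent feedback in a community of
haploid annual selfers with island-model pollen dispersal, a global (or
dispersal-limited) seed lottery, fixed total size, and mutation on the
allocation gene — and reproduces S-shaped rank-abundance diagrams.

Intended users: theoretical ecologists and evolutionary biologists exploring
coexistence mechanisms, sex-allocation evolution, and neutral-like community
patterns produced by non-neutral dynamics.

## Worked example

Ten species on a resource ladder `R = 2.0, 1.9, …, 1.1` in a small community
(10⁴ individuals in 100 demes of 100; 1/100 of the full-size experiment),
1000 generations:

```python
from sexalloc import resource_ladder_community, run_replicates, theory
from sexalloc.model import census

spec = resource_ladder_community(scale=100, generations=1000, seed=42)
res = run_replicates(spec).results[0]
counts = res.final_census
_, mean_g = census(res.final_state, 10)
```

which prints, per species:

```
species  R     abundance  mean_g  s(lambda)
      0  2.0       4887  0.504   0.510
      1  1.9       1869  0.532   0.527
      2  1.8       2388  0.562   0.521
      3  1.7        583  0.579   0.586
      4  1.6        182  0.633   0.730
      5  1.5          0      -       -
      6  1.4          0      -       -
      7  1.3         91  0.834   0.828
      8  1.2          0      -       -
      9  1.1          0      -       -
final richness: 6
```

Surviving species line up on the theory curve: the dominant species
(R = 2.0, density λ ≈ 49) has evolved near-equal allocation 0.504, while a
rare species (R = 1.3, λ ≈ 0.9) is strongly female-biased at 0.834 —
matching `s(λ) = 0.828`. Several poor-resource species went extinct: in a
community this small their equilibrium populations are tens of individuals,
and such species stochastically fail to evolve female bias before drifting
extinct. Richness rises with community size (run the
`community_size_sweep` scenario to measure this).

The ES allocation curve itself:

```bash
$ sexalloc theory --lam-min 0.25 --lam-max 16 --num 7
lam     n       s
0.25    1.1302  0.942398
0.5     1.27075 0.893469
1       1.58198 0.81606
2       2.31304 0.716166
4       4.07463 0.622711
8       8.00268 0.562479
16      16      0.53125
```

Simulations can also be driven from a TOML config via `sexalloc run
config.toml --out-dir out/` (see `sexalloc/io.py` for the config schema);
outputs are tidy TSV tables (per-generation census, final census,
rank-abundance) plus a JSON manifest that reproduces the run bit for bit.

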
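# Methods

## The model

`sexalloc` simulates a community of haploid, annual, self-compatible plant
species competing for space under lottery recruitment, where the only
heritable trait is each individual's sex allocation: the fraction
`g ∈ (0, 1)` of its species-specific resource amount `R` devoted to seeds,
with `(1 − g) R` devoted to pollen.

The spatial structure is an island model. `N` individuals are distributed
over `D` demes of equal capacity `N/D`; a deme is the pollen dispersal area.
One generation proceeds as:

1. **Fertilisation.** Every seed's father is drawn from the conspecific
   pollen pool of the mother's deme, with probability proportional to pollen
   output `(1 − g) R`. Species are self-compatible and the mother's own
   pollen competes undiscounted, so a lone conspecific in a deme
   self-fertilises with certainty and every seed is fertilised.
2. **Recruitment.** The `N` adults of the next generation are drawn by
   lottery from the community-wide seed pool: mothers are sampled
   independently per recruitment slot with probability proportional to seed
   output `g R`. Seed output is treated as a continuous sampling weight;
   this is the large-seed-number limit of a multinomial lottery over a
   discrete seed pool and avoids rounding artifacts from non-integer
   resource amounts. With limited seed dispersal (below) most slots recruit
   locally instead.
3. **Inheritance and mutation.** Each offspring copies `g` from its mother
   or father with probability 1/2, then mutates with probability `μ` per
   generation (default 0.001). The default mutation model replaces `g` with
   a fresh Uniform(0, 1) draw; the perturbation variant adds Normal(0, σ)
   noise (default σ = 0.05) reflected back into (0, 1). Draws avoid the
   exact endpoints so `g` stays strictly inside the open interval.
4. **Turnover.** All adults die; total `N` is conserved exactly; there is no
   seed bank and no speciation, so species richness can only decrease.

**Seed-dispersal limitation.** With long-distance probability `d < 1`
(default 0.01 where enabled), each deme is partitioned into contiguous seed
neighbourhoods of `seed_neighborhood_capacity` slots; a slot draws its
mother from last generation's occupants of its own neighbourhood, except
that with probability `d` it draws from the whole community. `d = 1`
recovers the base model.

**Heterogeneous environment.** Demes carry an environment type indexing a
row of the species-resource table. The built-in mosaic assigns the primary
type to exactly 3/4 of demes and a secondary type, with the per-species
resource ranking exactly reversed, to the rest.

**Initialisation.** `g` i.i.d. Uniform(0, 1); species assigned with equal
probability; individuals shuffled into deme slots.

## Theory

For a local mating population of `n` conspecifics, the evolutionarily stable
female allocation is Hamilton's `s = (n + 1) / (2n)`. A rare species is
absent from some demes; conditioning on presence replaces `n` with the
zero-truncated Poisson mean `n(λ) = λ / (1 − e^{−λ})`, where `λ` is the
expected conspecific number per deme (total abundance / D). Substituting
gives the density-dependent ES allocation

    s(λ) = (λ + 1 − e^{−λ}) / (2λ),

strictly decreasing from 1 (isolated founders) to 1/2 (high density). Both
`n(λ)` and `s(λ)` are evaluated through `expm1` with a second-order series
below `λ = 10⁻⁸` to avoid cancellation.

Because per-capita population growth under the global lottery is
proportional to seed output `R s`, a species matches the growth rate of a
reference (dominant) species exactly when its allocation equals
`R_ref s_ref / R_i`; values above 1 mean no allocation can compensate its
resource deficit.

The package does not assert Hamilton's formula on authority alone: a
Shaw–Mohler-type invasion-fitness oracle (`theory.invasion_fitness`) books
the expected gene copies of one mutant among `n − 1` residents — own seeds,
plus a share of local seeds proportional to its pollen fraction, with selfed
seeds counting both copies — and the test suite verifies numerically that
its best response at the resident ESS is the resident value for every
`n ∈ {2, …, 50}`. This fitness function is the standard construction
consistent with Hamilton's result; it is used as a test oracle, not as part
of the simulator.

## Numerical implementation

Parent sampling is the hot loop. Mothers under the global lottery are drawn
by generating the order statistics of `N` uniforms directly (normalised
cumulative exponential spacings), resolving them against the cumulative seed
weights with a single linear merge, and shuffling the result into random
slot order — distributionally identical to `N` independent weighted draws
but cache-friendly. Fathers are drawn with a bounded binary search inside
each (deme, species) segment of the pollen cumulative sum; group bounds come
from a dense `D × S` offset table. Both kernels are numba-compiled; one
generation at `N = 10⁵` takes ~20 ms on one core. Weighted draws use
`cumsum` + binary search on half-open intervals, so zero-probability
individuals are never selected; ties in rank-abundance sorting break by
ascending species id (stable sort).

Reproducibility: every run consumes a single `numpy.random.Generator`
seeded from the config; replicate `r` of a scenario uses seed
`master + r`. Identical configs give bit-identical outputs at fixed library
versions; the run manifest echoes the full config and seeds.

## Scenarios and default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `μ` | 0.001 | mutation probability per locus per generation |
| mutation model | uniform replacement | supplement variant: perturbation, σ = 0.05 |
| `d` | 1.0 (base), 0.01 (dispersal-limited scenario) | long-distance seed dispersal probability |
| deme capacity | 100 (1000 in the dispersal-limited scenario) | pollen dispersal area |
| seed neighbourhood | 100 | seed dispersal area when `d < 1` |
| resources | ladder 2 → 1.1 (10 species) or 2 → 1.001 (1000 species) | species-specific resource amounts; normal variant mean 1.5, SD 0.25 |

The four scenario builders reproduce the standard experiments: the
ten-species resource ladder over 2000 generations (`N = 10⁶`, `D = 10⁴` at
full scale), the community-size sweep (1000 species, 10,000 generations,
100 replicates, grid 10⁴…3×10⁵ by default), seed-dispersal limitation, and
the 3:1 reversed-ranking environment mosaic. A `scale` argument divides `N`
and `D` jointly, preserving deme capacity and therefore every species'
density `λ` per pollen dispersal area — scaled runs probe the same mating
ecology with proportionally smaller absolute abundances.

## What the tests show — and what they do not

The synthetic communities are the model's own study conditions, not field
data: resource ladders are exactly linear, environments exactly reversed,
and generations non-overlapping. Passing tests demonstrate the internal
consistency of the eco-evolutionary mechanism (allocations track `s(λ)`,
growth rates equalise, richness grows with space, RADs become S-shaped),
not that any real community behaves this way.

Desk-scale choices: the acceptance checks run the ladder community at 1/10
of full size (`N = 10⁵`, `D = 10³`, 2000 generations, 5 replicates), the
ESS-recovery check at `N = 10⁴` (100 demes of 100, 10 replicates), the
richness sweep at `N ∈ {2, 5, 10, 20} × 10³` for 1000 generations, and the
environment-mosaic comparison at `N = 2×10⁴` for 4000 generations with 10
replicate pairs. The mosaic comparison is run under dispersal limitation
(pollen areas of 1000, seed neighbourhoods of 100, `d = 0.01`) — the
configuration the mosaic experiment is defined with. This matters: under a
fully global seed lottery the mosaic only rescales each species' effective
resource to `0.75 R_A + 0.25 R_B` (halving the spread without changing the
space constraint), whereas local recruitment lets each species persist as a
specialist of the patch type that favours it. Even so, at these desk sizes
the mosaic's measured richness gain (a fraction of a species to ~1.6
species, depending on horizon) is small relative to between-replicate
noise; the secondary patch type holds only a few thousand individuals, so
most of its would-be specialists drift extinct regardless of the
environment. Detecting the effect cleanly requires community sizes closer
to the full-scale experiment.

Two desk-scale effects are worth knowing about. First, the poorest-resource
ladder species equilibrates near `λ ≈ 0.33` (≈330 individuals at 1/10
scale) and frequently fails to evolve female-biased allocation before
drifting extinct — the same small-population stochastic failure the
full-scale model exhibits only for much poorer species. At 1/10 scale the
typical final richness over 2000 generations is therefore 8–10 (most often
9: the poorest rung of the ladder is lost), while the surviving community
sits on the theory curve. Second, single-generation fluctuations
of a rare species' mean allocation around `s(λ)` scale like the inverse
square root of its abundance, so final-snapshot deviations at 1/10 scale
can reach ~0.05–0.08 for the rarest species even though trajectories hug
the curve.

## Known limitations

Haploid one-locus genetics only; no inbreeding depression,
self-incompatibility, seed banks, overlapping generations, or speciation.
No fitting of neutral-theory or log-series models to the emitted RADs.
Replicate RAD averaging is done on log abundance by default (switchable to
linear) since whether the mean should be taken on the log or linear scale
is a presentation choice.
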
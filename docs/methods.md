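# Methods

## Model

Genotypes are length-`L` vectors of spins `s_i ∈ {−1, +1}` (all variable loci
bi-allelic).  Log-fitness is quadratic,

    F(g) = f0 + Σ_i f_i s_i + Σ_{i<j} f_ij s_i s_j,

with additive effects `f_i ~ Normal(0, σ_fi)` and pairwise epistatic effects
`f_ij ~ Normal(0, σ_fij)` drawn i.i.d.  Higher-order epistasis is out of
scope.  The offset `f0` shifts all genotypes equally; because reproduction
depends only on relative fitness it is carried through the types but is not
an inference target, and a shift-invariance test guards that no downstream
result depends on it.

Two conventions coexist and are linked exactly: spins with magnetizations
`χ_i = <s_i>` and connected correlations `χ_ij`, and 0/1 allele frequencies
`m_i = (χ_i + 1)/2`, `χ_ij = 4 (m_ij − m_i m_j)`.  All conversions live in
`freqstats` and are covered by round-trip tests.

## Simulator

`wfsim` is a discrete-generation haploid Wright-Fisher simulator.  Each
generation applies, in a fixed, centralized order:

1. **selection + drift** — multinomial resampling of N offspring with
   probabilities ∝ exp(F(g)).  The exponential (Malthusian) fitness-to-weight
   map keeps weights positive for any parameter draw and makes the `f0`
   invariance exact; at the benchmark's |F| ≲ 0.2 it is numerically close to
   a (1+F) map, and it is isolated in `reproductive_weight` so a linear
   variant could be added.
2. **recombination** — each offspring outcrosses with probability `r`
   (FFPopSim-style outcrossing semantics); an outcrossed offspring takes each
   locus from itself or a uniformly drawn second parent with probability 1/2
   (free recombination).  The pairwise separation probability is therefore
   `c_ij = 1/2` uniformly, and all QLE formulas consume the single effective
   product `r·c`; `c` is configurable so the alternative reading of `r` as a
   per-pair crossover probability can be emulated.
3. **mutation** — symmetric per-site flips at rate `μ`, consistent with the
   `μ(1 − 2m)` flux that both inference schemes assume.

The event order is a modeling choice the benchmark's data do not pin down;
any fixed order differs at O(μ, 1/N) per generation.

Initial populations default to uniform random spins (expected frequency 0.5
per site); monomorphic and given-frequency starts are available.  The
default records the whole population every generation (`sample_fraction=1`);
subsampling without replacement is provided for robustness experiments.

Physics guards: neutral drift is a martingale; one-generation drift variance
is `m(1−m)/N` (checked within 15%); a neutral allele at frequency `p` fixes
with probability `p` (±0.03 at N=50); mutation flux matches
`E[Δm] = μ(1−2m)`; a single selected locus follows the replicator recursion
`m' = m e^{2f} / (m e^{2f} + 1 − m)`.

**Seeding.**  One root seed; per-replicate generators derive from
`SeedSequence(seed, spawn_key=(0, k))` and the experiment-level landscape
from `spawn_key=(1,)`.  Replicate k is therefore reproducible in isolation
and unchanged when more replicates are added, which makes replicate-count
curves compare nested data sets.

## Frequency estimation

Moments are count-weighted with a pseudocount `λ` (default 0.5 per table,
Jeffreys-like): each pair's four joint-state counts get `λ/4`, each single
state `λ/2`.  This equals mixing with the uniform independent distribution
at weight `λ/(n+λ)`, which strictly bounds |χ_i| < 1 (finite `atanh`) and
makes the correlation matrix positive definite — both required by the
inverse-Ising step.  Sites monomorphic in the raw sample are flagged via the
pseudocount cap.  The benchmark's qualitative results are insensitive to λ
in [0.1, 1].

## tQLE inference

Under strong recombination the genotype distribution is transiently
Gibbs-Boltzmann with time-varying Ising parameters (h, J).  Inference:

* **Couplings** by naive mean field: `J = −(C⁻¹)` off-diagonal, where C is
  the connected-correlation matrix.  Exactness is verified against
  enumerated Boltzmann distributions at L ≤ 5 (weak coupling).
* **Fields**: `h_i = atanh(χ_i) − Σ_j J_ij χ_j`.
* **Epistasis mapping**: couplings relax toward `f_ij/(r c)`, giving
  `f_ij* = r c J_ij` (variant `rc`), the mutation-corrected
  `f_ij* = (r c + 4μ) J_ij` (variant `rc_4mu`, default), and a
  Gaussian-closure form `f_ij* = (r c + 4μ) χ_ij / [(1−χ_i²)(1−χ_j²)]`
  that bypasses the inversion (variant `gaussian_closure`).
* **Additive effects** from the field dynamics:
  `f_i* = Δh_i/Δt − Σ_j f_ij* χ_j`, computed per unit interval (Δt = 1 by
  default) and averaged over all T intervals; per-interval values and their
  spread are kept for diagnostics.  With no epistasis the estimator reduces
  exactly to the discrete derivative of `atanh(χ_i)` (variant
  `additive_only`), which is what the additive-only scenarios use.

**Pooling design.**  Both h and J are estimated per generation from moments
pooled across replicates at that generation; coupling estimates are then
accumulated over time by averaging the per-generation `f_ij*` values.  The
alternative — pooling raw counts across generations before inverting — was
evaluated and rejected: with drifting allele frequencies the pooled
correlation matrix picks up the between-generation covariance of the mean
magnetizations (a mixture artifact of order Δχ_i Δχ_j), which at
σ_fi ≥ 0.05 swamps the epistatic signal (|J| spurious ≈ 10× signal) and
drives the additive estimator into anti-correlation with the truth.
Per-generation estimation restores positive recovery in all settings and
leaves the epistasis-dominated setting unchanged.

An optional centered moving-average smoothing of h before differencing
(`smooth_window`, default off) is provided because finite-sample `atanh`
noise is amplified by differencing.

## MPL inference

The Wright-Fisher diffusion limit gives a path likelihood for the allele
frequency trajectory; maximizing it with a Gaussian prior of width γ yields
the ridge system

    (Σ_k Δt_k D(t_k) + γ I) s = m(t_K) − m(t_0) − μ Σ_k Δt_k (1 − 2 m(t_k)),

with D the diffusion matrix in the 0/1 convention (diagonal `m_i(1−m_i)`,
off-diagonal `m_ij − m_i m_j`), integrated with a left-endpoint rule
(trapezoid optional).  The diffusion matrix uses pseudocounted frequencies
(avoids exactly-zero variance rows); the net change `dm` uses raw endpoint
frequencies.  The model is purely additive; epistatic ground truth acts as a
confounder and is never estimated.

**Convention bridge.**  The solve is in the 0/1 convention, where changing
one allele changes F by `2 f_i`; hence `f_i* = s/2`.  This factor is fixed
here and validated end-to-end by ground-truth recovery (a wrong factor shows
up as a regression slope of ≈ 2 or ≈ 0.5).

Default γ = 0.1 — small against diagonal entries of the integrated diffusion
matrix at the benchmark scale (≈ Σ_t m(1−m) ≤ 7.5 per replicate) — and is
always recorded in the estimate's hyperparameters.  Replicates pool by
summing sufficient statistics (independent paths, additive log-likelihoods);
doubling the data halves the effective influence of γ.

## Evaluation

The headline metrics are rank-based, reflecting that genotype fitness order
— not parameter magnitude — is what selection acts on:

* **Universe**: unique genotypes observed anywhere in the analyzed
  trajectories (not all 2^L), ranked by true fitness with deterministic
  first-observation tie-breaking.
* **Spearman (all)**: midrank Spearman between true and predicted fitness
  over the universe.  tQLE predicts with both `f_i*` and `f_ij*` when
  epistasis was inferred; MPL and additive-only tQLE predict additively.
* **Spearman (top 5%)**: the elite is the ceil(0.05·n) genotypes of highest
  TRUE fitness; their predicted ranks are positions within the full-universe
  ordering.  Rank metrics are invariant under any strictly increasing
  transform of predictions (tested).
* **Parameter recovery**: Pearson, Spearman, regression slope and RMSE for
  `f_i` and (when inferred) `f_ij`.
* **Distributions**: count-weighted per-individual decomposition of fitness
  into additive + epistatic parts at the first and last generation, with
  two-sample KS distances and a descriptive min-oriented Gumbel fit to the
  final additive component (never a gate on inference quality).

## Benchmark scenarios and problem sizes

All presets share N=1000, L=25, T=30, r=0.5.  Additive-only rows
(σ_fij = 0): (μ, σ_fi) ∈ {(0.003, 0.01), (0.01, 0.01), (0.01, 0.05)} with a
single replicate.  Epistatic rows (σ_fij = 0.002, μ = 0.01):
σ_fi ∈ {0.005, 0.05, 0.1} with 30 replicates and replicate-count sweeps over
{1, 5, 30}.  Experiment-level conclusions use medians over five experiment
seeds; the full sweep (3 epistatic settings × 5 seeds × both methods at
three replicate counts, plus the additive rows) runs in about five minutes
on one CPU.

## What the generator does and does not emulate

The generator produces fully phased, error-free, time-stamped genomes from
a well-mixed population of constant size — the idealized data regime for
both inference schemes.  Real population data additionally feature
unphased or partial genomes, sampling noise and uneven time grids,
population structure and migration, time-varying selection, multi-allelic
loci and non-uniform mutation/recombination maps; none of these are
modeled, so passing benchmarks here demonstrate correctness of the
inference machinery in its own regime, not robustness on field data.
Uneven time grids are, however, supported throughout (Δt-aware estimators)
and exercised with thinned trajectories.

## Known limitations

* Replicate pooling keeps improving tQLE well past 5 replicates in the
  epistasis-dominated setting (the 5-vs-30 Spearman ratio is ≈ 0.6 rather
  than ≈ 1): the per-generation field estimates that feed the time
  derivative shrink like 1/√(pooled sample), so the benefit of pooling has
  not saturated at the benchmark's sample sizes.
* At σ_fi ≥ 0.05 hitchhiking fixes many loci within 30 generations; the
  population's epistatic-fitness distribution therefore narrows slightly and
  shifts by the landscape-dependent residual Σ f_ij χ_i χ_j.  The change is
  small (KS ≈ 0.1–0.3 over 30 pooled replicates, versus ≈ 0.05 when
  σ_fi = 0.005) but resolvable at 30 000 pooled individuals — the epistatic
  component is far less heritable than the additive one, yet not perfectly
  conserved.
* nMF inverse-Ising is a weak-coupling approximation; no TAP or
  pseudolikelihood corrections are implemented.
* MPL's posterior covariance is not computed; γ, μ are taken as known.
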
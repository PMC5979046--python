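# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `grnmod`, in the spirit of the model documentation that
simulation packages ship alongside their APIs.

## Developmental dynamics

Gene networks are Boolean threshold networks.  The genotype is an `N × N`
signed matrix `G`; row *i* lists the regulators of gene *i*.  States are
binary vectors updated synchronously:

    s_i(t+1) = σ_i( Σ_j g_ij s_j(t) − θ_i ),

where σ returns 1 for a positive argument, 0 for a negative one, and holds
the current state on an exact tie.  The gene-specific threshold is
θ_i = ½ Σ_j g_ij.  This choice guarantees that some combination of a
gene's regulators can switch it on and some can switch it off, and it makes
the model exactly equivalent to the classic Wagner model with states in
{−1, +1} and zero thresholds under the map σ = 2s − 1.  The equivalence is
asserted by exhaustive enumeration in the test suite and is the reason the
half-row-sum reading of the threshold was adopted over a literal
"sum of squares" reading, which would force θ_i ≥ 0 and break it.
A variant with θ_i = 0 for all genes is available
(`DynamicsVariant(threshold_rule="zero")`), as is a continuous-weight
genotype mode (binary states, real interaction weights).

Because the dynamics are deterministic on a finite state space, every
trajectory ends in a fixed point or limit cycle (the gene activity
phenotype, GAP).  `develop` walks the trajectory until a state recurs and
reports the cycle and transient length.  For engine-internal use, states
are packed into integers and the full 2^N successor table of a genotype is
built in one vectorized pass (N ≤ 12; larger networks fall back to
memoized per-state updates).  Attractor lookups, including all transient
states encountered, are cached per genotype; since unmutated offspring
share their parent's genotype object, an evolving population touches far
fewer distinct genotypes than individuals.

## Fitness and selection

An individual develops `total_cells = 100` cells, split evenly over the
`T` target GAPs (K = 100/T).  A cell assigned to target X starts from X
with every gene flipped independently with probability κ and contributes
`w = (1 − S)^D(X, Y)` when it develops to attractor Y.  The distance rule
is the Hamming distance for a stationary Y and the arithmetic mean of the
per-state Hamming distances over a limit cycle — this reduces correctly
for fixed points, penalizes oscillating phenotypes, and is exposed as a
configurable rule because the original definition appears only in
supplementary material that is not part of this package's sources.

Within one generation all individuals are evaluated against the same
freshly drawn set of perturbed initial states: noise is an environment of
the generation rather than of the individual.  This makes fitness a pure
function of genotype inside a generation, so per-genotype memoization is
exact — the test suite asserts that cached and uncached engines produce
bit-identical traces for a fixed seed.  Selection is fitness-proportional
(roulette wheel) with replacement, M parents per generation.

## Mutation

Default (biased) scheme, per gene per generation: with R current
regulators out of N possible, an interaction is lost with probability
μ(1−γ)R/N and gained with probability μγ(N−R)/N; the two are mutually
exclusive alternatives, so the per-gene mutation probability never exceeds
μ.  Detailed balance of these rates gives a Binomial(N, γ) stationary
distribution for R — mean regulator count γN, mean interactions per
network γN².  γ is therefore the sparseness dial of every experiment.
Gained interactions are +1 or −1 with equal probability (a symmetric
choice; the activation/repression balance of new regulatory links is not
otherwise constrained).

Two variants: *unbiased* (a mutating gene gains or loses with equal
probability regardless of R; impossible moves are no-ops, which yields a
uniform stationary distribution of R with mean N/2) and *continuous*
(gains draw standard-normal weights; additionally, with probability μγR/N
an existing weight is redrawn from a standard normal with its sign forced
to the pre-mutation sign).

## Populations, founders and stages

A population starts as M copies of a founder: random networks with
round(γN²) interactions (uniform placement, self-interactions permitted,
random signs) are drawn until the first stage's target GAP is a fixed
point.  Stages run consecutively on the same population (no re-founding);
each stage may override γ or κ.  At each stage end the population is
re-evaluated once, the maximum fitness is recorded, the population counts
as *adapted* if that maximum exceeds 0.9, and a *focal* network is sampled
uniformly among the top-fitness individuals.  All randomness flows from a
single generator in a fixed documented order, so traces are reproducible
bit for bit.  Default parameters: N = 10, M = 200, μ = 0.01, γ = 0.3,
κ = 0.05, S = 0.4.

## Modularity and null models

For a directed graph with L edges, Q_P = Σ_m [l_m/L − d_m^in d_m^out/L²];
self-loops count both in l_m and in the degree sums.  The single-module
partition scores exactly 0.  `spectral_partition` maximizes Q by
Leicht–Newman recursive spectral bisection on the symmetrized modularity
matrix B + Bᵀ (B_ij = A_ij − k_i^in k_j^out / L), with Kernighan–Lin-style
fine tuning of each split and a final deterministic single-node refinement
across modules (strictly improving moves only, lowest node index wins
ties; eigenvector entries of exactly zero join the positive group).
Against an exhaustive search over all set partitions of 8-node graphs the
optimizer attains the true maximum in >90% of random instances with a mean
shortfall below 0.002.

Normalized scores are z-scores against 10³ degree-preserving
randomizations produced by the edge-switching algorithm: two edges
(a→b), (c→d) are rewired to (a→d), (c→b) unless that would duplicate an
edge or create a self-loop; 100·L swaps are attempted per randomization
(a common choice; the attempt count is configurable).  Existing self-loops
are held fixed and excluded from the swappable pool, keeping both degree
sequences exact.  For Q_P^N the partition is held fixed across the
ensemble (only the intra-module edge count varies, which the
implementation exploits); for Q^N the partition is re-optimized for every
randomized network.  A null ensemble with zero standard deviation yields
an undefined (NaN) z-score rather than a silent 0.

Random reference ensembles place edges uniformly without replacement.
Self-loops are allowed in these ensembles: gene self-regulation is part of
the model family, and the resulting raw-score statistics for 10-node
networks (mean Q^opt ≈ 0.28 at 20 edges, ≈ 0.14 at 50) match the study
conditions, whereas excluding self-loops depresses both means by ≈ 0.06.

## Synthetic study inputs

`make_target_pair(N, n_differing)` builds the standard target pairs: two
stationary patterns identical on the first N − n_differing genes (set A)
and complementary on the rest (set B), plus the reference partition
{A, B}.  The default ancestral pattern is all-active; a random pattern can
be drawn instead.  The generalization argument behind the model family —
what holds for one pair of stationary GAPs holds for any pair differing in
the same number of gene states — justifies using generated patterns in
place of any particular printed bit pattern.

## Problem sizes and tolerances

Full-scale experiments (500 populations, 10⁴–2·10⁴ generations) are
cluster-scale.  The package's own test and acceptance profiles use reduced
sizes chosen so that adaptation and the modularity response have clearly
plateaued in pilot traces while a complete run stays within minutes on one
CPU:

- acceptance script: 3000-graph ensembles; 30 populations × (1000 + 4000)
  generations for the two-stage scenario; 16 populations × (4000 + 4000)
  for the single-GAP epoch switch; 10³ randomizations per z-score.
- test suite: 1200-graph ensembles; 8 populations × (600 + 2500) and
  8 × (1500 + 1500) generations; 120–300 randomizations.

Tolerance bands in the scenario tests combine the reported between-
population spreads (SD ≈ 0.85–1.0 for z-scores, 4.3 for interaction
counts) with the Monte-Carlo error of the reduced samples, plus an
allowance for the residual drift of shortened stages; they are asserted as
fixed numbers in `tests/test_acceptance.py`.  With 8 populations the
2-standard-error band of a z-score mean is about ±0.7, and shortened
second stages in pilots sat within ≈ 0.4 of the long-run mean, giving the
±0.9 bands used there.  Under single-GAP selection the shortened second
epoch leaves networks slightly denser than the γN² equilibrium of the new
γ (relaxation time N/μ = 1000 generations), which makes the epoch-2 Q^N
mean slightly less negative than at full scale.

## What the synthetic conditions do and do not show

The generator reproduces the in-silico study conditions exactly — it *is*
the study system, not a proxy for laboratory data.  What passing tests do
not establish: behaviour of networks with graded expression levels,
asynchronous or stochastic update schedules, gene duplication or
recombination, or the modularity of any particular empirical network
(`analyze-network` provides the procedure; the published network
structures themselves live in their original sources and are not bundled).

## Known limitations

- The spectral optimizer is deterministic but heuristic; on adversarial
  graphs it can stop short of the global optimum (bounded in tests by the
  exhaustive oracle at small N).
- The switching chain is the field-standard randomizer, but for some
  directed degree sequences its move set is known not to connect the whole
  graph space; z-scores inherit this caveat from the method itself.
- Fitness evaluation shares one perturbation draw per generation across
  individuals (see above); regimes where per-individual noise realizations
  matter would need a different evaluation mode.
- Epoch/stage lengths in the desk-scale profiles trade a small, documented
  bias (incomplete density relaxation) for runtime.
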
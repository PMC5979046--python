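"""Population-level evolution of gene regulatory networks.

A population of ``M`` networks evolves by rounds of fitness evaluation,
roulette-wheel selection (with replacement) and mutation.  Selection
rewards networks that reproduce one or more stationary target expression
patterns (target GAPs) from perturbed initial conditions: an individual is
a bundle of 100 cells, ``K = 100/T`` per target; a cell starts from the
target pattern with every gene flipped independently with probability
``kappa``, develops to its attractor ``Y``, and contributes fitness

    w = (1 - S) ** D(X, Y)

where ``D`` is the (cycle-averaged) Hamming distance to the target ``X``.
A target's contribution is the mean over its cells and organismal fitness
is the product over targets.

Mutation rewires single regulatory interactions.  Under the default biased
scheme, gene ``i`` with ``R_i`` regulators loses one with probability
``mu * (1 - gamma) * R_i / N`` and gains one with probability
``mu * gamma * (N - R_i) / N``; the stationary regulator count is Binomial
``(N, gamma)``, so the expected number of interactions per network is
``gamma * N**2``.  ``gamma`` therefore tunes network sparseness.

Within one generation, all individuals are scored against the same set of
perturbed initial conditions (noise is an environment of the generation,
redrawn every generation).  Fitness is then a pure function of the genotype,
which makes per-genotype caching exact: cached and uncached runs with the
same seed produce bit-identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .dynamics import (
    DEFAULT_VARIANT,
    Attractor,
    DynamicsVariant,
    Genotype,
    _TABLE_MAX_N,
    _table_from_matrix,
    develop,
    perturb_state,
    state_to_int,
)

__all__ = [
    "TargetSpec",
    "Stage",
    "EvolutionConfig",
    "PopulationTrace",
    "StageEnd",
    "gap_distance",
    "cell_fitness",
    "organism_fitness",
    "mutate",
    "roulette_select",
    "build_founder",
    "run_population",
]

MutationVariant = Literal["biased", "unbiased", "continuous"]
ADAPTATION_THRESHOLD = 0.9


@dataclass(frozen=True)
class TargetSpec:
    """A set of stationary target expression patterns and the cell budget.

    ``total_cells`` cells are split evenly: ``K = total_cells / T`` cells
    are required to produce each of the ``T`` targets.
    """

    targets: tuple
    total_cells: int = 100
    labels: tuple = ()

    def __post_init__(self) -> None:
        targets = tuple(np.asarray(t, dtype=np.uint8) for t in self.targets)
        if not targets:
            raise ValueError("need at least one target")
        n = targets[0].shape[0]
        if any(t.shape != (n,) for t in targets):
            raise ValueError("all targets must have the same length")
        for t in targets:
            t.setflags(write=False)
        object.__setattr__(self, "targets", targets)
        if self.total_cells % len(targets):
            raise ValueError("total_cells must be divisible by the number of targets")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"target_{i + 1}" for i in range(len(targets)))
            )

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def cells_per_target(self) -> int:
        return self.total_cells // len(self.targets)

    @property
    def n_genes(self) -> int:
        return self.targets[0].shape[0]


@dataclass(frozen=True)
class Stage:
    """One selection regime: a target set, its duration, and optional
    per-stage overrides of the gain propensity or perturbation rate."""

    target_spec: TargetSpec
    n_generations: int
    gamma: float | None = None
    kappa: float | None = None


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of an evolutionary run.

    Defaults are the study's standard conditions: N = 10 genes, M = 200
    networks, mu = 0.01 mutations per gene per generation, gain propensity
    gamma = 0.3 (expected 30 interactions), perturbation rate kappa = 0.05,
    selection coefficient S = 0.4.
    """

    stages: tuple
    n_genes: int = 10
    pop_size: int = 200
    mu: float = 0.01
    gamma: float = 0.3
    kappa: float = 0.05
    selection: float = 0.4
    mutation_variant: MutationVariant = "biased"
    dynamics: DynamicsVariant = DEFAULT_VARIANT
    founder_max_attempts: int = 2_000_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.stages:
            raise ValueError("need at least one stage")
        for p, name in [(self.mu, "mu"), (self.gamma, "gamma"),
                        (self.kappa, "kappa"), (self.selection, "selection")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pop_size < 1:
            raise ValueError("pop_size must be positive")
        for st in self.stages:
            if st.target_spec.n_genes != self.n_genes:
                raise ValueError("stage targets do not match n_genes")


@dataclass(frozen=True)
class StageEnd:
    """Snapshot at the end of one selection regime."""

    fitnesses: np.ndarray
    max_fitness: float
    adapted: bool
    focal: Genotype
    population: tuple
    mean_interactions: float


@dataclass(frozen=True)
class PopulationTrace:
    max_fitness: np.ndarray
    mean_fitness: np.ndarray
    mean_interactions: np.ndarray
    stage_ends: tuple
    config: EvolutionConfig

    @property
    def n_generations(self) -> int:
        return self.max_fitness.shape[0]

    @property
    def adapted(self) -> bool:
        return self.stage_ends[-1].adapted

    @property
    def focal_network(self) -> Genotype:
        return self.stage_ends[-1].focal


# ---------------------------------------------------------------------------
# fitness primitives


def gap_distance(
    target: Sequence[int] | np.ndarray,
    attained: Attractor,
    rule: str = "cycle_mean",
) -> float:
    """Distance between a target pattern and an attained attractor.

    ``cycle_mean`` (default): Hamming distance for a fixed point; for a
    limit cycle, the arithmetic mean of the Hamming distances of its states
    to the target.  Zero iff the attractor is exactly the stationary target.
    """
    if rule != "cycle_mean":
        raise ValueError(f"unknown distance rule {rule!r}")
    t = np.asarray(target, dtype=np.int64)
    states = attained.states_array().astype(np.int64)
    if states.shape[1] != t.shape[0]:
        raise ValueError("target length does not match attractor states")
    return float(np.abs(states - t).sum(axis=1).mean())


def cell_fitness(distance: float, selection: float) -> float:
    """Fitness contribution of one cell: (1 - S) ** D."""
    return (1.0 - selection) ** distance


def organism_fitness(
    genotype: Genotype,
    spec: TargetSpec,
    kappa: float,
    selection: float,
    rng: np.random.Generator,
    variant: DynamicsVariant = DEFAULT_VARIANT,
) -> float:
    """Product over targets of the mean cell fitness for that target.

    Each of the ``K`` cells assigned to a target starts from the target
    pattern perturbed with probability ``kappa`` per gene.
    """
    total = 1.0
    for target in spec.targets:
        acc = 0.0
        for _ in range(spec.cells_per_target):
            s0 = perturb_state(target, kappa, rng)
            att = develop(genotype, s0, variant)
            acc += cell_fitness(gap_distance(target, att), selection)
        total *= acc / spec.cells_per_target
    return total


# ---------------------------------------------------------------------------
# variation and selection


def _apply_loss(mat: np.ndarray, gene: int, rng: np.random.Generator) -> None:
    nz = np.flatnonzero(mat[gene])
    mat[gene, nz[rng.integers(len(nz))]] = 0


def _apply_gain(
    mat: np.ndarray, gene: int, rng: np.random.Generator, continuous: bool
) -> None:
    zeros = np.flatnonzero(mat[gene] == 0)
    j = zeros[rng.integers(len(zeros))]
    if continuous:
        mat[gene, j] = rng.standard_normal()
        if mat[gene, j] == 0.0:  # pragma: no cover - measure-zero guard
            mat[gene, j] = 1e-12
    else:
        mat[gene, j] = 1 if rng.random() < 0.5 else -1


def _apply_modify(mat: np.ndarray, gene: int, rng: np.random.Generator) -> None:
    nz = np.flatnonzero(mat[gene])
    j = nz[rng.integers(len(nz))]
    w = abs(rng.standard_normal())
    mat[gene, j] = math.copysign(w if w > 0 else 1e-12, mat[gene, j])


def _event_probs(
    r: np.ndarray, n: int, mu: float, gamma: float, variant: MutationVariant
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene probabilities of (loss, gain, weight-modification)."""
    r = r.astype(float)
    if variant == "biased":
        return mu * (1 - gamma) * r / n, mu * gamma * (n - r) / n, np.zeros_like(r)
    if variant == "unbiased":
        # gain or loss with equal probability; impossible moves are no-ops,
        # which makes the regulator count a reflected random walk with a
        # uniform stationary distribution on 0..N
        return (
            np.where(r > 0, mu / 2, 0.0),
            np.where(r < n, mu / 2, 0.0) * np.ones_like(r),
            np.zeros_like(r),
        )
    if variant == "continuous":
        return (
            mu * (1 - gamma) * r / n,
            mu * gamma * (n - r) / n,
            mu * gamma * r / n,
        )
    raise ValueError(f"unknown mutation variant {variant!r}")


def mutate(
    genotype: Genotype,
    mu: float,
    gamma: float,
    rng: np.random.Generator,
    variant: MutationVariant = "biased",
) -> Genotype:
    """Return a (possibly) mutated copy of a genotype.

    Loss, gain and (continuous variant only) weight modification are drawn
    as mutually exclusive alternatives per gene; their probabilities sum to
    at most ``mu``.
    """
    n = genotype.n_genes
    mat = np.array(genotype.matrix)
    r = genotype.regulator_counts()
    p_loss, p_gain, p_mod = _event_probs(r, n, mu, gamma, variant)
    u = rng.random(n)
    continuous = genotype.mode == "continuous"
    for i in range(n):
        if u[i] < p_loss[i]:
            if r[i] > 0:
                _apply_loss(mat, i, rng)
        elif u[i] < p_loss[i] + p_gain[i]:
            if r[i] < n:
                _apply_gain(mat, i, rng, continuous)
        elif u[i] < p_loss[i] + p_gain[i] + p_mod[i]:
            _apply_modify(mat, i, rng)
    return Genotype(mat, mode=genotype.mode)


def roulette_select(
    fitnesses: Sequence[float] | np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Fitness-proportional sampling of ``m`` parents with replacement."""
    w = np.asarray(fitnesses, dtype=float)
    if (w < 0).any():
        raise ValueError("fitnesses must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all fitnesses are zero")
    cum = np.cumsum(w)
    return np.searchsorted(cum, rng.random(m) * total, side="right")


def build_founder(
    target: Sequence[int] | np.ndarray,
    n_genes: int,
    gamma: float,
    rng: np.random.Generator,
    max_attempts: int = 2_000_000,
    variant: DynamicsVariant = DEFAULT_VARIANT,
) -> Genotype:
    """Random network with round(gamma * N**2) interactions for which the
    target pattern is a fixed point of the unperturbed dynamics.

    Candidate networks (uniform edge placement, random signs) are drawn
    until one keeps the target stationary.
    """
    t = np.asarray(target, dtype=np.int64)
    if t.shape != (n_genes,):
        raise ValueError("target length does not match n_genes")
    n_int = int(round(gamma * n_genes * n_genes))
    for _ in range(max_attempts):
        mat = np.zeros(n_genes * n_genes, dtype=np.int8)
        pos = rng.choice(n_genes * n_genes, size=n_int, replace=False)
        mat[pos] = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_int)
        mat = mat.reshape(n_genes, n_genes)
        h = mat @ t - variant.thresholds(mat.astype(float))
        nxt = np.where(h > 0, 1, np.where(h < 0, 0, t))
        if np.array_equal(nxt, t):
            return Genotype(mat)
    raise RuntimeError(
        f"no founder found for the target in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# the generation engine


class _Indiv:
    """Internal population member: matrix plus cached content key and
    per-row regulator counts."""

    __slots__ = ("mat", "key", "rc", "n_int")

    def __init__(self, mat: np.ndarray) -> None:
        self.mat = mat
        self.key = mat.tobytes()
        self.rc = np.count_nonzero(mat, axis=1)
        self.n_int = int(self.rc.sum())


class _DevelopCache:
    """Per-genotype attractor lookup.

    For small N the full 2**N transition table is built once per genotype
    (one vectorized pass) and trajectories are walked as integer lookups;
    for larger N successors are computed and memoized on demand.
    """

    def __init__(self, variant: DynamicsVariant, n_genes: int,
                 mode: str = "discrete", max_entries: int = 20000):
        self.variant = variant
        self.n = n_genes
        self.mode = mode
        self.max_entries = max_entries
        self.use_table = n_genes <= min(_TABLE_MAX_N, 12)
        self._per_genotype: dict[bytes, dict] = {}
        self._bitw = (1 << np.arange(n_genes, dtype=np.int64))

    def entry(self, ind: _Indiv) -> dict:
        e = self._per_genotype.get(ind.key)
        if e is None:
            if len(self._per_genotype) >= self.max_entries:
                self._per_genotype.clear()
            mat = np.asarray(ind.mat, dtype=float)
            theta = self.variant.thresholds(mat)
            e = {"att": {}, "w": {}}
            if self.use_table:
                e["table"] = _table_from_matrix(mat, theta)
            else:
                e["mat"] = mat
                e["theta"] = theta
                e["next"] = {}
            self._per_genotype[ind.key] = e
        return e

    def attractor_from_entry(self, e: dict, code: int) -> tuple:
        att = e["att"]
        hit = att.get(code)
        if hit is not None:
            return hit
        seen: dict[int, int] = {}
        path: list[int] = []
        c = code
        if self.use_table:
            table = e["table"]
            while c not in seen:
                seen[c] = len(path)
                path.append(c)
                c = int(table[c])
        else:
            nxt_cache = e["next"]
            mat, theta = e["mat"], e["theta"]
            while c not in seen:
                seen[c] = len(path)
                path.append(c)
                nc = nxt_cache.get(c)
                if nc is None:
                    s = ((c >> np.arange(self.n)) & 1).astype(np.int64)
                    h = mat @ s - theta
                    out = np.where(h > 0, 1, np.where(h < 0, 0, s))
                    nc = int(out @ self._bitw)
                    nxt_cache[c] = nc
                c = nc
        cycle = tuple(path[seen[c]:])
        # transient states reach the same cycle; remember them all
        for s in path:
            att[s] = cycle
        return cycle

    def attractor(self, ind: _Indiv, code: int) -> tuple:
        return self.attractor_from_entry(self.entry(ind), code)


def _popcount_distance(cycle: tuple, target_code: int) -> float:
    return sum((c ^ target_code).bit_count() for c in cycle) / len(cycle)


class _Engine:
    def __init__(self, config: EvolutionConfig, rng: np.random.Generator,
                 use_cache: bool = True):
        self.cfg = config
        self.rng = rng
        self.use_cache = use_cache
        mode = "continuous" if config.mutation_variant == "continuous" else "discrete"
        self.mode = mode
        self.dev = _DevelopCache(config.dynamics, config.n_genes, mode=mode)
        self._bitw = (1 << np.arange(config.n_genes, dtype=np.int64))

    def _draw_initial_states(self, spec: TargetSpec, kappa: float):
        """Perturbed initial conditions of the generation, shared by all
        individuals; returns per target a list of (state code, multiplicity)."""
        out = []
        k = spec.cells_per_target
        for target in spec.targets:
            tcode = int(target.astype(np.int64) @ self._bitw)
            flips = (self.rng.random((k, self.cfg.n_genes)) < kappa).astype(np.int64)
            codes = (flips @ self._bitw) ^ tcode
            uniq, counts = np.unique(codes, return_counts=True)
            out.append((tcode, list(zip(uniq.tolist(), counts.tolist()))))
        return out

    def _fitness_one(self, ind: _Indiv, drawn, selection: float, k: int) -> float:
        e = self.dev.entry(ind)
        wcache = e["w"]  # (target code, initial code) -> cell fitness
        total = 1.0
        for tcode, state_counts in drawn:
            acc = 0.0
            for code, mult in state_counts:
                w = wcache.get((tcode, code))
                if w is None:
                    cycle = self.dev.attractor_from_entry(e, code)
                    w = (1.0 - selection) ** _popcount_distance(cycle, tcode)
                    wcache[(tcode, code)] = w
                acc += mult * w
            total *= acc / k
        return total

    def evaluate(self, pop: list, spec: TargetSpec, kappa: float) -> np.ndarray:
        drawn = self._draw_initial_states(spec, kappa)
        k = spec.cells_per_target
        sel = self.cfg.selection
        fits = np.empty(len(pop))
        if self.use_cache:
            per_key: dict[bytes, float] = {}
            for i, ind in enumerate(pop):
                f = per_key.get(ind.key)
                if f is None:
                    f = self._fitness_one(ind, drawn, sel, k)
                    per_key[ind.key] = f
                fits[i] = f
        else:
            for i, ind in enumerate(pop):
                # fresh lookup per individual: no sharing across genotypes
                self.dev = _DevelopCache(self.cfg.dynamics, self.cfg.n_genes,
                                         mode=self.mode)
                fits[i] = self._fitness_one(ind, drawn, sel, k)
        return fits

    def reproduce(self, pop: list, fits: np.ndarray, gamma: float) -> list:
        cfg = self.cfg
        m, n = cfg.pop_size, cfg.n_genes
        parents = roulette_select(fits, m, self.rng)
        rmat = np.stack([pop[p].rc for p in parents]).astype(float)
        p_loss, p_gain, p_mod = _event_probs(rmat, n, cfg.mu, gamma,
                                             cfg.mutation_variant)
        u = self.rng.random((m, n))
        loss = u < p_loss
        gain = (~loss) & (u < p_loss + p_gain)
        mod = (~loss) & (~gain) & (u < p_loss + p_gain + p_mod)
        hit = loss | gain | mod
        hit_any = hit.any(axis=1)
        offspring: list = []
        continuous = cfg.mutation_variant == "continuous"
        for o in range(m):
            parent = pop[parents[o]]
            if not hit_any[o]:
                offspring.append(parent)  # unmutated offspring share storage
                continue
            mat = parent.mat.copy()
            for i in np.flatnonzero(hit[o]):
                if loss[o, i]:
                    if parent.rc[i] > 0:
                        _apply_loss(mat, i, self.rng)
                elif gain[o, i]:
                    if parent.rc[i] < n:
                        _apply_gain(mat, i, self.rng, continuous)
                else:
                    _apply_modify(mat, i, self.rng)
            offspring.append(_Indiv(mat))
        return offspring

    def stage_end(self, pop: list, fits: np.ndarray) -> StageEnd:
        top = float(fits.max())
        best = np.flatnonzero(fits == top)
        focal_idx = int(best[self.rng.integers(len(best))])
        mode = "continuous" if self.cfg.mutation_variant == "continuous" else "discrete"
        genos = tuple(Genotype(ind.mat.copy(), mode=mode) for ind in pop)
        return StageEnd(
            fitnesses=fits.copy(),
            max_fitness=top,
            adapted=top > ADAPTATION_THRESHOLD,
            focal=genos[focal_idx],
            population=genos,
            mean_interactions=sum(ind.n_int for ind in pop) / len(pop),
        )


def run_population(
    config: EvolutionConfig,
    rng: np.random.Generator,
    use_cache: bool = True,
) -> PopulationTrace:
    """Evolve one population through all configured stages.

    The population is founded as ``M`` copies of a random network for which
    the first stage's first target is a fixed point.  Each generation:
    evaluate fitness (shared perturbed initial states), roulette-select
    ``M`` parents with replacement, mutate every offspring.  At the end of
    every stage the population is re-evaluated once to take the stage-end
    snapshot (maximum fitness, adapted flag, and a focal network sampled
    uniformly among the top-fitness individuals).
    """
    eng = _Engine(config, rng, use_cache=use_cache)
    founder = build_founder(
        config.stages[0].target_spec.targets[0],
        config.n_genes,
        config.stages[0].gamma if config.stages[0].gamma is not None else config.gamma,
        rng,
        max_attempts=config.founder_max_attempts,
        variant=config.dynamics,
    )
    fmat = np.array(founder.matrix, dtype=(np.float64 if config.mutation_variant == "continuous" else np.int8))
    pop = [_Indiv(fmat.copy())]
    pop = pop * config.pop_size  # copies share storage until mutated

    max_f: list[float] = []
    mean_f: list[float] = []
    mean_i: list[float] = []
    stage_ends: list[StageEnd] = []

    for stage in config.stages:
        gamma = stage.gamma if stage.gamma is not None else config.gamma
        kappa = stage.kappa if stage.kappa is not None else config.kappa
        spec = stage.target_spec
        for _ in range(stage.n_generations):
            fits = eng.evaluate(pop, spec, kappa)
            max_f.append(float(fits.max()))
            mean_f.append(float(fits.mean()))
            mean_i.append(sum(ind.n_int for ind in pop) / len(pop))
            pop = eng.reproduce(pop, fits, gamma)
        fits = eng.evaluate(pop, spec, kappa)
        stage_ends.append(eng.stage_end(pop, fits))

    return PopulationTrace(
        max_fitness=np.array(max_f),
        mean_fitness=np.array(mean_f),
        mean_interactions=np.array(mean_i),
        stage_ends=tuple(stage_ends),
        config=config,
    )
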
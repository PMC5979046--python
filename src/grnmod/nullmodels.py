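"""Degree-preserving null models, random ensembles and normalized scores.

A raw modularity score is hard to compare across networks of different
density: sparse random graphs carry larger density fluctuations and hence
larger apparent modularity.  The normalized scores used throughout this
package are z-scores against an ensemble of randomized networks with the
same in- and out-degree sequence, produced by the edge-switching algorithm:

    Q_P^N = (Q_P - mean_null) / sd_null      (fixed partition P)
    Q^N   = (Q^opt - mean_null) / sd_null    (partition re-optimized per network)

This module also generates every synthetic input the analyses use: uniform
random digraphs with fixed edge counts, and pairs of stationary target
expression patterns that agree on one gene set and are complementary on the
other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modularity import DirectedGraph, ModularityResult, Partition, q_score, spectral_partition

__all__ = [
    "NormalizedModularity",
    "switch_randomize",
    "normalized_qp",
    "normalized_qopt",
    "random_digraph",
    "make_target_pair",
]

# Attempted swaps per randomization, as a multiple of the edge count.
SWITCH_ATTEMPTS_PER_EDGE = 100


@dataclass(frozen=True)
class NormalizedModularity:
    """Raw score with its null-ensemble mean/SD and z-score.

    ``z`` is NaN when the null ensemble is degenerate (zero SD); this is
    reported as undefined rather than silently coerced to 0.
    """

    raw: float
    null_mean: float
    null_sd: float
    z: float
    n_randomizations: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.z)


def _switch_kernel_py(edges: np.ndarray, adj: np.ndarray, picks: np.ndarray) -> None:
    """Sequential edge-swap moves; ``edges`` and ``adj`` updated in place.

    Each attempt takes two edges (a->b), (c->d) and proposes (a->d), (c->b);
    the move is rejected if it would duplicate an existing edge or create a
    self-loop.  Both moves preserve every in- and out-degree exactly.
    """
    for t in range(picks.shape[0]):
        e1 = picks[t, 0]
        e2 = picks[t, 1]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[c, d] = False
        adj[a, d] = True
        adj[c, b] = True
        edges[e1, 1] = d
        edges[e2, 1] = b


try:  # optional JIT of the inner loop; logic and RNG stream are identical
    from numba import njit

    _switch_kernel = njit(cache=False)(_switch_kernel_py)
    _switch_kernel(
        np.array([[0, 1], [2, 3]], dtype=np.int64),
        np.zeros((4, 4), dtype=np.bool_),
        np.zeros((1, 2), dtype=np.int64),
    )  # warm the compile once at import
except Exception:  # pragma: no cover - numba is present in normal installs
    _switch_kernel = _switch_kernel_py


def switch_randomize(
    graph: DirectedGraph,
    rng: np.random.Generator,
    n_attempts: int | None = None,
) -> DirectedGraph:
    """Degree-preserving randomization via repeated edge swaps.

    Existing self-loops are kept fixed and excluded from the swappable pool;
    no new self-loops are created.  The number of attempted swaps defaults
    to 100 per edge.
    """
    loops = graph.edges[graph.edges[:, 0] == graph.edges[:, 1]]
    pool = graph.edges[graph.edges[:, 0] != graph.edges[:, 1]].copy()
    if pool.shape[0] < 2:
        return DirectedGraph(graph.n_nodes, graph.edges.copy(), labels=graph.labels)
    if n_attempts is None:
        n_attempts = SWITCH_ATTEMPTS_PER_EDGE * graph.n_edges
    adj = np.zeros((graph.n_nodes, graph.n_nodes), dtype=np.bool_)
    adj[graph.edges[:, 0], graph.edges[:, 1]] = True
    picks = rng.integers(0, pool.shape[0], size=(n_attempts, 2), dtype=np.int64)
    _switch_kernel(pool, adj, picks)
    edges = np.vstack([pool, loops]) if loops.size else pool
    return DirectedGraph(graph.n_nodes, edges, labels=graph.labels)


def _null_scores(
    graph: DirectedGraph,
    n_rand: int,
    rng: np.random.Generator,
    score,
) -> np.ndarray:
    return np.array([score(switch_randomize(graph, rng)) for _ in range(n_rand)])


def _zscore(raw: float, null: np.ndarray, n_rand: int) -> NormalizedModularity:
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = (raw - mean) / sd if sd > 0 else float("nan")
    return NormalizedModularity(raw=raw, null_mean=mean, null_sd=sd, z=z,
                                n_randomizations=n_rand)


def normalized_qp(
    graph: DirectedGraph,
    partition: Partition,
    n_rand: int = 1000,
    rng: np.random.Generator | None = None,
) -> NormalizedModularity:
    """z-score of Q_P against degree-preserving randomizations, keeping the
    same partition P for every randomized network."""
    if n_rand < 2:
        raise ValueError("need at least two randomizations")
    rng = np.random.default_rng() if rng is None else rng
    raw = q_score(graph, partition)
    memb = partition.membership
    L = graph.n_edges
    # Degree sums per module are invariant under switching, so only the
    # intra-module edge count varies across the null ensemble.
    nm = int(memb.max()) + 1
    din = np.bincount(memb[graph.edges[:, 1]], minlength=nm).astype(float)
    dout = np.bincount(memb[graph.edges[:, 0]], minlength=nm).astype(float)
    expect = float(din @ dout) / (L * L)

    def score(g: DirectedGraph) -> float:
        e = g.edges
        return float(np.count_nonzero(memb[e[:, 0]] == memb[e[:, 1]])) / L - expect

    null = _null_scores(graph, n_rand, rng, score)
    return _zscore(raw, null, n_rand)


def normalized_qopt(
    graph: DirectedGraph,
    n_rand: int = 1000,
    rng: np.random.Generator | None = None,
) -> NormalizedModularity:
    """z-score of the optimized score Q^opt; the partition is re-optimized
    independently for the focal network and for every randomization."""
    if n_rand < 2:
        raise ValueError("need at least two randomizations")
    rng = np.random.default_rng() if rng is None else rng
    raw = spectral_partition(graph).q
    null = _null_scores(graph, n_rand, rng, lambda g: spectral_partition(g).q)
    return _zscore(raw, null, n_rand)


def random_digraph(
    n_nodes: int,
    n_edges: int,
    rng: np.random.Generator,
    allow_self_loops: bool = False,
) -> DirectedGraph:
    """Uniform random digraph: ``n_edges`` distinct ordered pairs drawn
    without replacement from all admissible positions."""
    positions = n_nodes * n_nodes - (0 if allow_self_loops else n_nodes)
    if n_edges > positions:
        raise ValueError(f"cannot place {n_edges} distinct edges in {positions} positions")
    flat = rng.choice(positions, size=n_edges, replace=False)
    if allow_self_loops:
        src, dst = np.divmod(flat, n_nodes)
    else:
        src, off = np.divmod(flat, n_nodes - 1)
        dst = off + (off >= src)  # skip the diagonal
    return DirectedGraph(n_nodes, np.column_stack([src, dst]))


def make_target_pair(
    n_genes: int,
    n_differing: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, Partition]:
    """Two stationary target expression patterns plus the reference partition.

    The patterns agree on the first ``n_genes - n_differing`` genes (set A)
    and are complementary on the remaining ``n_differing`` genes (set B).
    Without an ``rng`` the first pattern is the all-active state; with one,
    it is drawn uniformly.  Returns ``(pattern_I, pattern_II, partition)``
    with the partition assigning set A to module 0 and set B to module 1.
    """
    if not 1 <= n_differing <= n_genes - 1:
        raise ValueError("n_differing must lie in [1, n_genes - 1]")
    if rng is None:
        first = np.ones(n_genes, dtype=np.uint8)
    else:
        first = rng.integers(0, 2, size=n_genes).astype(np.uint8)
    second = first.copy()
    second[n_genes - n_differing:] ^= 1
    memb = np.zeros(n_genes, dtype=np.int64)
    memb[n_genes - n_differing:] = 1
    return first, second, Partition(memb)
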
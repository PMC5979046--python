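"""Directed-network modularity: partition scores and spectral optimization.

For a directed graph with ``L`` edges and a partition ``P`` of its nodes,

    Q_P = sum_m [ l_m / L  -  d_m^in * d_m^out / L**2 ]

where ``l_m`` counts edges internal to module ``m`` and ``d_m^in``,
``d_m^out`` are the summed in- and out-degrees of its nodes.  ``Q`` of the
trivial single-module partition is exactly 0; positive values indicate that
edges concentrate within modules beyond the degree-based expectation.

``spectral_partition`` searches for a partition maximizing Q by recursive
spectral bisection of the directed modularity matrix
``B_ij = A_ij - k_i^in * k_j^out / L`` (split by the sign of the leading
eigenvector of ``B + B^T``), with Kernighan--Lin style fine tuning, plus a
final deterministic single-node refinement across modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DirectedGraph",
    "Partition",
    "ModularityResult",
    "q_score",
    "spectral_partition",
]


class DirectedGraph:
    """Simple directed graph on nodes ``0..n-1`` without duplicate edges.

    Edges are ordered pairs ``(source, target)``; self-loops are allowed.
    Edge signs play no role in modularity and are discarded upstream.
    """

    __slots__ = ("n_nodes", "edges", "labels")

    def __init__(
        self,
        n_nodes: int,
        edges: Iterable[tuple[int, int]] | np.ndarray,
        labels: Sequence[str] | None = None,
    ) -> None:
        e = np.asarray(list(map(tuple, edges)) if not isinstance(edges, np.ndarray) else edges,
                       dtype=np.int64)
        if e.size == 0:
            e = e.reshape(0, 2)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be (source, target) pairs")
        if e.size and (e.min() < 0 or e.max() >= n_nodes):
            raise ValueError("edge endpoint out of range")
        if len({(int(a), int(b)) for a, b in e}) != len(e):
            raise ValueError("duplicate edges are not allowed")
        self.n_nodes = int(n_nodes)
        self.edges = e
        self.labels = list(labels) if labels is not None else None

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int64)
        if self.n_edges:
            a[self.edges[:, 1], self.edges[:, 0]] = 1  # A[i, j] = edge j -> i
        return a

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 1], minlength=self.n_nodes)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.edges[:, 0], minlength=self.n_nodes)

    @classmethod
    def from_genotype(cls, genotype) -> "DirectedGraph":
        """Regulatory graph of a genotype: nonzero ``G[i, j]`` becomes the
        edge ``j -> i`` (regulator to regulated gene); signs are dropped."""
        rows, cols = np.nonzero(np.asarray(genotype.matrix))
        return cls(genotype.matrix.shape[0], np.column_stack([cols, rows]))

    @classmethod
    def from_networkx(cls, g) -> "DirectedGraph":
        nodes = list(g.nodes())
        index = {u: i for i, u in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in g.edges()]
        return cls(len(nodes), edges, labels=[str(u) for u in nodes])

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to exactly one module.

    ``membership[v]`` is the module id of node ``v``; ids are relabelled to
    consecutive integers in order of first appearance.
    """

    membership: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=np.int64)
        _, relabelled = np.unique(m, return_inverse=True)
        # preserve first-appearance order for determinism
        order: dict[int, int] = {}
        out = np.empty_like(m)
        for i, v in enumerate(m):
            if v not in order:
                order[v] = len(order)
            out[i] = order[v]
        out.setflags(write=False)
        object.__setattr__(self, "membership", out)

    @classmethod
    def from_sets(cls, n_nodes: int, modules: Sequence[Iterable[int]]) -> "Partition":
        memb = np.full(n_nodes, -1, dtype=np.int64)
        for mid, nodes in enumerate(modules):
            for v in nodes:
                if memb[v] != -1:
                    raise ValueError(f"node {v} assigned twice")
                memb[v] = mid
        if (memb == -1).any():
            raise ValueError("partition does not cover all nodes")
        return cls(memb)

    @property
    def n_modules(self) -> int:
        return int(self.membership.max()) + 1 if self.membership.size else 0

    def modules(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_modules)]
        for v, m in enumerate(self.membership):
            out[m].append(v)
        return out


@dataclass(frozen=True)
class ModularityResult:
    partition: Partition
    q: float
    method: str


def q_score(graph: DirectedGraph, partition: Partition | np.ndarray) -> float:
    """Modularity of a given partition (directed form)."""
    memb = partition.membership if isinstance(partition, Partition) else np.asarray(partition)
    if memb.shape[0] != graph.n_nodes:
        raise ValueError("partition does not cover the graph's nodes")
    L = graph.n_edges
    if L == 0:
        raise ValueError("modularity is undefined for an empty graph")
    src, dst = graph.edges[:, 0], graph.edges[:, 1]
    intra = float(np.count_nonzero(memb[src] == memb[dst]))
    nm = int(memb.max()) + 1
    din = np.bincount(memb[dst], minlength=nm).astype(float)
    dout = np.bincount(memb[src], minlength=nm).astype(float)
    return intra / L - float(din @ dout) / (L * L)


def _modularity_matrix(graph: DirectedGraph) -> np.ndarray:
    """Symmetrized directed modularity matrix C = B + B^T with
    B_ij = A_ij - kin_i * kout_j / L."""
    a = graph.adjacency().astype(float)
    kin = graph.in_degrees().astype(float)
    kout = graph.out_degrees().astype(float)
    b = a - np.outer(kin, kout) / graph.n_edges
    return b + b.T


def _fine_tune_split(c_g: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Kernighan--Lin style refinement of a bisection sign vector.

    Repeatedly performs a sweep in which every node is moved exactly once
    (best strict gain first, ties to the lowest node index) and keeps the
    best prefix of the sweep if it improves the objective s^T C s.
    """
    n = s.shape[0]
    s = s.copy()
    while True:
        cs = c_g @ s
        obj = float(s @ cs)
        free = np.ones(n, dtype=bool)
        trial = s.copy()
        best_obj, best_k = obj, -1
        states: list[int] = []
        cur = obj
        for kstep in range(n):
            gains = -4.0 * trial * (c_g @ trial) + 4.0 * np.diag(c_g)
            gains[~free] = -np.inf
            v = int(np.argmax(gains))
            cur += float(gains[v])
            trial[v] = -trial[v]
            free[v] = False
            states.append(v)
            if cur > best_obj + 1e-12:
                best_obj, best_k = cur, kstep
        if best_k < 0:
            return s
        for v in states[: best_k + 1]:
            s[v] = -s[v]


def _split_group(c: np.ndarray, group: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Propose a bisection of ``group``; return (sign vector, delta objective)
    or None if no strictly positive gain is found."""
    c_g = c[np.ix_(group, group)].copy()
    np.fill_diagonal(c_g, np.diag(c_g) - c_g.sum(axis=1))
    w, v = np.linalg.eigh(c_g)
    lead = v[:, -1]
    if w[-1] <= 1e-12:
        s = np.ones(len(group))
    else:
        s = np.where(lead >= 0.0, 1.0, -1.0)  # zero entries join the + group
    s = _fine_tune_split(c_g, s)
    gain = float(s @ (c_g @ s))
    if gain <= 1e-12 or np.all(s == s[0]):
        return None
    return s, gain


def _refine_global(graph: DirectedGraph, memb: np.ndarray) -> np.ndarray:
    """Deterministic single-node moves between existing modules, accepted
    while Q strictly improves; lowest node index wins ties."""
    memb = memb.copy()
    q = q_score(graph, memb)
    improved = True
    while improved:
        improved = False
        for v in range(graph.n_nodes):
            current = memb[v]
            best_q, best_m = q, current
            for m in range(int(memb.max()) + 1):
                if m == current:
                    continue
                memb[v] = m
                qq = q_score(graph, memb)
                if qq > best_q + 1e-12:
                    best_q, best_m = qq, m
            memb[v] = best_m
            if best_m != current:
                q = best_q
                improved = True
        # drop empty module ids
        memb = Partition(memb).membership.copy()
    return memb


def spectral_partition(graph: DirectedGraph) -> ModularityResult:
    """Leicht--Newman spectral community detection for directed graphs.

    Recursive bisection on the (generalized) modularity matrix with KL fine
    tuning; recursion stops when a proposed split does not increase Q.
    Indivisible graphs come back as a single module with Q = 0.
    """
    if graph.n_edges < 1:
        raise ValueError("modularity is undefined for an empty graph")
    c = _modularity_matrix(graph)
    memb = np.zeros(graph.n_nodes, dtype=np.int64)
    stack = [np.arange(graph.n_nodes)]
    next_id = 1
    while stack:
        group = stack.pop()
        if len(group) < 2:
            continue
        res = _split_group(c, group)
        if res is None:
            continue
        s, _ = res
        plus = group[s > 0]
        minus = group[s < 0]
        memb[minus] = next_id
        next_id += 1
        stack.append(plus)
        stack.append(minus)
    memb = Partition(memb).membership.copy()
    memb = _refine_global(graph, memb)
    part = Partition(memb)
    return ModularityResult(partition=part, q=q_score(graph, part), method="spectral")
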
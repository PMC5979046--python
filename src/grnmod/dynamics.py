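"""Developmental dynamics of Boolean threshold gene regulatory networks.

A network of ``N`` cross-regulating genes is encoded by a signed interaction
matrix ``G``: ``G[i, j] > 0`` means gene ``j`` activates gene ``i`` and
``G[i, j] < 0`` means gene ``j`` represses gene ``i``.  Gene states are
binary (1 = active).  All genes update synchronously,

    s_i(t+1) = 1  if  sum_j G[i, j] * s_j(t) > theta_i,
             = s_i(t)  on an exact tie,
             = 0  otherwise,

with the gene-specific threshold ``theta_i`` equal to half the sum of row
``i`` of ``G``.  With this threshold the model is equivalent to the classic
Wagner model with states in {-1, +1} and zero thresholds (map s -> 2s - 1).
A variant with ``theta_i = 0`` for every gene is provided as well.

Because the state space is finite and the update deterministic, every
trajectory ends in a cycle: a fixed point (period 1) or limit cycle.  The
terminal cycle is the network's gene activity phenotype (GAP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "Attractor",
    "DynamicsVariant",
    "threshold",
    "step",
    "develop",
    "perturb_state",
    "transition_table",
    "state_to_int",
    "int_to_state",
]

ThresholdRule = Literal["half_rowsum", "zero"]

# Above this size the 2**N transition table is not materialized.
_TABLE_MAX_N = 14


@dataclass(frozen=True)
class DynamicsVariant:
    """Switches of the update rule.  The default is the half-row-sum
    threshold; ``zero`` sets every gene's threshold to 0."""

    threshold_rule: ThresholdRule = "half_rowsum"

    def thresholds(self, matrix: np.ndarray) -> np.ndarray:
        if self.threshold_rule == "half_rowsum":
            return matrix.sum(axis=1) / 2.0
        if self.threshold_rule == "zero":
            return np.zeros(matrix.shape[0])
        raise ValueError(f"unknown threshold rule {self.threshold_rule!r}")


DEFAULT_VARIANT = DynamicsVariant()


@dataclass(frozen=True)
class Genotype:
    """Signed genotype matrix.  Row ``i`` lists the regulators of gene ``i``.

    In ``discrete`` mode entries are restricted to {-1, 0, +1}; in
    ``continuous`` mode they are real weights (states remain binary).
    """

    matrix: np.ndarray
    mode: Literal["discrete", "continuous"] = "discrete"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("genotype matrix must be square")
        if m.shape[0] < 1:
            raise ValueError("genotype needs at least one gene")
        if self.mode == "discrete":
            m = m.astype(np.int8)
            if not np.isin(m, (-1, 0, 1)).all():
                raise ValueError("discrete genotype entries must be -1, 0 or +1")
        else:
            m = m.astype(np.float64)
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_interactions(self) -> int:
        return int(np.count_nonzero(self.matrix))

    def regulator_counts(self) -> np.ndarray:
        """Number of regulators per gene (nonzero entries per row)."""
        return np.count_nonzero(self.matrix, axis=1)

    def key(self) -> bytes:
        """Hashable content key (used by the engine's caches)."""
        return self.matrix.tobytes()


@dataclass(frozen=True)
class Attractor:
    """Terminal cycle of the synchronous dynamics.

    ``states`` holds the ``period`` distinct cycle states in visiting order,
    starting at the first state of the cycle the trajectory reached;
    ``transient_length`` counts the steps taken before entering the cycle.
    """

    states: tuple[tuple[int, ...], ...]
    transient_length: int

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def states_array(self) -> np.ndarray:
        return np.array(self.states, dtype=np.uint8)

    def canonical(self) -> tuple[tuple[int, ...], ...]:
        """Cycle rotated so the lexicographically smallest state is first
        (use this when comparing attractors for equality)."""
        k = len(self.states)
        best = min(range(k), key=lambda r: self.states[r])
        return tuple(self.states[(best + j) % k] for j in range(k))


def _as_state(state: Sequence[int] | np.ndarray, n: int) -> np.ndarray:
    s = np.asarray(state, dtype=np.int64)
    if s.shape != (n,):
        raise ValueError(f"state length {s.shape} does not match N={n}")
    if not np.isin(s, (0, 1)).all():
        raise ValueError("state entries must be 0 or 1")
    return s


def threshold(
    genotype: Genotype, gene: int, variant: DynamicsVariant = DEFAULT_VARIANT
) -> float:
    """Activation threshold of one gene under the given variant."""
    if not 0 <= gene < genotype.n_genes:
        raise IndexError(f"gene index {gene} out of range")
    return float(variant.thresholds(np.asarray(genotype.matrix, dtype=float))[gene])


def step(
    genotype: Genotype,
    state: Sequence[int] | np.ndarray,
    variant: DynamicsVariant = DEFAULT_VARIANT,
) -> np.ndarray:
    """One synchronous update of every gene."""
    n = genotype.n_genes
    s = _as_state(state, n)
    m = np.asarray(genotype.matrix, dtype=float)
    h = m @ s - variant.thresholds(m)
    return np.where(h > 0, 1, np.where(h < 0, 0, s)).astype(np.uint8)


def state_to_int(state: Sequence[int] | np.ndarray) -> int:
    """Pack a binary state vector into an integer (gene i -> bit i)."""
    out = 0
    for i, b in enumerate(state):
        if b:
            out |= 1 << i
    return out


def int_to_state(code: int, n: int) -> np.ndarray:
    return np.array([(code >> i) & 1 for i in range(n)], dtype=np.uint8)


def _table_from_matrix(m: np.ndarray, theta: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    codes = np.arange(1 << n, dtype=np.int64)
    states = ((codes[:, None] >> np.arange(n)) & 1).astype(np.float64)
    h = states @ m.T - theta
    nxt = np.where(h > 0, 1.0, np.where(h < 0, 0.0, states))
    return (nxt.astype(np.int64) @ (1 << np.arange(n, dtype=np.int64))).astype(
        np.int64
    )


def transition_table(
    genotype: Genotype, variant: DynamicsVariant = DEFAULT_VARIANT
) -> np.ndarray:
    """Successor of every one of the 2**N states, as packed integers.

    One vectorized pass over the whole state space; only sensible for
    small N (refused above N=14).
    """
    n = genotype.n_genes
    if n > _TABLE_MAX_N:
        raise ValueError(f"transition table too large for N={n}")
    m = np.asarray(genotype.matrix, dtype=float)
    return _table_from_matrix(m, variant.thresholds(m))


def _walk(next_of, code: int) -> tuple[list[int], int]:
    """Follow successors from ``code`` until a state repeats; return the
    cycle (in visiting order, starting at its first-reached state) and the
    transient length."""
    seen: dict[int, int] = {}
    path: list[int] = []
    c = code
    while c not in seen:
        seen[c] = len(path)
        path.append(c)
        c = next_of(c)
    start = seen[c]
    return path[start:], start


def develop(
    genotype: Genotype,
    initial: Sequence[int] | np.ndarray,
    variant: DynamicsVariant = DEFAULT_VARIANT,
) -> Attractor:
    """Iterate the dynamics from ``initial`` until the trajectory closes.

    Termination is guaranteed: the state space is finite, so a state must
    recur within 2**N steps.
    """
    n = genotype.n_genes
    s0 = _as_state(initial, n)
    m = np.asarray(genotype.matrix, dtype=float)
    theta = variant.thresholds(m)

    def nxt(code: int) -> int:
        s = int_to_state(code, n).astype(np.int64)
        h = m @ s - theta
        out = np.where(h > 0, 1, np.where(h < 0, 0, s))
        return state_to_int(out)

    cycle, transient = _walk(nxt, state_to_int(s0))
    if len(set(cycle)) != len(cycle):  # pragma: no cover - internal check
        raise AssertionError("attractor states are not distinct")
    states = tuple(tuple(int(b) for b in int_to_state(c, n)) for c in cycle)
    return Attractor(states=states, transient_length=transient)


def perturb_state(
    state: Sequence[int] | np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each gene's state independently with probability ``kappa``.

    Models non-genetic perturbation of the initial condition of a cell's
    developmental trajectory.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    s = np.asarray(state, dtype=np.uint8)
    flips = rng.random(s.shape) < kappa
    return (s ^ flips).astype(np.uint8)
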
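"""Tests for degree-preserving randomization, ensembles and z-scores."""

import itertools

import numpy as np
import pytest

from grnmod import (
    DirectedGraph,
    Partition,
    make_target_pair,
    normalized_qopt,
    normalized_qp,
    q_score,
    random_digraph,
    switch_randomize,
)


def degree_signature(g):
    return g.in_degrees().tolist(), g.out_degrees().tolist()


class TestSwitchRandomize:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequences_conserved(self, seed):
        rng = np.random.default_rng(seed)
        g = random_digraph(10, 20, rng)
        r = switch_randomize(g, rng)
        assert degree_signature(r) == degree_signature(g)
        assert r.n_edges == g.n_edges
        assert r.n_nodes == g.n_nodes
        # still a simple digraph: no duplicates was asserted by construction;
        # no new self-loops either
        assert not (r.edges[:, 0] == r.edges[:, 1]).any()

    def test_single_edge_unchanged(self, rng):
        g = DirectedGraph(3, [(0, 1)])
        r = switch_randomize(g, rng)
        assert r.edges.tolist() == [[0, 1]]

    def test_self_loops_kept_fixed(self, rng):
        g = DirectedGraph(4, [(0, 0), (0, 1), (1, 2), (2, 3), (3, 1)])
        r = switch_randomize(g, rng)
        assert [0, 0] in r.edges.tolist()
        assert not ((r.edges[:, 0] == r.edges[:, 1]) & (r.edges[:, 0] != 0)).any()

    def test_marginals_match_exact_uniform_ensemble(self):
        """On a small graph, edge-presence frequencies under switching match
        the exact uniform distribution over all simple digraphs with the
        same in/out degree sequence (enumeration oracle)."""
        g = DirectedGraph(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        kin, kout = degree_signature(g)
        positions = [(i, j) for i in range(4) for j in range(4) if i != j]
        members = []
        for combo in itertools.combinations(positions, g.n_edges):
            e = np.array(combo)
            din = np.bincount(e[:, 1], minlength=4).tolist()
            dout = np.bincount(e[:, 0], minlength=4).tolist()
            if din == kin and dout == kout:
                members.append(set(map(tuple, combo)))
        exact = {p: np.mean([p in m for m in members]) for p in positions}

        rng = np.random.default_rng(0)
        reps = 4000
        counts = {p: 0 for p in positions}
        for _ in range(reps):
            r = switch_randomize(g, rng)
            for p in map(tuple, r.edges):
                counts[p] += 1
        max_dev = max(abs(counts[p] / reps - exact[p]) for p in positions)
        assert max_dev < 0.03


class TestNormalizedScores:
    def planted(self):
        rng = np.random.default_rng(12)
        within = [(i, j) for i in range(5) for j in range(5) if i != j]
        e = []
        for block in (0, 5):
            idx = rng.choice(len(within), size=9, replace=False)
            e += [(within[k][0] + block, within[k][1] + block) for k in idx]
        e += [(0, 7), (8, 2)]
        return DirectedGraph(10, e)

    def test_planted_partition_z_large(self):
        g = self.planted()
        part = Partition(np.repeat([0, 1], 5))
        nm = normalized_qp(g, part, n_rand=300, rng=np.random.default_rng(1))
        assert nm.z > 2
        assert nm.raw == pytest.approx(q_score(g, part))
        assert nm.defined

    def test_qopt_z_positive_for_planted(self):
        g = self.planted()
        nm = normalized_qopt(g, n_rand=200, rng=np.random.default_rng(2))
        assert nm.z > 1

    def test_deterministic_given_seed(self):
        g = self.planted()
        part = Partition(np.repeat([0, 1], 5))
        z1 = normalized_qp(g, part, n_rand=50, rng=np.random.default_rng(9)).z
        z2 = normalized_qp(g, part, n_rand=50, rng=np.random.default_rng(9)).z
        assert z1 == z2

    def test_degenerate_null_reported_undefined(self, rng):
        # a 2-node graph with a single swappable pair has an invariant Q_P
        g = DirectedGraph(2, [(0, 1), (1, 0)])
        nm = normalized_qp(g, Partition(np.array([0, 1])), n_rand=10, rng=rng)
        assert not nm.defined
        assert np.isnan(nm.z)

    def test_self_null_family_z_centered(self):
        """Graphs scored against their own null family give z-scores with
        mean near 0 and spread near 1."""
        rng = np.random.default_rng(3)
        part = Partition(np.repeat([0, 1], 5))
        zs = []
        for _ in range(150):
            g = random_digraph(10, 20, rng, allow_self_loops=True)
            nm = normalized_qp(g, part, n_rand=120, rng=rng)
            if nm.defined:
                zs.append(nm.z)
        assert abs(np.mean(zs)) < 0.25
        assert 0.7 < np.std(zs) < 1.4


class TestRandomDigraph:
    def test_edge_count_and_distinctness(self, rng):
        g = random_digraph(10, 20, rng)
        assert g.n_edges == 20
        assert len({tuple(e) for e in g.edges}) == 20
        assert not (g.edges[:, 0] == g.edges[:, 1]).any()

    def test_complete_graph(self, rng):
        g = random_digraph(3, 9, rng, allow_self_loops=True)
        assert g.n_edges == 9

    def test_infeasible_rejected(self, rng):
        with pytest.raises(ValueError):
            random_digraph(3, 7, rng)  # only 6 loop-free positions

    def test_uniform_marginals(self, rng):
        counts = np.zeros((5, 5))
        reps = 4000
        for _ in range(reps):
            g = random_digraph(5, 6, rng)
            counts[g.edges[:, 0], g.edges[:, 1]] += 1
        off = ~np.eye(5, dtype=bool)
        p = counts[off] / reps
        assert abs(p.mean() - 6 / 20) < 0.01
        assert p.max() - p.min() < 0.08


class TestMakeTargetPair:
    def test_default_pair_and_partition(self):
        a, b, part = make_target_pair(10, 5)
        assert a.tolist() == [1] * 10
        assert b.tolist() == [1] * 5 + [0] * 5
        assert part.membership.tolist() == [0] * 5 + [1] * 5

    @pytest.mark.parametrize("n_diff, set_sizes", [(3, (7, 3)), (7, (3, 7))])
    def test_asymmetric_pairs(self, n_diff, set_sizes):
        a, b, part = make_target_pair(10, n_diff)
        same = (a == b).sum()
        assert same == 10 - n_diff
        sizes = tuple(np.bincount(part.membership))
        assert sizes == set_sizes

    def test_random_first_pattern(self):
        rng = np.random.default_rng(8)
        a, b, _ = make_target_pair(10, 4, rng)
        assert ((a != b).sum()) == 4

    def test_invalid_n_differing(self):
        with pytest.raises(ValueError):
            make_target_pair(10, 0)
        with pytest.raises(ValueError):
            make_target_pair(10, 10)
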
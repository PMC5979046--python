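"""Tests for fitness evaluation, mutation, selection and population runs."""

import numpy as np
import pytest

from grnmod import (
    EvolutionConfig,
    Genotype,
    TargetSpec,
    build_founder,
    cell_fitness,
    develop,
    gap_distance,
    mutate,
    organism_fitness,
    roulette_select,
    run_population,
)
from grnmod.evolution import Stage, _event_probs

from conftest import random_discrete_genotype


class TestGapDistance:
    def test_identical_fixed_point_is_zero(self):
        att = develop(Genotype(np.zeros((4, 4), dtype=int)), [1, 1, 0, 0])
        assert gap_distance([1, 1, 0, 0], att) == 0.0

    def test_hamming_count_for_fixed_points(self):
        att = develop(Genotype(np.zeros((4, 4), dtype=int)), [0, 1, 0, 1])
        assert gap_distance([1, 1, 0, 0], att) == 2.0

    def test_cycle_mean(self):
        # the two-gene toggle yields the 2-cycle {(1,0), (0,1)}
        att = develop(Genotype([[0, 1], [1, 0]]), [1, 0])
        assert att.period == 2
        assert gap_distance([1, 0], att) == 1.0  # distances 0 and 2, averaged


def test_cell_fitness_values():
    assert cell_fitness(0.0, 0.4) == 1.0
    assert cell_fitness(2.0, 0.4) == pytest.approx(0.36)
    assert cell_fitness(1.0, 0.0) == 1.0


class TestOrganismFitness:
    def test_perfect_network_unperturbed(self, rng):
        target = np.ones(6, dtype=int)
        founder = build_founder(target, 6, 0.3, rng)
        spec = TargetSpec((target,), total_cells=10)
        assert organism_fitness(founder, spec, 0.0, 0.4, rng) == 1.0

    def test_fixed_point_at_distance_d(self, rng):
        # all-zero genotype holds any state; target differing in d genes
        g = Genotype(np.zeros((5, 5), dtype=int))
        target = np.array([1, 1, 1, 0, 0])
        spec = TargetSpec((target,), total_cells=10)
        # kappa=0: every cell starts at the target, which is already fixed
        assert organism_fitness(g, spec, 0.0, 0.4, rng) == 1.0

    def test_deterministic_given_seed(self, rng):
        g = random_discrete_genotype(6, 10, rng)
        target = np.ones(6, dtype=int)
        spec = TargetSpec((target,), total_cells=20)
        f1 = organism_fitness(g, spec, 0.05, 0.4, np.random.default_rng(3))
        f2 = organism_fitness(g, spec, 0.05, 0.4, np.random.default_rng(3))
        assert f1 == f2
        assert 0 < f1 <= 1


class TestMutation:
    def test_event_probability_values(self):
        # at R = gamma*N the gain and loss rates balance
        p_loss, p_gain, p_mod = _event_probs(
            np.array([3.0]), 10, 0.01, 0.3, "biased"
        )
        assert p_loss[0] == pytest.approx(0.0021)
        assert p_gain[0] == pytest.approx(0.0021)
        assert p_mod[0] == 0.0

    def test_boundary_rows(self):
        p_loss, p_gain, _ = _event_probs(np.array([0.0, 10.0]), 10, 0.01, 0.3, "biased")
        assert p_loss[0] == 0.0
        assert p_gain[1] == 0.0

    @pytest.mark.parametrize(
        "variant, expected_mean, tol",
        [("biased", 3.0, 0.35), ("unbiased", 5.0, 0.8)],
    )
    def test_neutral_regulator_count_equilibrium(self, variant, expected_mean, tol):
        """Without selection, regulator counts drift to gamma*N (biased
        mutation) or N/2 (unbiased); elevated mu only rescales time."""
        rng = np.random.default_rng(5)
        g = random_discrete_genotype(10, 30, rng)
        means = []
        for it in range(4000):
            g = mutate(g, 0.5, 0.3, rng, variant=variant)
            if it >= 2000:
                means.append(g.regulator_counts().mean())
        assert abs(np.mean(means) - expected_mean) < tol

    def test_continuous_variant_weights(self, rng):
        g = Genotype(rng.standard_normal((6, 6)) * (rng.random((6, 6)) < 0.4),
                     mode="continuous")
        signs_before = np.sign(g.matrix)
        out = mutate(g, 1.0, 0.5, rng, variant="continuous")
        assert out.mode == "continuous"
        # a modified weight keeps its sign; structure changes by at most one
        # interaction per gene
        for i in range(6):
            changed = np.sign(out.matrix[i]) != signs_before[i]
            assert changed.sum() <= 1


class TestRouletteSelection:
    def test_proportionality(self, rng):
        picks = roulette_select([1.0, 3.0], 100000, rng)
        freq = (picks == 1).mean()
        se = np.sqrt(0.75 * 0.25 / 100000)
        assert abs(freq - 0.75) < 3 * se

    def test_zero_fitness_never_selected(self, rng):
        picks = roulette_select([0.0, 1.0, 0.5], 5000, rng)
        assert not (picks == 0).any()

    def test_all_zero_raises(self, rng):
        with pytest.raises(ValueError):
            roulette_select([0.0, 0.0], 5, rng)


class TestFounder:
    def test_postconditions(self, rng):
        target = np.ones(10, dtype=int)
        founder = build_founder(target, 10, 0.3, rng)
        assert founder.n_interactions == 30  # round(gamma * N^2)
        att = develop(founder, target)
        assert att.is_fixed_point and att.states == (tuple(target),)

    def test_unreachable_raises(self, rng):
        # gamma = 0 gives the empty network, which fixes every state; an
        # exhausted attempt budget must raise for an impossible combination
        target = np.array([1, 0])
        with pytest.raises(RuntimeError):
            # a 2-gene network with all 4 interactions rarely fixes (1,0);
            # an attempt budget of zero forces the failure path
            build_founder(target, 2, 1.0, rng, max_attempts=0)


def _tiny_config(n_genes=8, pop_size=40, gens=(25, 25), **kw):
    target1 = np.ones(n_genes, dtype=np.uint8)
    target2 = target1.copy()
    target2[n_genes // 2:] = 0
    spec1 = TargetSpec((target1,), total_cells=20)
    spec2 = TargetSpec((target1, target2), total_cells=20)
    return EvolutionConfig(
        stages=(Stage(spec1, gens[0]), Stage(spec2, gens[1])),
        n_genes=n_genes,
        pop_size=pop_size,
        **kw,
    )


class TestRunPopulation:
    def test_no_mutation_no_perturbation_keeps_fitness_one(self):
        cfg = _tiny_config(mu=0.0, kappa=0.0, gens=(10, 0))
        cfg = EvolutionConfig(stages=cfg.stages[:1], n_genes=8, pop_size=20,
                              mu=0.0, kappa=0.0)
        trace = run_population(cfg, np.random.default_rng(11))
        assert np.allclose(trace.max_fitness, 1.0)
        assert np.allclose(trace.mean_fitness, 1.0)

    def test_trace_shapes_and_adapted_flag(self):
        cfg = _tiny_config()
        trace = run_population(cfg, np.random.default_rng(1))
        assert trace.n_generations == 50
        assert len(trace.stage_ends) == 2
        assert trace.stage_ends[0].adapted == (trace.stage_ends[0].max_fitness > 0.9)
        assert 0 < trace.stage_ends[1].max_fitness <= 1

    def test_bit_identical_given_seed(self):
        cfg = _tiny_config()
        t1 = run_population(cfg, np.random.default_rng(42))
        t2 = run_population(cfg, np.random.default_rng(42))
        assert np.array_equal(t1.max_fitness, t2.max_fitness)
        assert np.array_equal(t1.mean_fitness, t2.mean_fitness)
        assert np.array_equal(
            t1.focal_network.matrix, t2.focal_network.matrix
        )

    def test_cached_and_uncached_traces_identical(self):
        """Memoizing attractors/fitness per genotype must not change any
        trace relative to the uncached engine on a fixed seed."""
        cfg = _tiny_config(pop_size=30, gens=(15, 15))
        t1 = run_population(cfg, np.random.default_rng(7), use_cache=True)
        t2 = run_population(cfg, np.random.default_rng(7), use_cache=False)
        assert np.array_equal(t1.max_fitness, t2.max_fitness)
        assert np.array_equal(t1.mean_fitness, t2.mean_fitness)
        assert np.array_equal(t1.mean_interactions, t2.mean_interactions)
        assert np.array_equal(t1.focal_network.matrix, t2.focal_network.matrix)

    def test_interaction_count_tracks_gamma(self):
        # neutral regime (kappa 0, mu high, single trivially satisfied target)
        n = 8
        target = np.ones(n, dtype=np.uint8)
        cfg = EvolutionConfig(
            stages=(Stage(TargetSpec((target,), total_cells=10), 120),),
            n_genes=n, pop_size=30, mu=0.3, gamma=0.25, kappa=0.0, selection=0.0,
        )
        trace = run_population(cfg, np.random.default_rng(9))
        expected = 0.25 * n * n
        assert abs(np.mean(trace.mean_interactions[60:]) - expected) < 2.5
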
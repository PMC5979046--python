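"""Scenario runners: two-stage selection, parameter sweeps, epoch switches,
interaction-frequency maps and paired statistics.

The central design is a two-stage experiment.  Populations first adapt to a
single ancestral target expression pattern (GAP I).  Selection then starts
to reward, in addition, a second pattern (GAP II) that agrees with GAP I on
one set of genes (set A) and is complementary on another (set B).  The
partition {A, B} is the mechanistic prediction for where modules should
form, and the partition z-score Q_P^N against degree-preserving null
networks quantifies whether they did.  Under single-target selection no
partition is predicted, so the optimized z-score Q^N is used instead.

Analyses follow the adapted-populations protocol by default: populations
whose maximum fitness exceeds 0.9 at the end of a regime count as adapted,
and one network sampled uniformly among the top-fitness individuals (the
"focal" network) represents each adapted population.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import Genotype
from .evolution import (
    EvolutionConfig,
    Stage,
    TargetSpec,
    run_population,
)
from .modularity import DirectedGraph, Partition
from .nullmodels import (
    NormalizedModularity,
    make_target_pair,
    normalized_qp,
    normalized_qopt,
)

__all__ = [
    "ExperimentResult",
    "two_stage_config",
    "run_two_stage",
    "run_gamma_sweep",
    "run_kappa_sweep",
    "run_epoch_switch",
    "interaction_frequency_map",
    "within_between_frequencies",
    "paired_tests",
    "analyze_empirical_network",
]

Protocol = Literal["adapted_focal", "all_focal", "population_mean"]


@dataclass(frozen=True)
class ExperimentResult:
    """Per-population table plus aggregate statistics.

    ``populations`` carries one row per evolved population; ``aggregate``
    holds summary statistics recomputable from the table; ``metadata``
    records the scenario parameters and seed information.
    """

    populations: pd.DataFrame
    aggregate: dict
    metadata: dict
    focal_networks: dict


@dataclass(frozen=True)
class PairedTestResult:
    w_statistic: float
    p_wilcoxon: float
    ks_statistic: float
    p_ks: float


def paired_tests(
    before: Sequence[float], after: Sequence[float]
) -> PairedTestResult:
    """Wilcoxon signed-rank test (one-sided, increase) on paired scores and
    a two-sample KS test on the two distributions.

    The Wilcoxon statistic is the sum of positive-difference ranks; zero
    differences are dropped and ties receive average ranks.  If every
    difference is zero the test is undefined and reported as W=0, p=1.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if b.shape != a.shape:
        raise ValueError("paired samples must have equal length")
    if b.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        w, p_w = 0.0, 1.0
    else:
        res = stats.wilcoxon(nz, alternative="greater")
        w, p_w = float(res.statistic), float(res.pvalue)
    ks = stats.ks_2samp(b, a)
    return PairedTestResult(w, p_w, float(ks.statistic), float(ks.pvalue))


def interaction_frequency_map(networks: Sequence[Genotype]) -> np.ndarray:
    """Entry (i, j): fraction of the given networks in which gene j
    regulates gene i."""
    if not networks:
        raise ValueError("need at least one network")
    mats = np.stack([np.asarray(g.matrix) for g in networks])
    return (mats != 0).mean(axis=0)


def within_between_frequencies(
    freq: np.ndarray, partition: Partition
) -> tuple[float, float]:
    """Mean interaction frequency within modules vs between modules."""
    memb = partition.membership
    same = memb[:, None] == memb[None, :]
    return float(freq[same].mean()), float(freq[~same].mean())


def _measure(
    genotype: Genotype,
    partition: Partition | None,
    n_rand: int,
    rng: np.random.Generator,
) -> NormalizedModularity:
    graph = DirectedGraph.from_genotype(genotype)
    if partition is not None:
        return normalized_qp(graph, partition, n_rand=n_rand, rng=rng)
    return normalized_qopt(graph, n_rand=n_rand, rng=rng)


def two_stage_config(
    n_differing: int = 5,
    stage1_generations: int = 2000,
    stage2_generations: int = 8000,
    total_cells: int = 100,
    **config_kwargs,
) -> tuple[EvolutionConfig, Partition]:
    """Standard two-stage scenario: selection for GAP I alone, then for
    GAPs I and II differing in ``n_differing`` gene states."""
    n_genes = config_kwargs.pop("n_genes", 10)
    gap_i, gap_ii, partition = make_target_pair(n_genes, n_differing)
    spec1 = TargetSpec((gap_i,), total_cells=total_cells, labels=("I",))
    spec2 = TargetSpec((gap_i, gap_ii), total_cells=total_cells, labels=("I", "II"))
    cfg = EvolutionConfig(
        stages=(
            Stage(spec1, stage1_generations),
            Stage(spec2, stage2_generations),
        ),
        n_genes=n_genes,
        **config_kwargs,
    )
    return cfg, partition


def _spawn(rng: np.random.Generator, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def run_two_stage(
    n_populations: int,
    rng: np.random.Generator,
    config: EvolutionConfig | None = None,
    partition: Partition | None = None,
    n_differing: int = 5,
    n_rand: int = 1000,
    protocol: Protocol = "adapted_focal",
    **config_kwargs,
) -> ExperimentResult:
    """Evolve independent populations through the two-stage scenario and
    measure the partition z-score of the focal network at both stage ends.

    With ``protocol='all_focal'`` every population is scored regardless of
    adaptation; with ``'population_mean'`` the score of a population is the
    mean z over a systematic sample of 10 of its networks instead of a
    single focal network.
    """
    if config is None:
        config, partition = two_stage_config(n_differing=n_differing, **config_kwargs)
    if partition is None:
        raise ValueError("a reference partition is required with an explicit config")
    rows = []
    focals: dict = {}
    for pop_idx, prng in enumerate(_spawn(rng, n_populations)):
        trace = run_population(config, prng)
        end1, end2 = trace.stage_ends[0], trace.stage_ends[-1]
        row = {
            "population": pop_idx,
            "adapted_stage1": end1.adapted,
            "adapted_stage2": end2.adapted,
            "max_fitness_stage1": end1.max_fitness,
            "max_fitness_stage2": end2.max_fitness,
            "n_interactions_focal2": end2.focal.n_interactions,
            "mean_interactions_stage2": end2.mean_interactions,
        }
        use = (end1.adapted and end2.adapted) or protocol == "all_focal"
        if use:
            if protocol == "population_mean":
                z1 = _population_mean_z(end1, partition, n_rand, prng)
                z2 = _population_mean_z(end2, partition, n_rand, prng)
            else:
                z1 = _measure(end1.focal, partition, n_rand, prng).z
                z2 = _measure(end2.focal, partition, n_rand, prng).z
            row["qpn_stage1"] = z1
            row["qpn_stage2"] = z2
            focals[pop_idx] = (end1.focal, end2.focal)
        else:
            row["qpn_stage1"] = np.nan
            row["qpn_stage2"] = np.nan
        rows.append(row)
    columns = [
        "population", "adapted_stage1", "adapted_stage2",
        "max_fitness_stage1", "max_fitness_stage2",
        "n_interactions_focal2", "mean_interactions_stage2",
        "qpn_stage1", "qpn_stage2",
    ]
    table = pd.DataFrame(rows, columns=columns)
    scored = table.dropna(subset=["qpn_stage1", "qpn_stage2"])
    agg = {
        "n_populations": n_populations,
        "n_adapted": int((table.adapted_stage1 & table.adapted_stage2).sum()),
        "mean_qpn_stage1": float(scored.qpn_stage1.mean()) if len(scored) else np.nan,
        "sd_qpn_stage1": float(scored.qpn_stage1.std()) if len(scored) > 1 else np.nan,
        "mean_qpn_stage2": float(scored.qpn_stage2.mean()) if len(scored) else np.nan,
        "sd_qpn_stage2": float(scored.qpn_stage2.std()) if len(scored) > 1 else np.nan,
        "mean_interactions_stage2": float(
            table.loc[table.adapted_stage2, "n_interactions_focal2"].mean()
        ) if table.adapted_stage2.any() else np.nan,
    }
    if len(scored) >= 2:
        test = paired_tests(scored.qpn_stage1, scored.qpn_stage2)
        agg.update(
            wilcoxon_w=test.w_statistic,
            p_wilcoxon=test.p_wilcoxon,
            ks_d=test.ks_statistic,
            p_ks=test.p_ks,
        )
    meta = {
        "scenario": "two_stage",
        "protocol": protocol,
        "n_rand": n_rand,
        "gamma": config.gamma,
        "kappa": config.kappa,
        "stage_generations": [s.n_generations for s in config.stages],
    }
    return ExperimentResult(table, agg, meta, focals)


def _population_mean_z(end, partition, n_rand, rng, n_sample: int = 10) -> float:
    idx = np.linspace(0, len(end.population) - 1, n_sample).astype(int)
    zs = [_measure(end.population[i], partition, n_rand, rng).z for i in idx]
    return float(np.nanmean(zs))


def run_gamma_sweep(
    gammas: Sequence[float],
    n_populations: int,
    rng: np.random.Generator,
    n_rand: int = 1000,
    **kwargs,
) -> dict[float, ExperimentResult]:
    """Two-stage scenario repeated across gain-propensity values."""
    return {
        g: run_two_stage(n_populations, rng, gamma=g, n_rand=n_rand, **kwargs)
        for g in gammas
    }


def run_kappa_sweep(
    kappas: Sequence[float],
    n_populations: int,
    rng: np.random.Generator,
    n_rand: int = 1000,
    **kwargs,
) -> dict[float, ExperimentResult]:
    """Two-stage scenario repeated across perturbation rates (same kappa in
    both stages)."""
    return {
        k: run_two_stage(n_populations, rng, kappa=k, n_rand=n_rand, **kwargs)
        for k in kappas
    }


def run_epoch_switch(
    parameter: Literal["gamma", "kappa"],
    values: tuple[float, float],
    n_targets: int,
    generations_per_epoch: int,
    n_populations: int,
    rng: np.random.Generator,
    n_differing: int = 5,
    n_rand: int = 1000,
    **config_kwargs,
) -> ExperimentResult:
    """One selection regime throughout; a single parameter switches value at
    the epoch boundary.

    Modularity is scored at both epoch ends: the partition z-score Q_P^N
    under two-target selection, and the optimized z-score Q^N under
    single-target selection (no partition is predicted there).
    """
    if parameter not in ("gamma", "kappa"):
        raise ValueError("parameter must be 'gamma' or 'kappa'")
    n_genes = config_kwargs.pop("n_genes", 10)
    total_cells = config_kwargs.pop("total_cells", 100)
    gap_i, gap_ii, partition = make_target_pair(n_genes, n_differing)
    if n_targets == 1:
        spec = TargetSpec((gap_i,), total_cells=total_cells, labels=("I",))
        partition_used = None
    elif n_targets == 2:
        spec = TargetSpec((gap_i, gap_ii), total_cells=total_cells, labels=("I", "II"))
        partition_used = partition
    else:
        raise ValueError("n_targets must be 1 or 2")
    v1, v2 = values
    ov1 = {parameter: v1}
    ov2 = {parameter: v2}
    cfg = EvolutionConfig(
        stages=(
            Stage(spec, generations_per_epoch, **ov1),
            Stage(spec, generations_per_epoch, **ov2),
        ),
        n_genes=n_genes,
        **config_kwargs,
    )
    rows = []
    focals: dict = {}
    score_col = "qpn" if partition_used is not None else "qn"
    for pop_idx, prng in enumerate(_spawn(rng, n_populations)):
        trace = run_population(cfg, prng)
        end1, end2 = trace.stage_ends
        row = {
            "population": pop_idx,
            "adapted_epoch1": end1.adapted,
            "adapted_epoch2": end2.adapted,
            "n_interactions_focal2": end2.focal.n_interactions,
        }
        if end1.adapted and end2.adapted:
            row[f"{score_col}_epoch1"] = _measure(end1.focal, partition_used, n_rand, prng).z
            row[f"{score_col}_epoch2"] = _measure(end2.focal, partition_used, n_rand, prng).z
            focals[pop_idx] = (end1.focal, end2.focal)
        else:
            row[f"{score_col}_epoch1"] = np.nan
            row[f"{score_col}_epoch2"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    c1, c2 = f"{score_col}_epoch1", f"{score_col}_epoch2"
    scored = table.dropna(subset=[c1, c2])
    agg = {
        "n_populations": n_populations,
        "n_adapted": len(scored),
        f"mean_{c1}": float(scored[c1].mean()) if len(scored) else np.nan,
        f"mean_{c2}": float(scored[c2].mean()) if len(scored) else np.nan,
        f"sd_{c1}": float(scored[c1].std()) if len(scored) > 1 else np.nan,
        f"sd_{c2}": float(scored[c2].std()) if len(scored) > 1 else np.nan,
    }
    if len(scored) >= 2:
        test = paired_tests(scored[c1], scored[c2])
        agg.update(
            wilcoxon_w=test.w_statistic,
            p_wilcoxon=test.p_wilcoxon,
            ks_d=test.ks_statistic,
            p_ks=test.p_ks,
        )
    meta = {
        "scenario": "epoch_switch",
        "parameter": parameter,
        "values": list(values),
        "n_targets": n_targets,
        "generations_per_epoch": generations_per_epoch,
        "score": score_col,
        "n_rand": n_rand,
    }
    return ExperimentResult(table, agg, meta, focals)


def analyze_empirical_network(
    edge_list_path,
    n_rand: int = 1000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Normalized optimized modularity of a network given as an edge list.

    Returns the four columns of a summary row: raw Q, null-ensemble mean
    and SD, and the z-score Q^N.
    """
    from .io import read_edge_list

    graph = read_edge_list(edge_list_path)
    if graph.n_edges < 2:
        raise ValueError("network too small for a null ensemble")
    rng = np.random.default_rng() if rng is None else rng
    nm = normalized_qopt(graph, n_rand=n_rand, rng=rng)
    return {
        "nodes": graph.n_nodes,
        "interactions": graph.n_edges,
        "Q": nm.raw,
        "Q_null_mean": nm.null_mean,
        "Q_null_sd": nm.null_sd,
        "QN": nm.z,
    }
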
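"""File formats and run manifests.

Edge lists are tab-separated text with a header line
``source<TAB>target[<TAB>sign]``; comment lines start with ``#``.  The sign
column is optional and defaults to +1.  An edge ``source -> target`` (the
source regulates the target) corresponds to the genotype entry
``G[target, source]`` -- note the index order, which also fixes which
degree is "in" and which is "out" in the modularity score.

Genotype files use the same dialect with a weight column and a ``# N=``
header so that genes without any interaction survive a round-trip.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .dynamics import Genotype
from .modularity import DirectedGraph

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_genotype",
    "write_genotype",
    "load_config",
    "write_manifest",
]


class EdgeListError(ValueError):
    pass


def _parse_rows(path: Path, expect_cols: tuple[int, ...]):
    lines = Path(path).read_text().splitlines()
    rows = []
    header_meta = {}
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            for token in body.split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    header_meta[k] = v
            continue
        parts = stripped.split("\t")
        if not header_seen:
            header_seen = True
            if parts[0].lower() == "source":
                continue  # column header
        if len(parts) not in expect_cols:
            raise EdgeListError(f"{path}:{lineno}: expected {expect_cols} columns, got {len(parts)}")
        rows.append((lineno, parts))
    if not rows:
        raise EdgeListError(f"{path}: no edges found")
    return rows, header_meta


def read_edge_list(path) -> DirectedGraph:
    """Read a TSV edge list into a directed graph.

    Node labels are mapped to dense indices in first-appearance order;
    duplicate edges are an error (the offending line is named).
    """
    rows, _ = _parse_rows(Path(path), (2, 3))
    index: dict[str, int] = {}
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for lineno, parts in rows:
        src_label, dst_label = parts[0], parts[1]
        if not src_label or not dst_label:
            raise EdgeListError(f"line {lineno}: empty node label")
        if len(parts) == 3 and parts[2] not in ("1", "+1", "-1"):
            raise EdgeListError(f"line {lineno}: sign must be +1 or -1")
        for lab in (src_label, dst_label):
            if lab not in index:
                index[lab] = len(index)
        e = (index[src_label], index[dst_label])
        if e in seen:
            raise EdgeListError(f"line {lineno}: duplicate edge {src_label}->{dst_label}")
        seen.add(e)
        edges.append(e)
    labels = sorted(index, key=index.get)
    return DirectedGraph(len(index), edges, labels=labels)


def write_edge_list(graph: DirectedGraph, path) -> None:
    labels = graph.labels or [str(i) for i in range(graph.n_nodes)]
    lines = ["source\ttarget"]
    for s, t in graph.edges:
        lines.append(f"{labels[s]}\t{labels[t]}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_genotype(genotype: Genotype, path) -> None:
    """Signed weighted edge list carrying the genotype matrix losslessly."""
    n = genotype.n_genes
    lines = [f"# N={n} mode={genotype.mode}", "source\ttarget\tweight"]
    mat = np.asarray(genotype.matrix)
    for i in range(n):
        for j in range(n):
            if mat[i, j] != 0:
                w = int(mat[i, j]) if genotype.mode == "discrete" else repr(float(mat[i, j]))
                lines.append(f"g{j}\tg{i}\t{w}")  # edge j -> i
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype(path) -> Genotype:
    rows, meta = _parse_rows(Path(path), (3,))
    if "N" not in meta:
        raise EdgeListError(f"{path}: missing '# N=' header")
    n = int(meta["N"])
    mode = meta.get("mode", "discrete")
    mat = np.zeros((n, n), dtype=np.float64 if mode == "continuous" else np.int8)
    seen = set()
    for lineno, (src, dst, w) in ((ln, p) for ln, p in rows):
        j = int(src.lstrip("g"))
        i = int(dst.lstrip("g"))
        if (i, j) in seen:
            raise EdgeListError(f"line {lineno}: duplicate entry g{j}->g{i}")
        seen.add((i, j))
        mat[i, j] = float(w)
    return Genotype(mat, mode=mode)


_CONFIG_FIELDS = {
    "n_genes": int,
    "pop_size": int,
    "mu": float,
    "gamma": float,
    "kappa": float,
    "selection": float,
    "mutation_variant": str,
    "threshold_rule": str,
    "n_differing": int,
    "total_cells": int,
    "stage1_generations": int,
    "stage2_generations": int,
    "generations_per_epoch": int,
    "n_populations": int,
    "n_rand": int,
    "n_targets": int,
    "parameter": str,
    "values": list,
    "gammas": list,
    "kappas": list,
    "protocol": str,
    "n_nodes": int,
    "n_edges": int,
    "n_networks": int,
}


def load_config(path) -> dict:
    """Flat key-value scenario configuration (YAML); unknown keys are
    rejected to catch typos in parameter sweeps."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    out = {}
    for key, value in raw.items():
        if key not in _CONFIG_FIELDS:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
        caster = _CONFIG_FIELDS[key]
        out[key] = caster(value) if caster is not list else list(value)
    return out


def write_manifest(out_dir, scenario: str, params: dict, seed: int) -> Path:
    """Record everything needed to re-run a scenario bit-identically."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scenario": scenario,
        "parameters": params,
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
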
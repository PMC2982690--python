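"""Ground-truthed synthetic expression data.

Emulates short, equally sampled, cell-cycle-like microarray series: source
genes follow smooth periodic signals (one or two sinusoids with random
phase) plus Gaussian noise, each planted regulatory edge copies its source
into the target after an integer-sample lag scaled by a coupling strength,
and uninvolved genes are independent noise.  The planted edge list is the
ground truth every downstream stage is scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import ExpressionProfile, write_expression_table

__all__ = [
    "PlantedEdge",
    "PlantedNetwork",
    "generate",
    "random_planted_network",
    "DEFAULT_REGIME",
]


@dataclass(frozen=True)
class PlantedEdge:
    source: str
    target: str
    lag_samples: int
    coupling: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-edges are not allowed")
        if self.lag_samples < 1:
            raise ValueError("lag must be a positive number of samples")
        if not 0.0 < self.coupling <= 1.0:
            raise ValueError("coupling must lie in (0, 1]")


@dataclass(frozen=True)
class PlantedNetwork:
    """A sparse ground-truth network to emit expression data from."""

    n_genes: int
    time_points: int
    edges: frozenset[PlantedEdge]
    noise_sd: float = 0.2
    seed: int = 42
    time_step_h: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        if self.n_genes < 2:
            raise ValueError("need at least two genes")
        if self.time_points < 4:
            raise ValueError("need at least four time points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for e in self.edges:
            if e.lag_samples >= self.time_points / 2:
                raise ValueError(
                    f"lag {e.lag_samples} too large for {self.time_points} points"
                )
        n_pairs = self.n_genes * (self.n_genes - 1) // 2
        if len({frozenset((e.source, e.target)) for e in self.edges}) > 0.5 * n_pairs:
            raise ValueError("edge density exceeds 0.5")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        width = len(str(self.n_genes))
        return tuple(f"G{i + 1:0{width}d}" for i in range(self.n_genes))


def _gene_order(planted: PlantedNetwork) -> list[str]:
    """Topological order of the planted DAG (roots first)."""
    parents: dict[str, list[PlantedEdge]] = {g: [] for g in planted.gene_ids}
    for e in planted.edges:
        if e.source not in parents or e.target not in parents:
            raise ValueError(f"edge {e} references an unknown gene")
        parents[e.target].append(e)
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(g: str) -> None:
        if state.get(g) == 2:
            return
        if state.get(g) == 1:
            raise ValueError("planted edges form a cycle")
        state[g] = 1
        for e in parents[g]:
            visit(e.source)
        state[g] = 2
        order.append(g)

    for g in planted.gene_ids:
        visit(g)
    return order


def generate(planted: PlantedNetwork):
    """Emit ``(ExpressionProfile, truth DataFrame)`` for a planted network.

    Deterministic for a fixed seed.  The truth table lists exactly the
    planted edges (source, target, lag_samples, coupling).
    """
    import pandas as pd

    rng = np.random.default_rng(planted.seed)
    T = planted.time_points
    genes = planted.gene_ids
    parents: dict[str, list[PlantedEdge]] = {g: [] for g in genes}
    for e in planted.edges:
        parents[e.target].append(e)

    # cumulative lag along the deepest ancestral path decides the padding
    # needed so every delayed copy has real samples to copy from
    order = _gene_order(planted)
    depth: dict[str, int] = {}
    for g in order:
        depth[g] = max(
            (depth[e.source] + e.lag_samples for e in parents[g]), default=0
        )
    pad = max(depth.values(), default=0)
    ext = pad + T

    signals: dict[str, np.ndarray] = {}
    # one rng draw sequence per gene in id order keeps output independent of
    # the topological-visit order
    draws: dict[str, tuple] = {}
    for g in genes:
        period = rng.uniform(0.45 * T, 0.95 * T)
        phase = rng.uniform(0.0, 2.0 * math.pi)
        harmonic = rng.random() < 0.5
        noise = rng.normal(0.0, planted.noise_sd, size=ext)
        draws[g] = (period, phase, harmonic, noise)

    for g in order:
        period, phase, harmonic, noise = draws[g]
        if parents[g]:
            base = np.zeros(ext)
            for e in sorted(parents[g], key=lambda e: e.source):
                shifted = np.empty(ext)
                shifted[e.lag_samples :] = signals[e.source][: ext - e.lag_samples]
                shifted[: e.lag_samples] = signals[e.source][0]
                base += e.coupling * shifted
            signals[g] = base + noise
        elif any(e.source == g for e in planted.edges):
            t = np.arange(ext, dtype=float)
            base = np.sin(2 * math.pi * t / period + phase)
            if harmonic:
                base = base + 0.5 * np.sin(4 * math.pi * t / period + 2 * phase)
            signals[g] = base + noise
        else:
            signals[g] = noise  # independent gene: noise only

    values = np.vstack([signals[g][pad:] for g in genes])
    times = np.arange(T, dtype=float) * planted.time_step_h
    profile = ExpressionProfile(genes, times, values)
    truth = pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "lag_samples": e.lag_samples,
                "coupling": e.coupling,
            }
            for e in sorted(planted.edges, key=lambda e: (e.source, e.target))
        ]
    )
    return profile, truth


def random_planted_network(
    n_genes: int = 24,
    time_points: int = 14,
    n_edges: int = 20,
    noise_sd: float = 0.2,
    seed: int = 42,
    max_lag: int = 1,
    coupling_range: tuple[float, float] = (0.6, 1.0),
    time_step_h: float = 0.5,
) -> PlantedNetwork:
    """Draw a random sparse planted network in the default study regime.

    Targets are distinct and disjoint from sources, so each target copies a
    root signal directly and lags never accumulate along chains.
    """
    if n_edges >= n_genes:
        raise ValueError("need n_edges < n_genes so at least one root remains")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]
    shuffled = list(rng.permutation(genes))
    targets = shuffled[:n_edges]
    roots = shuffled[n_edges:]
    edges = set()
    for tgt in targets:
        src = roots[int(rng.integers(len(roots)))]
        lag = int(rng.integers(1, max_lag + 1))
        coupling = float(rng.uniform(*coupling_range))
        edges.add(PlantedEdge(src, tgt, lag, coupling))
    return PlantedNetwork(
        n_genes, time_points, frozenset(edges), noise_sd, seed, time_step_h
    )


#: the frozen default study regime used by the end-to-end recovery checks
DEFAULT_REGIME = dict(
    n_genes=24, time_points=14, n_edges=20, noise_sd=0.2, seed=42
)


def write_dataset(
    planted: PlantedNetwork, outdir: str | Path
) -> tuple[Path, Path]:
    """Write the expression table and truth edge table; return their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profile, truth = generate(planted)
    expr_path = outdir / "expression.tsv"
    truth_path = outdir / "truth_edges.tsv"
    write_expression_table(profile, expr_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return expr_path, truth_path
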
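"""Model/Results layer: one object per analysis, statsmodels-style.

``GeneNetworkModel`` holds the expression profile and every supervision
knob (bins, AM weights, p-value policy, the APG band, threshold increments,
gain threshold, knowledge constraints).  ``fit()`` runs the full pipeline —
pairwise metrics, centroid initialisation, optional p-threshold adaptation,
the PGHC/MOCO threshold walk, per-pair direction calls, network assembly —
and returns a ``GeneNetworkResults`` carrying the estimates, partitions,
diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import moco as _moco
from . import network as _network
from . import pairwise as _pairwise
from . import pghc as _pghc
from . import spectral as _spectral
from .io import ExpressionProfile, read_expression_table

__all__ = ["GeneNetworkModel", "GeneNetworkResults"]


class GeneNetworkModel:
    """Supervised regulatory-network model over an expression time series.

    Parameters
    ----------
    profile
        Genes x time-points log2 expression matrix.
    bins
        Histogram bins for mutual information (default Sturges on T).
    weights
        AM weights ``(w1, w2)`` or ``"centroid"`` for 1/centroid per axis.
    p_threshold
        Significance threshold for the correlation route.
    adapt_p
        If true and fewer than the band's lower fraction of pairs reach
        ``p_threshold``, lift it along the fixed ladder (the supervision
        step short weakly-significant series require).
    apg_band
        Target APG fraction interval for the threshold walk.
    delta_mi, delta_cc
        PGHC threshold increments (bits / correlation units).
    gain_threshold
        Transfer-gain cut below which no direction is called.
    zero_phase_tol
        Phase magnitude (radians) below which a pair is undirected.
    knowledge
        Forced/forbidden edge constraints, or None.
    """

    def __init__(
        self,
        profile: ExpressionProfile,
        *,
        bins: int | None = None,
        weights: tuple[float, float] | str = "centroid",
        p_threshold: float = 0.05,
        adapt_p: bool = True,
        apg_band: tuple[float, float] = _pghc.DEFAULT_BAND,
        delta_mi: float = 0.005,
        delta_cc: float = 0.005,
        gain_threshold: float = 0.3,
        zero_phase_tol: float = _spectral.DEFAULT_ZERO_PHASE_TOL,
        knowledge: _moco.KnowledgeConstraints | None = None,
        max_iterations: int = 10_000,
    ) -> None:
        if profile.n_genes < 2:
            raise ValueError("network inference needs at least two genes")
        self.profile = profile
        self.bins = bins if bins is not None else _pairwise.default_bins(
            profile.n_time_points
        )
        self.weights = weights
        self.p_threshold = p_threshold
        self.adapt_p = adapt_p
        self.apg_band = apg_band
        self.delta_mi = delta_mi
        self.delta_cc = delta_cc
        self.gain_threshold = gain_threshold
        self.zero_phase_tol = zero_phase_tol
        self.knowledge = knowledge or _moco.KnowledgeConstraints(
            gain_threshold=gain_threshold
        )
        self.max_iterations = max_iterations

    # ------------------------------------------------------------------ #
    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "GeneNetworkModel":
        return cls(read_expression_table(path), **kwargs)

    @classmethod
    def from_dataframe(cls, frame, **kwargs) -> "GeneNetworkModel":
        """Build from a DataFrame indexed by gene with time (hours) columns."""
        profile = ExpressionProfile(
            tuple(str(g) for g in frame.index),
            np.asarray([float(c) for c in frame.columns]),
            frame.to_numpy(dtype=float),
        )
        return cls(profile, **kwargs)

    # ------------------------------------------------------------------ #
    def fit(self) -> "GeneNetworkResults":
        stats = _pairwise.all_pair_stats(self.profile, self.bins, self.weights)
        cents = _pairwise.centroids(stats)

        p_th = self.p_threshold
        p_adapted = False
        lo = self.apg_band[0]
        if self.adapt_p:
            n = len(stats)
            if sum(s.p_value <= p_th for s in stats) / n < lo:
                p_th = _pghc.adapt_p_threshold(stats, lo)
                p_adapted = True

        init = _pghc.Thresholds(
            mi_th=cents.mi_centroid,
            cc_th=min(cents.cor_centroid, 1.0),
            p_th=p_th,
            delta_mi=self.delta_mi,
            delta_cc=self.delta_cc,
        )
        moco_result = _moco.solve(
            stats, init, self.knowledge, self.apg_band, self.max_iterations
        )
        partition = moco_result.partition

        calls: dict[tuple[str, str], _spectral.PhaseCall] = {}
        spectra: dict[tuple[str, str], _spectral.CrossSpectrum] = {}
        for pair in sorted(partition.apgs):
            a, b = pair
            sp = _spectral.cross_spectrum(
                self.profile.series(a), self.profile.series(b)
            )
            spectra[pair] = sp
            calls[pair] = _spectral.call_direction(
                sp, self.gain_threshold, self.zero_phase_tol
            )

        net = _network.build_network(
            partition,
            calls,
            stats,
            list(self.profile.gene_ids),
            forced_edges=self.knowledge.forced_edges,
            forced_flags=moco_result.forced_flags,
        )
        return GeneNetworkResults(
            model=self,
            pair_stats=stats,
            centroids=cents,
            initial_thresholds=init,
            p_threshold_used=p_th,
            p_threshold_adapted=p_adapted,
            moco=moco_result,
            phase_calls=calls,
            spectra=spectra,
            network=net,
        )


@dataclass
class GeneNetworkResults:
    """Fitted pipeline state: estimates, partition, calls, network."""

    model: GeneNetworkModel
    pair_stats: list[_pairwise.PairStats]
    centroids: _pairwise.MetricCentroids
    initial_thresholds: _pghc.Thresholds
    p_threshold_used: float
    p_threshold_adapted: bool
    moco: _moco.MocoResult
    phase_calls: dict[tuple[str, str], _spectral.PhaseCall]
    spectra: dict[tuple[str, str], _spectral.CrossSpectrum]
    network: _network.RegulatoryNetwork

    # -- convenience views --------------------------------------------- #
    @property
    def partition(self) -> _pghc.Partition:
        return self.moco.partition

    @property
    def thresholds_(self) -> _pghc.Thresholds:
        return self.partition.thresholds_used

    @property
    def converged(self) -> bool:
        return self.partition.converged

    def pair_stats_frame(self):
        return _pairwise.stats_to_frame(self.pair_stats)

    def partition_frame(self):
        import pandas as pd

        rows = []
        for group, pairs in (
            ("APG", self.partition.apgs),
            ("QPG", self.partition.qpgs),
            ("UPG", self.partition.upgs),
        ):
            for a, b in sorted(pairs):
                rows.append({"gene_a": a, "gene_b": b, "group": group})
        return pd.DataFrame(rows)

    def phase_frame(self):
        import pandas as pd

        rows = []
        for (a, b), call in sorted(self.phase_calls.items()):
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "direction": call.direction,
                    "dominant_frequency": call.dominant_frequency,
                    "phase_rad": call.phase_rad,
                    "gain": call.gain_at_dominant,
                    "coherence": call.coherence_at_dominant,
                }
            )
        return pd.DataFrame(rows)

    def degree_summary(self):
        return _network.degree_summary(self.network)

    # -- reporting ------------------------------------------------------ #
    def summary(self) -> str:
        part = self.partition
        th = self.thresholds_
        _, mean_deg = self.degree_summary()
        n_directed = len(self.network.directed_edges)
        n_undirected = len(self.network.undirected_edges)
        lines = [
            "Gene regulatory network inference",
            "=" * 50,
            f"genes: {self.model.profile.n_genes}   "
            f"time points: {self.model.profile.n_time_points}   "
            f"pairs: {part.n_pairs}",
            f"MI bins: {self.model.bins}",
            f"centroids: MI {self.centroids.mi_centroid:.4f}  "
            f"|r| {self.centroids.cor_centroid:.4f}",
            f"p threshold: {self.p_threshold_used:g}"
            + ("  (adapted along the ladder)" if self.p_threshold_adapted else ""),
            f"terminal thresholds: MI {th.mi_th:.4f}  |r| {th.cc_th:.4f}",
            f"PGHC iterations: {part.iterations}   status: {part.status}",
            f"partition: APGs {len(part.apgs)}  QPGs {len(part.qpgs)}  "
            f"UPGs {len(part.upgs)}  (APG fraction {part.apg_fraction:.3f})",
            f"gain threshold: {self.model.gain_threshold:g}   "
            f"zero-phase tol: {self.model.zero_phase_tol:.4f} rad",
            f"edges: {n_directed} directed, {n_undirected} undirected",
            f"mean total degree: {mean_deg:.2f}",
            "constraints: "
            + (
                "all satisfied"
                if self.moco.satisfied
                else "VIOLATED: "
                + ", ".join(
                    r.name for r in self.moco.constraint_report if not r.passed
                )
            ),
        ]
        return "\n".join(lines)

    def save_bundle(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full output bundle (tables, network files, run log)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pair_stats": outdir / "pair_stats.tsv",
            "partition": outdir / "partition.tsv",
            "phase": outdir / "phase_calls.tsv",
            "edge_table": outdir / "network_edges.tsv",
            "sif": outdir / "network.sif",
            "graphml": outdir / "network.graphml",
            "degrees": outdir / "degree_summary.tsv",
            "log": outdir / "run_log.txt",
        }
        self.pair_stats_frame().to_csv(paths["pair_stats"], sep="\t", index=False)
        self.partition_frame().to_csv(paths["partition"], sep="\t", index=False)
        self.phase_frame().to_csv(paths["phase"], sep="\t", index=False)
        _network.export_network(self.network, paths["edge_table"], "edge-table")
        _network.export_network(self.network, paths["sif"], "sif")
        _network.export_network(self.network, paths["graphml"], "graphml")
        deg, _ = self.degree_summary()
        deg.to_csv(paths["degrees"], sep="\t")
        with paths["log"].open("w") as fh:
            fh.write(self.summary() + "\n\n")
            fh.write("PGHC trace (iteration, mi_th, cc_th, |APGs|):\n")
            for rec in self.partition.trace:
                fh.write(f"  {rec[0]:5d}  {rec[1]:.4f}  {rec[2]:.4f}  {rec[3]}\n")
            fh.write("\nConstraint report:\n")
            for rec in self.moco.constraint_report:
                mark = "pass" if rec.passed else "FAIL"
                fh.write(f"  [{mark}] {rec.name}" + (f"  {rec.detail}" if rec.detail else "") + "\n")
        return paths
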
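"""Synthetic single-cell expression fixtures with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
distinct cell populations carrying cluster-specific signature genes,
housekeeping genes expressed uniformly everywhere, low noise genes that
should fall to the expression filter, multiplicative batch scale
differences between sample preparations, and -- optionally -- a linear
TF -> target regulatory program planted inside one cluster.

Abundances are log-normal: every cell value is ``2**(mu_g + N(0, sd))``
times its batch scale factor, with ``mu_g`` the gene's log2 baseline,
elevated by a configurable log2-fold change for signature genes in their
own cluster.  Ground-truth labels, signature lists, a marker panel, a
cell-type association table, and planted edges are emitted alongside
every fixture so that downstream accuracy can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, MarkerPanel, apply_expression_floor

__all__ = ["SimulationConfig", "SimulationResult", "simulate_cells",
           "simulate_regulatory_program"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    The defaults describe three well-separated populations measured in
    two batches, with 20 signature genes per population elevated by
    3 log2-fold over their baseline, 30 housekeeping genes, and 50 noise
    genes below the expression filter.
    """

    n_clusters: int = 3
    cells_per_cluster: list[int] = field(default_factory=lambda: [30, 25, 20])
    n_signature_genes: list[int] | int = 20
    n_housekeeping: int = 30
    n_noise_genes: int = 50
    signature_log2_fold: float = 3.0
    baseline_log2: float = 1.0
    housekeeping_log2: float = 5.0
    noise_gene_log2: float = -2.0
    batch_scales: list[float] = field(default_factory=lambda: [1.0, 1.5])
    noise_sd: float = 0.3
    markers_per_cluster: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cells_per_cluster) != self.n_clusters:
            raise ValueError("cells_per_cluster length must equal n_clusters")
        if isinstance(self.n_signature_genes, int):
            self.n_signature_genes = [self.n_signature_genes] * self.n_clusters
        if len(self.n_signature_genes) != self.n_clusters:
            raise ValueError("n_signature_genes length must equal n_clusters")
        if any(n < 0 for n in self.cells_per_cluster):
            raise ValueError("cell counts must be >= 0")
        if any(s <= 0 for s in self.batch_scales):
            raise ValueError("batch scale factors must be positive")


@dataclass
class SimulationResult:
    """A fixture plus every piece of ground truth needed to score it."""

    expression: ExpressionMatrix
    true_labels: pd.Series  # cell_id -> cluster label (C1..Ck)
    signature_genes: dict[str, list[str]]  # cluster -> planted signatures
    marker_panel: MarkerPanel
    association_table: pd.DataFrame
    config: SimulationConfig


def simulate_cells(cfg: SimulationConfig) -> SimulationResult:
    """Draw a synthetic cohort according to ``cfg`` (bitwise reproducible)."""
    rng = np.random.default_rng(cfg.seed)
    clusters = [f"C{l + 1}" for l in range(cfg.n_clusters)]

    cell_ids, cell_cluster, cell_batch = [], [], []
    counter = 0
    for label, n_cells in zip(clusters, cfg.cells_per_cluster):
        for _ in range(n_cells):
            cell_ids.append(f"cell{counter:03d}")
            cell_cluster.append(label)
            # round-robin so every batch contains every population
            cell_batch.append(counter % len(cfg.batch_scales))
            counter += 1

    gene_ids: list[str] = []
    base = []  # per-gene log2 baseline
    boost: list[tuple[int, str] | None] = []  # (row, cluster) for signatures
    signature_genes: dict[str, list[str]] = {c: [] for c in clusters}
    for label, n_sig in zip(clusters, cfg.n_signature_genes):
        for s in range(n_sig):
            g = f"sig_{label}_{s:03d}"
            signature_genes[label].append(g)
            boost.append((len(gene_ids), label))
            gene_ids.append(g)
            base.append(cfg.baseline_log2)
    for h in range(cfg.n_housekeeping):
        gene_ids.append(f"hk_{h:03d}")
        base.append(cfg.housekeeping_log2)
        boost.append(None)
    for n in range(cfg.n_noise_genes):
        gene_ids.append(f"noise_{n:03d}")
        base.append(cfg.noise_gene_log2)
        boost.append(None)

    mu = np.tile(np.array(base, dtype=float)[:, None], (1, len(cell_ids)))
    cluster_arr = np.array(cell_cluster)
    for entry in boost:
        if entry is None:
            continue
        row, label = entry
        mu[row, cluster_arr == label] += cfg.signature_log2_fold

    log2_vals = mu + rng.normal(0.0, cfg.noise_sd, size=mu.shape)
    scales = np.array([cfg.batch_scales[b] for b in cell_batch])
    values = (2.0**log2_vals) * scales[None, :]

    E = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=cell_ids),
        pd.Series(
            [f"sample{b + 1}" for b in cell_batch], index=cell_ids, name="sample"
        ),
    )
    E = apply_expression_floor(E)

    markers = {
        f"type_{label}": signature_genes[label][: cfg.markers_per_cluster]
        for label in clusters
        if signature_genes[label]
    }
    assoc_rows = [
        (g, f"type_{label}", 0.01, "positive")
        for label in clusters
        for g in signature_genes[label]
    ]
    assoc = pd.DataFrame(
        assoc_rows, columns=["gene", "cell_type", "support_pvalue", "direction"]
    )
    return SimulationResult(
        expression=E,
        true_labels=pd.Series(cell_cluster, index=cell_ids, name="cluster"),
        signature_genes=signature_genes,
        marker_panel=MarkerPanel(markers),
        association_table=assoc,
        config=cfg,
    )


def simulate_regulatory_program(
    n_cells: int = 40,
    n_tfs: int = 2,
    targets_per_tf: int = 5,
    n_decoy_tfs: int = 5,
    coefficient: float = 1.0,
    noise_sd: float = 0.25,
    tfs_per_target: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, set[str], set[str], list[tuple[str, str]]]:
    """Plant a linear TF -> target program over one cluster's cells.

    Regulating and decoy TF profiles are i.i.d. standard normal; every
    target is the sum of ``coefficient`` times each of its TFs plus
    Gaussian noise.  Returns the genes x cells expression table, the TF
    candidate set (regulators plus decoys), the target set, and the
    ground-truth edge list.
    """
    if tfs_per_target > n_tfs:
        raise ValueError("tfs_per_target cannot exceed n_tfs")
    rng = np.random.default_rng(seed)
    cells = [f"cell{j:03d}" for j in range(n_cells)]
    tf_ids = [f"TF{t}" for t in range(n_tfs)]
    decoy_ids = [f"decoyTF{t}" for t in range(n_decoy_tfs)]
    profiles: dict[str, np.ndarray] = {}
    for t in tf_ids + decoy_ids:
        profiles[t] = rng.normal(0.0, 1.0, size=n_cells)
    true_edges: list[tuple[str, str]] = []
    target_ids = []
    for t_idx, tf in enumerate(tf_ids):
        for s in range(targets_per_tf):
            tg = f"target_{tf}_{s}"
            target_ids.append(tg)
            regulators = [tf]
            extra = [x for x in tf_ids if x != tf][: tfs_per_target - 1]
            regulators += extra
            signal = sum(coefficient * profiles[r] for r in regulators)
            profiles[tg] = signal + rng.normal(0.0, noise_sd, size=n_cells)
            true_edges += [(r, tg) for r in regulators]
    table = pd.DataFrame(
        {g: profiles[g] for g in tf_ids + decoy_ids + target_ids},
        index=cells,
    ).T
    return (
        table,
        set(tf_ids + decoy_ids),
        set(target_ids),
        sorted(set(true_edges)),
    )
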
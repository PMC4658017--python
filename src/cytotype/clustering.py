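"""Unsupervised hierarchical clustering of cells and cluster significance.

Cells are clustered agglomeratively on a centered-Pearson distance
(``d = 1 - r``, range [0, 2]) with average linkage by default.  The tree
can be cut at a fixed height, at a fixed number of clusters, or -- when
neither is given -- at the smallest merge height whose clustering leaves
no more than ``gamma`` singleton clusters.

A permutation test quantifies whether the resulting partition captures
more within-cluster coherence than expected by chance: the statistic is
the mean within-cluster minus mean between-cluster cell-cell Pearson
correlation, and the null is built by independently permuting each gene's
values across cells and re-clustering with identical settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "cell_distance_matrix",
    "hierarchical_clusters",
    "permutation_significance",
    "coherence_statistic",
]


@dataclass
class ClusterAssignment:
    """Partition of cells into k labelled clusters.

    Cluster labels are ``C1..Ck`` in decreasing cluster-size order (ties
    broken by the lexicographically smallest member cell ID).
    """

    labels: pd.Series  # cell_id -> cluster label
    linkage_record: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.labels.nunique()

    @property
    def cluster_names(self) -> list[str]:
        return sorted(self.labels.unique(), key=lambda c: int(c[1:]))

    def cells_in(self, cluster: str) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def cell_distance_matrix(
    Z: ExpressionMatrix, metric: str = "centered_pearson"
) -> pd.DataFrame:
    """Symmetric cell-cell distance matrix.

    ``centered_pearson`` gives ``d(a, b) = 1 - r(a, b)`` where ``r`` is the
    Pearson correlation of the two cells' gene vectors (range [0, 2]);
    ``euclidean`` is the plain L2 distance.
    """
    vals = Z.values.to_numpy(dtype=float)
    cells = Z.cell_ids
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise ValueError("need >= 2 genes and >= 2 cells")
    if metric == "centered_pearson":
        sd = vals.std(axis=0, ddof=0)
        if (sd == 0).any():
            bad = [cells[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(
                f"constant cell vectors (correlation undefined): {bad[:5]}"
            )
        r = np.corrcoef(vals, rowvar=False)
        d = 1.0 - r
    elif metric == "euclidean":
        diff = vals[:, :, None] - vals[:, None, :]
        d = np.sqrt((diff**2).sum(axis=0))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=cells, columns=cells)


def _relabel_by_size(flat: np.ndarray, cells: list[str]) -> pd.Series:
    """Map raw flat-cluster codes to C1..Ck in decreasing size order."""
    groups: dict[int, list[str]] = {}
    for cell, code in zip(cells, flat):
        groups.setdefault(int(code), []).append(cell)
    ordered = sorted(
        groups.values(), key=lambda cs: (-len(cs), min(cs))
    )
    labels = {}
    for idx, members in enumerate(ordered, start=1):
        for cell in members:
            labels[cell] = f"C{idx}"
    return pd.Series({c: labels[c] for c in cells}, name="cluster")


def hierarchical_clusters(
    D: pd.DataFrame,
    linkage: str = "average",
    threshold: float | None = None,
    k: int | None = None,
    gamma: int | None = None,
) -> ClusterAssignment:
    """Agglomerative clustering of cells from a distance matrix.

    Exactly one cutting rule applies: ``threshold`` cuts the dendrogram at
    that height; ``k`` cuts to that many clusters; otherwise the merge
    heights are scanned in ascending order and the cut is placed at the
    smallest height whose clustering contains at most ``gamma`` singleton
    clusters (``gamma`` defaults to 0, i.e. no singletons).

    Cells are ordered lexicographically before linkage so that the result
    does not depend on input order.
    """
    if linkage not in ("average", "ward"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if threshold is not None and k is not None:
        raise ValueError("give at most one of threshold and k")
    cells = sorted(D.index)
    Dm = D.loc[cells, cells].to_numpy(dtype=float)
    condensed = squareform(Dm, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)

    if threshold is not None:
        flat = hierarchy.fcluster(Z, t=threshold, criterion="distance")
    elif k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    else:
        gamma = 0 if gamma is None else gamma
        flat = _gamma_search(Z, gamma)
    labels = _relabel_by_size(flat, cells)
    return ClusterAssignment(labels=labels, linkage_record=Z)


def _gamma_search(Z: np.ndarray, gamma: int) -> np.ndarray:
    """Smallest merge-height cut leaving <= gamma singleton clusters."""
    heights = np.unique(Z[:, 2])
    for h in heights:
        flat = hierarchy.fcluster(Z, t=h, criterion="distance")
        sizes = np.bincount(flat)
        if (sizes == 1).sum() <= gamma:
            return flat
    # cutting above the root always yields one (non-singleton) cluster
    return np.ones(Z.shape[0] + 1, dtype=int)


def coherence_statistic(
    Z: ExpressionMatrix, assignment: ClusterAssignment
) -> float:
    """Mean within-cluster minus mean between-cluster cell correlation."""
    vals = Z.values.to_numpy(dtype=float)
    cells = Z.cell_ids
    labels = assignment.labels.reindex(cells).to_numpy()
    r = np.corrcoef(vals, rowvar=False)
    n = len(cells)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    if not same.any() or same.all():
        raise ValueError("need both within- and between-cluster cell pairs")
    return float(r[iu, ju][same].mean() - r[iu, ju][~same].mean())


def permutation_significance(
    Z: ExpressionMatrix,
    assignment: ClusterAssignment,
    n_permutations: int = 100,
    seed: int = 0,
    metric: str = "centered_pearson",
    linkage: str = "average",
    threshold: float | None = None,
    k: int | None = None,
    gamma: int | None = None,
) -> dict[str, float]:
    """Permutation test of cluster coherence.

    The observed statistic ``T`` is the mean within-cluster minus mean
    between-cluster cell-cell Pearson correlation of ``assignment``.  Each
    permutation independently shuffles every gene's values across cells
    (preserving gene marginals, destroying gene covariance), re-clusters
    with the same settings, and recomputes ``T``.  Reports both a normal
    upper-tail approximation from the null mean/SD (supporting extreme
    significance levels) and the empirical ``(#null >= T + 1)/(B + 1)``.
    """
    if n_permutations < 20:
        raise ValueError("need >= 20 permutations")
    if assignment.k < 2:
        raise ValueError("significance needs k >= 2 clusters")
    rng = np.random.default_rng(seed)
    observed = coherence_statistic(Z, assignment)
    vals = Z.values.to_numpy(dtype=float)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = np.empty_like(vals)
        for i in range(vals.shape[0]):
            perm[i] = vals[i, rng.permutation(vals.shape[1])]
        Eb = ExpressionMatrix(
            pd.DataFrame(perm, index=Z.values.index, columns=Z.values.columns),
            Z.sample_of_cell,
            signed=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Db = cell_distance_matrix(Eb, metric=metric)
            Ab = hierarchical_clusters(
                Db, linkage=linkage, threshold=threshold, k=k, gamma=gamma
            )
        if Ab.k < 2 or Ab.k == len(Z.cell_ids):
            # a fully merged (or fully shattered) null partition carries no
            # within/between contrast; use a balanced random bipartition
            codes = rng.permutation(len(Z.cell_ids)) % 2
            Ab = ClusterAssignment(
                labels=pd.Series(
                    [f"C{c + 1}" for c in codes], index=Db.index, name="cluster"
                )
            )
        null[b] = coherence_statistic(Eb, Ab)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0:
        p_normal = 0.0 if observed > mu else 1.0
    else:
        p_normal = float(stats.norm.sf((observed - mu) / sd))
    p_empirical = float(((null >= observed).sum() + 1) / (n_permutations + 1))
    return {
        "statistic": observed,
        "null_mean": mu,
        "null_sd": sd,
        "p_normal": p_normal,
        "p_empirical": p_empirical,
    }
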
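"""Cell-type enrichment of cluster gene lists and marker-based validation.

Two complementary checks tie clusters to cell types:

* *enrichment*: each cluster's differentially expressed genes are tested
  for over-representation in curated gene/cell-type association sets with
  a one-tailed Fisher's exact test;
* *marker validation*: for an assigned cell type, every known marker
  ranks all cells by expression, the per-marker rankings are aggregated
  into one consensus ordering (robust rank aggregation by default), and
  the ROC AUC of that ordering against the cluster assignment quantifies
  how consistent the assignment is with the markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, GeneSetCollection
from .diffexpr import bh_adjust

__all__ = [
    "EnrichmentResult",
    "celltype_enrichment",
    "aggregate_marker_ranks",
    "marker_validation_auc",
]


@dataclass
class EnrichmentResult:
    """Tidy per (cluster, cell_type) Fisher test results.

    ``table`` columns: cluster, cell_type, overlap, list_size, set_size,
    universe_size, odds_ratio, p, q; sorted by p within each cluster.
    """

    table: pd.DataFrame

    def for_cluster(self, cluster: str) -> pd.DataFrame:
        return self.table[self.table["cluster"] == cluster]


def celltype_enrichment(
    de_genes: dict[str, set[str] | list[str]],
    sets: GeneSetCollection,
    universe: set[str],
) -> EnrichmentResult:
    """Over-representation of cluster gene lists in cell-type gene sets.

    For each (cluster, cell type), the one-tailed Fisher exact p-value of
    the 2x2 table [list&set, list-set, set-list, neither] over ``universe``.
    BH adjustment is applied across cell types within each cluster.
    """
    rows = []
    U = len(universe)
    for cluster, genes in de_genes.items():
        genes = set(genes) & universe
        if not genes:
            raise ValueError(f"empty gene list for cluster {cluster!r}")
        cluster_rows = []
        for ct, members in sets.sets.items():
            members = set(members) & universe
            a = len(genes & members)
            b = len(genes) - a
            c = len(members) - a
            d = U - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            cluster_rows.append(
                (cluster, ct, a, len(genes), len(members), U, odds, p)
            )
        sub = pd.DataFrame(
            cluster_rows,
            columns=[
                "cluster", "cell_type", "overlap", "list_size",
                "set_size", "universe_size", "odds_ratio", "p",
            ],
        )
        sub["q"] = bh_adjust(sub["p"].to_numpy())
        rows.append(sub.sort_values("p", kind="stable"))
    return EnrichmentResult(pd.concat(rows, ignore_index=True))


def aggregate_marker_ranks(
    E: ExpressionMatrix,
    markers: list[str],
    method: str = "rra",
) -> pd.DataFrame:
    """Consensus ranking of cells from multiple marker expressions.

    Each marker ranks all N cells by descending expression (average ranks
    on ties), giving normalized ranks ``r = rank / N``.  The default
    robust-rank-aggregation score of a cell is
    ``rho = min_k P(X >= k)`` with ``X ~ Binomial(m, r_(k))`` over the
    cell's sorted normalized ranks -- small when the cell sits near the
    top of unexpectedly many marker rankings.  ``method="borda"`` uses
    the mean normalized rank instead.  Cells are returned ascending by
    score (best first) with the consensus rank in column ``rank``.
    """
    present = [g for g in markers if g in E.values.index]
    if not present:
        raise ValueError("none of the markers are present in the matrix")
    if len(present) < len(markers):
        import warnings

        absent = sorted(set(markers) - set(present))
        warnings.warn(f"markers absent from matrix: {absent}", stacklevel=2)
    expr = E.values.loc[present]
    N = E.n_cells
    m = len(present)
    # rank cells per marker by descending expression; normalize to (0, 1]
    ranks = expr.rank(axis=1, ascending=False, method="average") / N
    rmat = ranks.to_numpy()
    if method == "rra":
        scores = np.empty(N)
        sorted_r = np.sort(rmat, axis=0)
        for j in range(N):
            tails = stats.binom.sf(
                np.arange(1, m + 1) - 1, m, sorted_r[:, j]
            )
            scores[j] = tails.min()
    elif method == "borda":
        scores = rmat.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    out = pd.DataFrame({"cell_id": E.cell_ids, "score": scores})
    out = out.sort_values(
        ["score", "cell_id"], kind="stable", ignore_index=True
    )
    out["rank"] = np.arange(1, N + 1)
    return out


def marker_validation_auc(
    ranking: pd.DataFrame, assigned: set[str] | list[str]
) -> float:
    """ROC AUC of a consensus cell ranking against a cluster assignment.

    Cells assigned to the cell type are positives, the rest negatives;
    the AUC is computed through the rank-sum identity ``U / (n+ * n-)``
    on the aggregation scores (smaller score = stronger marker support),
    with tied scores contributing 1/2.
    """
    assigned = set(assigned)
    cells = list(ranking["cell_id"])
    is_pos = np.array([c in assigned for c in cells])
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative cells")
    # ranks ascending in score: positives should have *small* scores
    score_ranks = stats.rankdata(ranking["score"].to_numpy(), method="average")
    rank_sum = score_ranks[is_pos].sum()
    u_stat = n_pos * n_neg + n_pos * (n_pos + 1) / 2 - rank_sum
    return float(u_stat / (n_pos * n_neg))
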
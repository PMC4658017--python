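"""Cell-type-specific regulatory network inference and TF importance.

Edges between candidate transcription factors (TFs) and candidate target
genes are established by *first-order conditional dependence*: the TF
``i`` is linked to target ``j`` only if the linear effect of ``i`` on
``j`` stays significant after conditioning on every single other
candidate TF ``k``.  Concretely, for every such ``k`` the model
``X_j = m + a_ij|k X_i + a_kj|i X_k + e`` is fitted by least squares and
the edge significance is ``S_ij = max_k p(a_ij|k = 0)``; the edge is
retained when ``S_ij`` falls below a cutoff.  Taking the *maximum*
p-value over conditionings makes the rule conservative: an edge must
survive its worst-case explanation away.

TF importance in the resulting network combines three classical
centralities (degree DC, closeness CC, betweenness BC) with three
disruption metrics measuring the damage done by deleting the node
(fragmentation DFC, lost pairwise connectivity DCC, lengthened shortest
paths DDC).  Each metric ranks the TFs (competition ranks on ties) and
the final importance is the average of the six ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix
from .diffexpr import DEResult
from .signature import SignatureMetrics

__all__ = [
    "RegulatoryNetwork",
    "NodeImportanceTable",
    "select_candidates",
    "infer_first_order_edges",
    "main_component",
    "node_importance",
    "rank_transcription_factors",
    "metric_diagnostics",
]

METRICS = ["DC", "CC", "BC", "DFC", "DCC", "DDC"]

#: conditioning TFs more collinear than this with the tested TF are skipped
COLLINEARITY_R = 1.0 - 1e-10


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target network with per-edge significance.

    ``edges`` columns: tf, target, S (max conditional p-value), sign (of
    the regression coefficient at the maximizing conditioning).
    """

    tf_nodes: set[str]
    target_nodes: set[str]
    edges: pd.DataFrame

    def graph(self, directed: bool = True) -> nx.Graph:
        G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
        for _, row in self.edges.iterrows():
            G.add_edge(row["tf"], row["target"], S=row["S"], sign=row["sign"])
        return G


@dataclass
class NodeImportanceTable:
    """Per-TF metric values, per-metric ranks, and the average rank."""

    values: pd.DataFrame  # index node, columns METRICS (all nodes)
    ranks: pd.DataFrame | None = None  # TFs only, filled by ranking
    average_rank: pd.Series | None = None


def select_candidates(
    de: DEResult,
    metrics: SignatureMetrics,
    tf_catalog: set[str] | list[str],
    p_tf: float = 0.05,
    p_target: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Candidate TFs and regulatory targets for one cluster.

    TFs are catalog genes either differentially expressed in the cluster
    (p < ``p_tf``) or commonly expressed there (mc = 1).  Targets are all
    genes differentially expressed at the stricter ``p_target``.
    """
    tf_catalog = set(tf_catalog)
    if not tf_catalog:
        raise ValueError("TF catalog is empty")
    p = de.pvalues(metrics.cluster)
    genes = metrics.table.index
    p = p.reindex(genes)
    common = metrics.table["mc"] == 1
    tf_mask = genes.isin(tf_catalog) & ((p.to_numpy() < p_tf) | common.to_numpy())
    tfs = set(genes[tf_mask])
    targets = set(genes[p.to_numpy() < p_target])
    if len(tfs) < 2:
        warnings.warn(
            "fewer than 2 candidate TFs; conditioning degenerates to "
            "marginal regression",
            stacklevel=2,
        )
    return tfs, targets


def _conditional_pvalue(
    xj: np.ndarray, xi: np.ndarray, xk: np.ndarray | None
) -> tuple[float, float]:
    """p-value and sign for the coefficient of ``xi`` in an OLS fit of xj.

    With ``xk`` given, the design is [1, xi, xk]; otherwise the marginal
    design [1, xi].  The p-value is the two-sided t-test of the ``xi``
    coefficient being zero.
    """
    n = len(xj)
    cols = [np.ones(n), xi] if xk is None else [np.ones(n), xi, xk]
    X = np.column_stack(cols)
    k = X.shape[1]
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return 1.0, 0.0
    beta = XtX_inv @ (X.T @ xj)
    resid = xj - X @ beta
    dof = n - k
    if dof <= 0:
        return 1.0, 0.0
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    if se == 0:
        return (0.0, float(np.sign(beta[1]))) if beta[1] != 0 else (1.0, 0.0)
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(p), float(np.sign(beta[1]))


def infer_first_order_edges(
    E: ExpressionMatrix,
    tfs: set[str] | list[str],
    targets: set[str] | list[str],
    cutoff: float = 0.05,
) -> RegulatoryNetwork:
    """First-order conditional-dependence edge inference.

    ``E`` must already be restricted to the cluster's cells.  For every
    TF/target pair, ``S_ij`` is the maximum over conditioning TFs ``k``
    of the p-value for the TF coefficient in
    ``X_j ~ 1 + X_i + X_k``; the edge is kept iff ``S_ij < cutoff``.
    Feedback from targets to TFs and self-loops are excluded; with fewer
    than 3 candidate TFs the marginal regression p-value is used.
    Conditioning TFs nearly collinear with the tested TF are skipped.
    """
    if E.n_cells < 5:
        raise ValueError("need >= 5 cells for edge inference")
    tfs = sorted(set(tfs) & set(E.values.index))
    targets = sorted(set(targets) & set(E.values.index))
    profiles = {
        g: E.values.loc[g].to_numpy(dtype=float)
        for g in set(tfs) | set(targets)
    }
    rows = []
    for i in tfs:
        xi = profiles[i]
        for j in targets:
            if j == i:
                continue
            xj = profiles[j]
            conditioners = [k for k in tfs if k not in (i, j)]
            pvals, signs = [], []
            for k in conditioners:
                xk = profiles[k]
                denom = xi.std() * xk.std()
                if denom > 0:
                    r_ik = abs(float(np.corrcoef(xi, xk)[0, 1]))
                else:
                    r_ik = 1.0
                if r_ik > COLLINEARITY_R:
                    warnings.warn(
                        f"conditioning TF {k!r} collinear with {i!r}; skipped",
                        stacklevel=2,
                    )
                    continue
                p, sign = _conditional_pvalue(xj, xi, xk)
                pvals.append(p)
                signs.append(sign)
            if not pvals:  # < 3 TFs or all conditioners collinear
                p, sign = _conditional_pvalue(xj, xi, None)
                pvals, signs = [p], [sign]
            worst = int(np.argmax(pvals))
            S = pvals[worst]
            if S < cutoff:
                rows.append((i, j, S, signs[worst]))
    edges = pd.DataFrame(rows, columns=["tf", "target", "S", "sign"])
    return RegulatoryNetwork(
        tf_nodes=set(tfs), target_nodes=set(targets), edges=edges
    )


def main_component(H: RegulatoryNetwork) -> nx.Graph:
    """Largest connected component of the undirected view of the network.

    Size ties go to the component containing the lexicographically
    smallest node ID.
    """
    if H.edges.empty:
        raise ValueError("network has no edges")
    G = H.graph(directed=False)
    comps = sorted(
        nx.connected_components(G), key=lambda c: (-len(c), min(c))
    )
    return G.subgraph(comps[0]).copy()


def node_importance(component: nx.Graph) -> NodeImportanceTable:
    """Six importance metrics for every node of a connected graph.

    DC: degree.  CC: reciprocal of the summed shortest-path distances to
    all other nodes.  BC: betweenness over ordered node pairs,
    unnormalized.  DFC: number of connected components after deleting the
    node, over N - 1.  DCC: fraction of ordered pairs of the residual
    graph that can no longer reach each other, after deleting the node.
    DDC: one minus the mean inverse shortest-path distance over ordered
    residual pairs (1/infinity = 0).
    """
    N = component.number_of_nodes()
    if N < 3:
        raise ValueError("need >= 3 nodes")
    if not nx.is_connected(component):
        raise ValueError("graph must be connected (take the main component)")
    nodes = sorted(component.nodes)
    dc = dict(component.degree())
    spl = dict(nx.all_pairs_shortest_path_length(component))
    cc = {i: 1.0 / sum(spl[i][j] for j in nodes if j != i) for i in nodes}
    bc_unordered = nx.betweenness_centrality(component, normalized=False)
    bc = {i: 2.0 * bc_unordered[i] for i in nodes}
    dfc, dcc, ddc = {}, {}, {}
    pair_count = (N - 1) * (N - 2)
    for i in nodes:
        residual = component.subgraph([n for n in nodes if n != i])
        comps = list(nx.connected_components(residual))
        dfc[i] = len(comps) / (N - 1)
        reach = sum(len(c) * (len(c) - 1) for c in comps)
        dcc[i] = 1.0 - reach / pair_count
        inv_sum = 0.0
        for lengths in dict(nx.all_pairs_shortest_path_length(residual)).values():
            inv_sum += sum(1.0 / d for d in lengths.values() if d > 0)
        ddc[i] = 1.0 - inv_sum / pair_count
    values = pd.DataFrame(
        {
            "DC": pd.Series(dc, dtype=float),
            "CC": pd.Series(cc),
            "BC": pd.Series(bc),
            "DFC": pd.Series(dfc),
            "DCC": pd.Series(dcc),
            "DDC": pd.Series(ddc),
        }
    ).loc[nodes]
    return NodeImportanceTable(values=values)


def _competition_ranks(values: np.ndarray) -> np.ndarray:
    """Descending competition ('min') ranks: ties share the best rank."""
    order = stats.rankdata(-values, method="min")
    return order.astype(int)


def rank_transcription_factors(
    table: NodeImportanceTable, tf_nodes: set[str] | list[str]
) -> NodeImportanceTable:
    """Rank TFs per metric and combine by the average rank.

    Each metric ranks the component's TFs in descending value with
    competition ranks (every tied element takes the numerically lowest
    rank of its tie block).  Final importance is the arithmetic mean of
    the six ranks; the final position is again a competition rank on the
    average (tied TFs share a position).
    """
    tfs = sorted(set(tf_nodes) & set(table.values.index))
    if not tfs:
        raise ValueError("no TFs present in the component")
    sub = table.values.loc[tfs]
    ranks = pd.DataFrame(
        {m: _competition_ranks(sub[m].to_numpy()) for m in METRICS},
        index=sub.index,
    )
    avg = ranks.mean(axis=1).rename("average_rank")
    position = pd.Series(
        stats.rankdata(avg.to_numpy(), method="min").astype(int),
        index=avg.index,
        name="position",
    )
    ranks = ranks.assign(average_rank=avg, position=position)
    ranks = ranks.sort_values(
        ["average_rank", "position"], kind="stable"
    )
    return NodeImportanceTable(
        values=table.values, ranks=ranks, average_rank=avg
    )


def metric_diagnostics(table: NodeImportanceTable) -> pd.DataFrame:
    """Per-metric sensitivity and relative power of the combined ranking.

    Sensitivity is the mean tie-block size of the metric's TF ranking
    (1 = all TFs distinguished).  Relative power is the Spearman
    correlation between the metric's ranking and the final average
    ranking, normalized so the six powers average to 1.
    """
    if table.ranks is None or table.average_rank is None:
        raise ValueError("rank the TFs first")
    rows = {}
    powers = {}
    avg = table.average_rank.to_numpy()
    for m in METRICS:
        r = table.ranks[m].to_numpy()
        _, counts = np.unique(r, return_counts=True)
        sensitivity = float(counts.mean())
        with warnings.catch_warnings():
            # a metric with all TFs tied has no defined correlation; its
            # power is reported as 0
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(r, avg).statistic
        powers[m] = float(rho) if np.isfinite(rho) else 0.0
        rows[m] = sensitivity
    mean_power = np.mean(list(powers.values()))
    out = pd.DataFrame(
        {
            "metric": METRICS,
            "sensitivity": [rows[m] for m in METRICS],
            "relative_power": [
                powers[m] / mean_power if mean_power != 0 else np.nan
                for m in METRICS
            ],
        }
    )
    return out
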
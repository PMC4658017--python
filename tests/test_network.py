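from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cytotype.core_io import ExpressionMatrix
from cytotype.network import (
    NodeImportanceTable,
    RegulatoryNetwork,
    infer_first_order_edges,
    main_component,
    metric_diagnostics,
    node_importance,
    rank_transcription_factors,
    select_candidates,
)
from cytotype.simulate import simulate_regulatory_program


# ---------------------------------------------------------------------------
# independent graph oracles (plain BFS / DP, no networkx)

def bfs_distances(adj, src):
    dist = {src: 0}
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def shortest_path_counts(adj, src):
    """#shortest paths from src to every node (BFS DAG dynamic program)."""
    dist = bfs_distances(adj, src)
    sigma = {src: 1}
    order = sorted(dist, key=dist.get)
    for u in order:
        if u == src:
            continue
        sigma[u] = sum(
            sigma[v] for v in adj[u] if dist.get(v, -2) == dist[u] - 1
        )
    return dist, sigma


def oracle_metrics(adj):
    """All six importance metrics by brute force on an adjacency dict."""
    nodes = sorted(adj)
    N = len(nodes)
    dist_all = {u: bfs_distances(adj, u) for u in nodes}
    sigma_all = {u: shortest_path_counts(adj, u)[1] for u in nodes}
    out = {}
    for i in nodes:
        dc = len(adj[i])
        cc = 1.0 / sum(dist_all[i][j] for j in nodes if j != i)
        bc = 0.0
        for j in nodes:
            for k in nodes:
                if i in (j, k) or j == k:
                    continue
                if dist_all[j].get(i, -1) >= 0 and (
                    dist_all[j][i] + dist_all[i][k] == dist_all[j][k]
                ):
                    bc += sigma_all[j][i] * sigma_all[i][k] / sigma_all[j][k]
        residual = {
            u: [v for v in adj[u] if v != i] for u in nodes if u != i
        }
        comps = []
        seen = set()
        for u in residual:
            if u not in seen:
                comp = set(bfs_distances(residual, u))
                comps.append(comp)
                seen |= comp
        dfc = len(comps) / (N - 1)
        reach = sum(len(c) * (len(c) - 1) for c in comps)
        dcc = 1.0 - reach / ((N - 1) * (N - 2))
        inv = 0.0
        for u in residual:
            d = bfs_distances(residual, u)
            inv += sum(1.0 / dd for v, dd in d.items() if v != u)
        ddc = 1.0 - inv / ((N - 1) * (N - 2))
        out[i] = dict(DC=dc, CC=cc, BC=bc, DFC=dfc, DCC=dcc, DDC=ddc)
    return out


def random_connected_graph(rng, max_nodes=12):
    n = int(rng.integers(3, max_nodes + 1))
    G = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
    while not nx.is_connected(G) or G.number_of_nodes() < 3:
        G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})


def adjacency(G):
    return {u: sorted(G.neighbors(u)) for u in G.nodes}


class TestNodeImportance:
    def test_star_hand_values(self):
        G = nx.star_graph(3)
        G = nx.relabel_nodes(G, {0: "c", 1: "l1", 2: "l2", 3: "l3"})
        table = node_importance(G).values
        assert table.loc["c", "DC"] == 3
        assert table.loc["c", "DFC"] == pytest.approx(1.0)
        assert table.loc["l1", "DFC"] == pytest.approx(1 / 3)
        assert table.loc["c", "DCC"] == pytest.approx(1.0)

    def test_path_hand_values(self):
        G = nx.path_graph(3)
        G = nx.relabel_nodes(G, {0: "a", 1: "b", 2: "c"})
        table = node_importance(G).values
        assert table.loc["b", "CC"] == pytest.approx(0.5)
        assert table.loc["b", "DDC"] == pytest.approx(1.0)
        assert table.loc["b", "DCC"] == pytest.approx(1.0)

    def test_triangle_hand_values(self):
        G = nx.complete_graph(3)
        table = node_importance(G).values
        for i in G.nodes:
            assert table.loc[i, "DFC"] == pytest.approx(0.5)
            assert table.loc[i, "DCC"] == pytest.approx(0.0)
            assert table.loc[i, "DDC"] == pytest.approx(0.0)

    @pytest.mark.parametrize("batch", range(4))
    def test_matches_bruteforce_on_random_graphs(self, batch):
        rng = np.random.default_rng(100 + batch)
        for _ in range(50):
            G = random_connected_graph(rng)
            table = node_importance(G).values
            oracle = oracle_metrics(adjacency(G))
            for node, metrics in oracle.items():
                for m, v in metrics.items():
                    assert table.loc[node, m] == pytest.approx(v, abs=1e-9), (
                        f"{m} mismatch at {node}"
                    )

    def test_disruption_metrics_bounded_and_cut_vertices_dominate(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            G = random_connected_graph(rng)
            table = node_importance(G).values
            for m in ("DFC", "DCC", "DDC"):
                assert ((table[m] >= -1e-12) & (table[m] <= 1 + 1e-12)).all()
            cuts = set(nx.articulation_points(G))
            non_cuts = set(G.nodes) - cuts
            if cuts and non_cuts:
                assert (
                    table.loc[sorted(cuts), "DFC"].min()
                    > table.loc[sorted(non_cuts), "DFC"].max()
                )

    def test_disconnected_input_rejected(self):
        G = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError):
            node_importance(G)


class TestMainComponent:
    def test_connected_graph_is_identity(self):
        H = RegulatoryNetwork(
            {"t1"}, {"g1", "g2"},
            pd.DataFrame(
                [("t1", "g1", 0.01, 1.0), ("t1", "g2", 0.01, 1.0)],
                columns=["tf", "target", "S", "sign"],
            ),
        )
        comp = main_component(H)
        assert set(comp.nodes) == {"t1", "g1", "g2"}

    def test_larger_component_wins(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
                 ("x", "y"), ("y", "z")]
        H = RegulatoryNetwork(
            {e[0] for e in edges}, {e[1] for e in edges},
            pd.DataFrame(
                [(u, v, 0.01, 1.0) for u, v in edges],
                columns=["tf", "target", "S", "sign"],
            ),
        )
        assert set(main_component(H).nodes) == {"a", "b", "c", "d", "e"}

    def test_size_tie_goes_to_smallest_node_id(self):
        edges = [("b", "c"), ("a", "d")]
        H = RegulatoryNetwork(
            {"a", "b"}, {"c", "d"},
            pd.DataFrame(
                [(u, v, 0.01, 1.0) for u, v in edges],
                columns=["tf", "target", "S", "sign"],
            ),
        )
        assert set(main_component(H).nodes) == {"a", "d"}


class TestRanking:
    def importance_from(self, values):
        idx = [f"t{i}" for i in range(len(values))]
        df = pd.DataFrame(
            {m: [v[j] for v in values] for j, m in enumerate(
                ["DC", "CC", "BC", "DFC", "DCC", "DDC"]
            )},
            index=idx,
        )
        return NodeImportanceTable(values=df)

    def test_competition_ranks_share_lowest(self):
        table = self.importance_from(
            [(5, 1, 1, 1, 1, 1), (5, 1, 1, 1, 1, 1), (3, 1, 1, 1, 1, 1)]
        )
        ranked = rank_transcription_factors(table, {"t0", "t1", "t2"})
        assert list(ranked.ranks["DC"].loc[["t0", "t1", "t2"]]) == [1, 1, 3]

    def test_unanimous_winner(self):
        table = self.importance_from(
            [(9, 9, 9, 9, 9, 9), (1, 1, 1, 1, 1, 1), (2, 2, 2, 2, 2, 2)]
        )
        ranked = rank_transcription_factors(table, {"t0", "t1", "t2"})
        assert ranked.average_rank.loc["t0"] == 1.0
        assert ranked.ranks["position"].loc["t0"] == 1

    def test_tied_average_ranks_share_position(self):
        table = self.importance_from(
            [(3, 1, 1, 1, 1, 1), (1, 3, 1, 1, 1, 1), (9, 9, 9, 9, 9, 9)]
        )
        ranked = rank_transcription_factors(table, {"t0", "t1", "t2"})
        pos = ranked.ranks["position"]
        assert pos.loc["t0"] == pos.loc["t1"]


class TestDiagnostics:
    def build_ranked(self, metric_values):
        idx = [f"t{i}" for i in range(len(next(iter(metric_values.values()))))]
        df = pd.DataFrame(metric_values, index=idx)
        table = NodeImportanceTable(values=df)
        return rank_transcription_factors(table, set(idx))

    def test_sensitivity_extremes(self):
        n = 5
        vals = {
            "DC": list(range(n)),       # all distinct -> sensitivity 1
            "CC": [1.0] * n,            # all tied -> sensitivity n
            "BC": list(range(n)),
            "DFC": list(range(n)),
            "DCC": list(range(n)),
            "DDC": list(range(n)),
        }
        ranked = self.build_ranked(vals)
        diag = metric_diagnostics(ranked).set_index("metric")
        assert diag.loc["DC", "sensitivity"] == 1.0
        assert diag.loc["CC", "sensitivity"] == n

    def test_aligned_metric_has_maximal_relative_power(self):
        rng = np.random.default_rng(3)
        n = 8
        aligned = list(range(n, 0, -1))
        vals = {"DC": aligned, "CC": aligned, "BC": aligned,
                "DFC": list(rng.permutation(n)),
                "DCC": list(rng.permutation(n)),
                "DDC": list(rng.permutation(n))}
        ranked = self.build_ranked(vals)
        diag = metric_diagnostics(ranked).set_index("metric")
        assert diag["relative_power"].mean() == pytest.approx(1.0)
        assert diag.loc["DC", "relative_power"] == diag["relative_power"].max()


class TestEdgeInference:
    def make_expr(self, table):
        return ExpressionMatrix(
            table, pd.Series("s1", index=table.columns), signed=True
        )

    def test_planted_linear_edge_recovered(self):
        rng = np.random.default_rng(0)
        n = 40
        xi = rng.normal(size=n)
        decoys = {f"d{t}": rng.normal(size=n) for t in range(5)}
        xj = 2.0 * xi + rng.normal(0, 0.2 * xi.std(), size=n)
        table = pd.DataFrame({"tf": xi, "tg": xj, **decoys}).T
        table.columns = [f"c{j}" for j in range(n)]
        E = self.make_expr(table)
        H = infer_first_order_edges(
            E, {"tf", *decoys}, {"tg"}, cutoff=0.05
        )
        found = set(zip(H.edges["tf"], H.edges["target"]))
        assert ("tf", "tg") in found

    def test_null_retention_conservative(self):
        rng = np.random.default_rng(1)
        kept = 0
        total = 0
        for _ in range(50):
            n = 30
            table = pd.DataFrame(
                {g: rng.normal(size=n) for g in
                 [f"t{i}" for i in range(5)] + ["g1", "g2"]}
            ).T
            table.columns = [f"c{j}" for j in range(n)]
            E = self.make_expr(table)
            H = infer_first_order_edges(
                E, {f"t{i}" for i in range(5)}, {"g1", "g2"}, cutoff=0.05
            )
            kept += len(H.edges)
            total += 10
        assert kept / total <= 0.05

    def test_coefficients_match_normal_equations(self):
        # 6-point hand dataset: compare against the closed-form solution
        xi = np.array([1.0, 2, 3, 4, 5, 6])
        xk = np.array([2.0, 1, 4, 3, 6, 5])
        xj = np.array([1.5, 3.2, 4.1, 6.3, 7.0, 9.1])
        X = np.column_stack([np.ones(6), xi, xk])
        beta = np.linalg.solve(X.T @ X, X.T @ xj)
        resid = xj - X @ beta
        s2 = resid @ resid / 3
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        from scipy import stats as ss

        p_hand = 2 * ss.t.sf(abs(beta[1] / se), 3)

        from cytotype.network import _conditional_pvalue

        p, sign = _conditional_pvalue(xj, xi, xk)
        assert p == pytest.approx(p_hand, abs=1e-12)
        assert sign == np.sign(beta[1])

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        xi, xk = rng.normal(size=25), rng.normal(size=25)
        xj = 0.6 * xi - 0.2 * xk + rng.normal(size=25)
        from cytotype.network import _conditional_pvalue

        p, _ = _conditional_pvalue(xj, xi, xk)
        fit = sm.OLS(xj, sm.add_constant(np.column_stack([xi, xk]))).fit()
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_collinear_conditioner_skipped(self):
        rng = np.random.default_rng(2)
        n = 30
        xi = rng.normal(size=n)
        table = pd.DataFrame(
            {"t0": xi, "t1": xi.copy(), "t2": rng.normal(size=n),
             "g": 1.5 * xi + rng.normal(0, 0.3, size=n)}
        ).T
        table.columns = [f"c{j}" for j in range(n)]
        E = self.make_expr(table)
        with pytest.warns(UserWarning, match="collinear"):
            H = infer_first_order_edges(
                E, {"t0", "t1", "t2"}, {"g"}, cutoff=0.05
            )
        assert len(H.edges) >= 1

    def test_planted_program_recovery(self):
        recalls, precisions = [], []
        for seed in range(10):
            table, tfs, targets, true_edges = simulate_regulatory_program(
                seed=seed
            )
            E = self.make_expr(table)
            H = infer_first_order_edges(E, tfs, targets, cutoff=0.05)
            found = set(zip(H.edges["tf"], H.edges["target"]))
            tset = set(true_edges)
            recalls.append(len(found & tset) / len(tset))
            precisions.append(len(found & tset) / max(len(found), 1))
        assert np.mean(recalls) >= 0.9
        assert np.mean(precisions) >= 0.8


class TestSelectCandidates:
    def test_catalog_gate_and_thresholds(
        self, planted, planted_clustering, planted_de, cluster_truth_map
    ):
        from cytotype.signature import compute_signature_metrics

        A = planted_clustering["assignment"]
        cl = A.cluster_names[0]
        truth = cluster_truth_map[cl]
        metrics = compute_signature_metrics(
            planted.expression, A, cl, planted_de
        )
        catalog = set(planted.signature_genes[truth][:5]) | {"hk_000"}
        tfs, targets = select_candidates(
            planted_de, metrics, catalog, p_tf=0.05, p_target=0.01
        )
        # catalog signature genes are DE in their own cluster -> TFs
        assert set(planted.signature_genes[truth][:5]) <= tfs
        # housekeeping gene is commonly expressed (mc=1) -> TF despite p
        assert "hk_000" in tfs
        # non-catalog DE genes are targets only
        assert set(planted.signature_genes[truth]) <= targets
        assert not (targets - set(planted.expression.gene_ids))

    def test_empty_catalog_rejected(self, planted_de):
        with pytest.raises(ValueError):
            select_candidates(planted_de, None, set())
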
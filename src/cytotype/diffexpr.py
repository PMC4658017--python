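"""Per-cluster one-tailed differential expression with FDR control.

For every cluster, each gene is tested for *higher* expression in the
cluster's cells than in all remaining cells.  When both groups have more
than ``min_parametric_n`` cells a one-tailed Welch unequal-variance t-test
is used; otherwise a one-tailed Wilcoxon rank-sum test (exact for small
tie-free samples, normal approximation with tie correction otherwise).
Benjamini-Hochberg adjustment is applied within each cluster's battery of
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterAssignment
from .core_io import ExpressionMatrix

__all__ = [
    "DEResult",
    "two_group_test",
    "cluster_differential_expression",
    "bh_adjust",
    "P_FLOOR",
]

#: p-values are floored here before any -log transform downstream.
P_FLOOR = 1e-300

#: exact rank-sum enumeration is used up to this combined sample size
EXACT_WILCOXON_MAX_N = 20


@dataclass
class DEResult:
    """Tidy per (gene, cluster) test results.

    ``table`` columns: gene, cluster, test, statistic, p, q, n_in, n_out.
    """

    table: pd.DataFrame

    def for_cluster(self, cluster: str) -> pd.DataFrame:
        return self.table[self.table["cluster"] == cluster]

    def pvalues(self, cluster: str) -> pd.Series:
        sub = self.for_cluster(cluster)
        return pd.Series(sub["p"].to_numpy(), index=sub["gene"].to_numpy())

    def genes_below(self, cluster: str, alpha: float, column: str = "q") -> list[str]:
        sub = self.for_cluster(cluster)
        return list(sub.loc[sub[column] < alpha, "gene"])


def two_group_test(
    x: np.ndarray, y: np.ndarray, test: str = "welch_t"
) -> tuple[float, float, bool]:
    """One-tailed two-group test (alternative: mean/location of x greater).

    Returns ``(statistic, p, degenerate)``; ``degenerate`` marks the case
    of zero variance in both groups with equal values, reported as
    p = 0.5 (no evidence either way).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if test == "welch_t":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("welch_t needs >= 2 values per group")
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            if x.mean() == y.mean():
                return 0.0, 0.5, True
            return (np.inf if x.mean() > y.mean() else -np.inf,
                    0.0 if x.mean() > y.mean() else 1.0, True)
        stat, p = stats.ttest_ind(
            x, y, equal_var=False, alternative="greater"
        )
        return float(stat), float(max(p, P_FLOOR)), False
    if test == "wilcoxon":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("wilcoxon needs >= 1 value per group")
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            return 0.0, 0.5, True
        exact = (
            len(pooled) <= EXACT_WILCOXON_MAX_N
            and len(np.unique(pooled)) == len(pooled)
        )
        res = stats.mannwhitneyu(
            x, y, alternative="greater",
            method="exact" if exact else "asymptotic",
        )
        return float(res.statistic), float(max(res.pvalue, P_FLOOR)), False
    raise ValueError(f"unknown test {test!r}")


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def cluster_differential_expression(
    E: ExpressionMatrix,
    assignment: ClusterAssignment,
    min_parametric_n: int = 5,
) -> DEResult:
    """One-vs-rest DE test for every (gene, cluster) pair.

    Welch's t-test is chosen when both the cluster and its complement
    have more than ``min_parametric_n`` cells, otherwise the Wilcoxon
    rank-sum test.  BH adjustment is applied per cluster.
    """
    if assignment.k < 2:
        raise ValueError("differential expression needs >= 2 clusters")
    vals = E.values
    cells = vals.columns
    labels = assignment.labels.reindex(cells)
    rows = []
    for cluster in assignment.cluster_names:
        inside = labels == cluster
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        use_welch = (
            n_in > max(min_parametric_n, 1) and n_out > max(min_parametric_n, 1)
        )
        test = "welch_t" if use_welch else "wilcoxon"
        xin = vals.loc[:, inside.to_numpy()].to_numpy(dtype=float)
        xout = vals.loc[:, (~inside).to_numpy()].to_numpy(dtype=float)
        pvals, statv = np.empty(vals.shape[0]), np.empty(vals.shape[0])
        for i in range(vals.shape[0]):
            statv[i], pvals[i], _ = two_group_test(xin[i], xout[i], test)
        qvals = bh_adjust(pvals)
        for g, s, p, q in zip(vals.index, statv, pvals, qvals):
            rows.append((g, cluster, test, s, p, q, n_in, n_out))
    table = pd.DataFrame(
        rows,
        columns=["gene", "cluster", "test", "statistic", "p", "q", "n_in", "n_out"],
    )
    return DEResult(table=table)
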
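"""Cell-type-specific signature gene ranking.

Four per-gene features quantify how specific a gene is to a cell
cluster:

* ``mc`` (common): 1 when the gene is expressed (at or above an
  abundance threshold) in at least ``delta`` percent of the cluster's
  cells;
* ``mu`` (unique): 1 when the gene's mean expression in the cluster is
  at least ``alpha`` times the ``eta``-quantile of its expression over
  all other cells (the quantile tolerates a few outlier cells outside
  the cluster);
* ``mt`` (test statistic): the cluster's differential-expression
  p-value, -log transformed and scaled by the cluster maximum into
  [0, 1];
* ``ms`` (profile similarity): Pearson correlation between the gene's
  full-cohort profile and an idealized reference profile for the
  cluster (1 inside, 0 outside), mapped to [0, 1] by ``(1 + rho)/2``.

A logistic regression trained on known markers (positives) against
non-DE, non-common, non-unique genes (negatives) combines the four
features into a signature probability used to rank candidate genes.
Repeated random subsampling validates the predicted signatures by the
accuracy of linear classifiers separating cluster pairs on the
signature genes alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC

from .clustering import ClusterAssignment
from .core_io import ExpressionMatrix
from .diffexpr import DEResult, P_FLOOR

__all__ = [
    "SignatureMetrics",
    "LogisticModel",
    "common_gene_metric",
    "unique_gene_metric",
    "test_statistic_metric",
    "synthetic_profile_similarity",
    "compute_signature_metrics",
    "build_training_set",
    "fit_signature_model",
    "subsampling_validation",
]

FEATURES = ["mc", "mu", "mt", "ms"]


@dataclass
class SignatureMetrics:
    """Per-gene feature table (columns mc, mu, mt, ms) for one cluster."""

    cluster: str
    table: pd.DataFrame  # index gene, columns mc/mu/mt/ms


@dataclass
class LogisticModel:
    """Fitted signature model: intercept and one coefficient per feature."""

    intercept: float
    coef: dict[str, float]
    n_positive: int
    n_negative: int
    seed: int | None = None

    def predict_proba(self, metrics: pd.DataFrame) -> pd.Series:
        """Signature probability for each gene row of a feature table."""
        eta = self.intercept + sum(
            self.coef[f] * metrics[f].to_numpy(dtype=float) for f in FEATURES
        )
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=metrics.index)


def common_gene_metric(
    E: ExpressionMatrix,
    cluster_cells: list[str],
    delta: float = 80.0,
    theta_expr: float = 5.0,
) -> pd.Series:
    """Binary: expressed (>= theta_expr) in >= delta percent of cluster cells."""
    if not 0 < delta <= 100:
        raise ValueError("delta must be in (0, 100]")
    if not cluster_cells:
        raise ValueError("empty cluster")
    need = int(np.ceil(delta / 100.0 * len(cluster_cells)))
    counts = (E.values[cluster_cells] >= theta_expr).sum(axis=1)
    return (counts >= need).astype(int).rename("mc")


def unique_gene_metric(
    E: ExpressionMatrix,
    cluster_cells: list[str],
    alpha: float = 2.0,
    eta: float = 0.85,
) -> pd.Series:
    """Binary: cluster mean >= alpha x (eta-quantile outside the cluster)."""
    if alpha <= 0 or not 0 < eta < 1:
        raise ValueError("need alpha > 0 and 0 < eta < 1")
    outside = [c for c in E.cell_ids if c not in set(cluster_cells)]
    if not outside:
        raise ValueError("no cells outside the cluster")
    inside_mean = E.values[cluster_cells].mean(axis=1)
    out_q = E.values[outside].quantile(eta, axis=1, interpolation="linear")
    return (inside_mean >= alpha * out_q).astype(int).rename("mu")


def test_statistic_metric(p: pd.Series) -> pd.Series:
    """Normalized -log p: the cluster's most significant gene scores 1."""
    logp = -np.log(np.clip(p.to_numpy(dtype=float), P_FLOOR, 1.0))
    top = logp.max()
    if top == 0:
        return pd.Series(0.0, index=p.index, name="mt")
    return pd.Series(logp / top, index=p.index, name="mt")


def synthetic_profile_similarity(
    E: ExpressionMatrix, cluster_cells: list[str]
) -> pd.Series:
    """Correlation with the cluster's idealized reference profile.

    The reference is the cluster indicator over all cells (1 inside,
    0 outside); ``ms = (1 + rho)/2`` with Pearson ``rho``; genes constant
    across the cohort get ``ms = 0.5`` (no information).
    """
    inside = set(cluster_cells)
    if len(inside) < 2 or E.n_cells - len(inside) < 2:
        raise ValueError("need >= 2 cells inside and outside the cluster")
    ref = np.array([1.0 if c in inside else 0.0 for c in E.cell_ids])
    vals = E.values.to_numpy(dtype=float)
    vc = vals - vals.mean(axis=1, keepdims=True)
    rc = ref - ref.mean()
    denom = np.sqrt((vc**2).sum(axis=1)) * np.sqrt((rc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (vc @ rc) / denom
    rho[~np.isfinite(rho)] = 0.0
    return pd.Series((1.0 + rho) / 2.0, index=E.values.index, name="ms")


def compute_signature_metrics(
    E: ExpressionMatrix,
    assignment: ClusterAssignment,
    cluster: str,
    de: DEResult,
    delta: float = 80.0,
    theta_expr: float = 5.0,
    alpha: float = 2.0,
    eta: float = 0.85,
) -> SignatureMetrics:
    """All four features for every gene, for one cluster."""
    cells = assignment.cells_in(cluster)
    p = de.pvalues(cluster).reindex(E.values.index)
    table = pd.concat(
        [
            common_gene_metric(E, cells, delta, theta_expr),
            unique_gene_metric(E, cells, alpha, eta),
            test_statistic_metric(p),
            synthetic_profile_similarity(E, cells),
        ],
        axis=1,
    )
    return SignatureMetrics(cluster=cluster, table=table)


def build_training_set(
    metrics: SignatureMetrics,
    de: DEResult,
    known_markers: list[str],
    p_non_de_min: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Class-balanced labelled genes for fitting the signature model.

    Positives are the known markers present in the feature table.
    The negative pool holds genes that are non-differentially expressed
    (p >= ``p_non_de_min``) and neither common nor unique (mc = mu = 0);
    negatives are sampled from it without replacement to match the
    number of positives (reproducibly, given ``seed``).
    """
    table = metrics.table
    positives = [g for g in known_markers if g in table.index]
    if len(positives) < 3:
        raise ValueError("need >= 3 known markers present in the matrix")
    p = de.pvalues(metrics.cluster).reindex(table.index)
    pool = table.index[
        (p.to_numpy() >= p_non_de_min)
        & (table["mc"] == 0)
        & (table["mu"] == 0)
        & (~table.index.isin(positives))
    ]
    rng = np.random.default_rng(seed)
    if len(pool) < len(positives):
        import warnings

        warnings.warn(
            "negative pool smaller than positives; using the whole pool",
            stacklevel=2,
        )
        negatives = list(pool)
    else:
        negatives = list(rng.choice(pool, size=len(positives), replace=False))
    labels = pd.Series(
        [1] * len(positives) + [0] * len(negatives),
        index=positives + negatives,
        name="label",
    )
    return labels


def fit_signature_model(
    training: pd.Series,
    metrics: SignatureMetrics,
    ridge: float = 1e-4,
) -> tuple[LogisticModel, pd.DataFrame]:
    """Fit the logistic model and score every gene of the feature table.

    A small ridge penalty keeps the maximum-likelihood fit finite when the
    marker-based training set is linearly separable (common).  Returns the
    model and a table ranked descending by signature probability with a
    min-max normalized score column.
    """
    if training.nunique() < 2:
        raise ValueError("training set needs both classes")
    X = metrics.table.loc[training.index, FEATURES].to_numpy(dtype=float)
    y = training.to_numpy(dtype=int)
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=5000)
    clf.fit(X, y)
    if clf.n_iter_[0] >= 5000:
        raise RuntimeError("logistic fit did not converge")
    model = LogisticModel(
        intercept=float(clf.intercept_[0]),
        coef=dict(zip(FEATURES, (float(c) for c in clf.coef_[0]))),
        n_positive=int(y.sum()),
        n_negative=int(len(y) - y.sum()),
    )
    theta = model.predict_proba(metrics.table)
    lo, hi = theta.min(), theta.max()
    norm = (theta - lo) / (hi - lo) if hi > lo else theta * 0.0
    scored = pd.DataFrame(
        {
            "cluster": metrics.cluster,
            **{f: metrics.table[f] for f in FEATURES},
            "score": theta,
            "normalized_score": norm,
        }
    )
    scored = scored.sort_values(
        ["score"], ascending=False, kind="stable"
    )
    return model, scored


def predict_signature(
    E: ExpressionMatrix,
    assignment: ClusterAssignment,
    cluster: str,
    de: DEResult,
    known_markers: list[str],
    top_n: int | None = None,
    candidate_alpha: float = 0.05,
    seed: int = 0,
    **metric_kwargs,
) -> pd.DataFrame:
    """End-to-end signature ranking for one cluster.

    Candidates are the cluster's differentially expressed genes
    (p < ``candidate_alpha``); the returned table is the scored ranking
    restricted to candidates, optionally truncated to ``top_n``.
    """
    metrics = compute_signature_metrics(
        E, assignment, cluster, de, **metric_kwargs
    )
    training = build_training_set(metrics, de, known_markers, seed=seed)
    _, scored = fit_signature_model(training, metrics)
    p = de.pvalues(cluster).reindex(scored.index)
    scored = scored[p.to_numpy() < candidate_alpha]
    if top_n is not None:
        scored = scored.head(top_n)
    return scored


def subsampling_validation(
    E: ExpressionMatrix,
    assignment: ClusterAssignment,
    cluster: str,
    de: DEResult,
    known_markers: list[str],
    repetitions: int = 100,
    frac: float = 0.8,
    top_n: int = 100,
    seed: int = 0,
    min_parametric_n: int = 5,
) -> pd.DataFrame:
    """Repeated random subsampling validation of the signature prediction.

    Per repetition: sample ``frac`` of the cluster's cells, re-run the
    signature prediction on the subsample, take the ``top_n`` signature
    genes, then for every other cluster train a linear support-vector
    classifier on ``frac`` of both clusters' cells restricted to those
    genes and record its accuracy on the held-out cells.  Returns the
    per-pair mean accuracy and standard error over repetitions.
    """
    from .diffexpr import cluster_differential_expression

    if repetitions < 2:
        raise ValueError("need >= 2 repetitions")
    rng = np.random.default_rng(seed)
    own_cells = assignment.cells_in(cluster)
    others = [c for c in assignment.cluster_names if c != cluster]
    n_keep = int(round(frac * len(own_cells)))
    if n_keep < 2 or n_keep >= len(own_cells):
        raise ValueError("cluster too small to subsample and hold out cells")
    acc: dict[str, list[float]] = {c: [] for c in others}
    for _ in range(repetitions):
        sub_own = list(rng.choice(own_cells, size=n_keep, replace=False))
        keep_cells = sub_own + [
            c for c in E.cell_ids if c not in set(own_cells)
        ]
        E_sub = E.subset_cells(keep_cells)
        A_sub = ClusterAssignment(labels=assignment.labels.loc[keep_cells])
        de_sub = cluster_differential_expression(
            E_sub, A_sub, min_parametric_n=min_parametric_n
        )
        sig = predict_signature(
            E_sub, A_sub, cluster, de_sub, known_markers,
            top_n=top_n, seed=int(rng.integers(2**31)),
        )
        genes = list(sig.index)
        if not genes:
            # no differentially expressed candidates: the signature carries
            # no information, score every pairwise classifier at chance
            for other in others:
                acc[other].append(0.5)
            continue
        for other in others:
            other_cells = assignment.cells_in(other)
            n_other = int(round(frac * len(other_cells)))
            n_other = min(max(n_other, 1), len(other_cells) - 1)
            sub_other = list(
                rng.choice(other_cells, size=n_other, replace=False)
            )
            train_cells = sub_own + sub_other
            test_cells = [
                c for c in own_cells + other_cells
                if c not in set(train_cells)
            ]
            Xtr = E.values.loc[genes, train_cells].to_numpy(dtype=float).T
            Xte = E.values.loc[genes, test_cells].to_numpy(dtype=float).T
            ytr = np.array([1 if c in set(own_cells) else 0 for c in train_cells])
            yte = np.array([1 if c in set(own_cells) else 0 for c in test_cells])
            clf = LinearSVC(dual="auto")
            clf.fit(np.log2(np.maximum(Xtr, 1e-3) + 1), ytr)
            pred = clf.predict(np.log2(np.maximum(Xte, 1e-3) + 1))
            acc[other].append(float((pred == yte).mean()))
    rows = [
        (
            cluster,
            other,
            float(np.mean(acc[other])),
            float(np.std(acc[other], ddof=1) / np.sqrt(repetitions)),
        )
        for other in others
    ]
    return pd.DataFrame(
        rows, columns=["cluster", "versus", "mean_accuracy", "standard_error"]
    )
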
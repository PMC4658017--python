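"""Gene pre-filtering, normalization, and quality-control summaries.

Pre-filtering combines two per-sample criteria:

* an *expression filter* keeping gene ``i`` in sample ``s`` when at least
  ``N`` cells of that sample express it at or above an abundance threshold
  ``theta``;
* a *cell specificity filter* based on a specificity index ``tau`` in
  [0, 1] (1 = the gene's expression is concentrated in a single cell of
  the sample, 0 = perfectly uniform), adapted from the classic tissue
  specificity index.  For gene ``i`` with within-sample min-max scaled
  expression ``x_ij``, ``tau_i = sum_j (1 - x_ij) / (q - 1)`` over the
  sample's ``q`` cells.

Genes passing both filters in *every* sample (Section 1) are retained;
the report labels the remaining genes Sections 2-4 by which filter failed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "PrefilterReport",
    "expression_filter",
    "specificity_index",
    "prefilter",
    "zscore_normalize",
    "trimmed_mean_normalize",
    "qc_summary",
]


@dataclass
class PrefilterReport:
    """Per-gene filter diagnostics.

    Attributes
    ----------
    expression_count
        genes x samples integer table of cells at/above the abundance
        threshold per sample.
    expression_pass
        genes x samples boolean table for the expression filter.
    specificity
        genes x samples table of the specificity index tau.
    section
        Per-gene label 1-4: 1 = passed both filters in every sample
        (kept); 2 = passed the expression filter everywhere but failed
        specificity somewhere; 3 = failed the expression filter in every
        sample; 4 = passed the expression filter in some but not all
        samples.
    kept
        Per-gene boolean; equivalent to ``section == 1``.
    """

    expression_count: pd.DataFrame
    expression_pass: pd.DataFrame
    specificity: pd.DataFrame
    section: pd.Series
    kept: pd.Series


def expression_filter(
    E: ExpressionMatrix, theta: float = 5.0, min_cells: int = 2
) -> pd.DataFrame:
    """Per-gene per-sample pass flags for the abundance filter.

    Gene ``i`` passes in sample ``s`` iff at least ``min_cells`` cells of
    ``s`` have abundance >= ``theta``.  Set ``min_cells=1`` to retain genes
    expressed in single, potentially rare, cells.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    counts = expression_counts(E, theta)
    sizes = E.sample_of_cell.value_counts()
    if min_cells > sizes.max():
        import warnings

        warnings.warn(
            "min_cells exceeds the largest sample size; no gene can pass",
            stacklevel=2,
        )
    return counts >= min_cells


def expression_counts(E: ExpressionMatrix, theta: float) -> pd.DataFrame:
    """genes x samples table counting cells with abundance >= theta."""
    cols = {}
    for s in E.samples:
        sub = E.values[E.cells_in_sample(s)]
        cols[s] = (sub >= theta).sum(axis=1)
    return pd.DataFrame(cols)


def specificity_index(E: ExpressionMatrix, sample: str) -> pd.Series:
    """Cell specificity index tau for every gene within one sample.

    ``tau = sum_j (1 - x_ij) / (q - 1)`` with ``x_ij`` the min-max scaled
    expression of gene ``i`` across the sample's ``q`` cells.  A gene
    expressed in exactly one cell scores 1; a constant gene scores 0 by
    convention (the scaling is 0/0 there, and a flat gene is maximally
    unspecific).
    """
    cells = E.cells_in_sample(sample)
    q = len(cells)
    if q < 2:
        raise ValueError(f"sample {sample!r} needs >= 2 cells for tau")
    vals = E.values[cells].to_numpy(dtype=float)
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] == 0
    span[constant] = 1.0  # avoid 0/0; overridden below
    x = (vals - lo) / span
    tau = (1.0 - x).sum(axis=1) / (q - 1)
    tau[constant] = 0.0
    return pd.Series(tau, index=E.values.index, name=f"tau_{sample}")


def prefilter(
    E: ExpressionMatrix,
    theta: float = 5.0,
    min_cells: int = 2,
    tau_min: float = 0.7,
) -> tuple[ExpressionMatrix, PrefilterReport]:
    """Apply the expression and specificity filters in every sample.

    Returns the matrix restricted to genes passing both filters in all
    samples, together with a :class:`PrefilterReport` labelling every gene
    with its section (1 kept, 2 unspecific, 3 unexpressed, 4 expressed in
    only part of the samples).
    """
    if not 0 <= tau_min <= 1:
        raise ValueError("tau_min must be in [0, 1]")
    counts = expression_counts(E, theta)
    epass = counts >= min_cells
    tau = pd.DataFrame(
        {s: specificity_index(E, s) for s in E.samples}
    )
    tpass = tau >= tau_min

    expr_all = epass.all(axis=1)
    expr_any = epass.any(axis=1)
    spec_all = tpass.all(axis=1)

    section = pd.Series(0, index=E.values.index, dtype=int)
    section[expr_all & spec_all] = 1
    section[expr_all & ~spec_all] = 2
    section[~expr_any] = 3
    section[expr_any & ~expr_all] = 4
    kept = section == 1

    report = PrefilterReport(
        expression_count=counts,
        expression_pass=epass,
        specificity=tau,
        section=section,
        kept=kept,
    )
    return E.subset_genes(E.values.index[kept]), report


def zscore_normalize(
    E: ExpressionMatrix, log2_transform: bool = False
) -> ExpressionMatrix:
    """Per-sample, per-gene z-score transform.

    Within each sample, every gene row is centred to its sample mean and
    scaled by its sample standard deviation; genes constant within a
    sample map to 0 there.  Optionally applies log2(x + 1) first.
    Idempotent (up to the log flag).
    """
    vals = E.values.to_numpy(dtype=float).copy()
    if log2_transform:
        vals = np.log2(vals + 1.0)
    out = np.empty_like(vals)
    col_index = {c: i for i, c in enumerate(E.values.columns)}
    for s in E.samples:
        idx = [col_index[c] for c in E.cells_in_sample(s)]
        block = vals[:, idx]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (block - mu) / sd
        z[(block.std(axis=1, ddof=0) == 0), :] = 0.0
        out[:, idx] = z
    zed = pd.DataFrame(out, index=E.values.index, columns=E.values.columns)
    return ExpressionMatrix(zed, E.sample_of_cell, signed=True)


def _trimmed_mean(col: np.ndarray, trim: float) -> float:
    from scipy import stats

    return float(stats.trim_mean(col, trim)) if trim > 0 else float(col.mean())


def trimmed_mean_normalize(
    E: ExpressionMatrix, trim: float = 0.05
) -> ExpressionMatrix:
    """Cell-level scaling equalizing the per-cell trimmed mean.

    Every cell's values are multiplied by (grand mean of all cells'
    trimmed means) / (that cell's trimmed mean), so the per-cell trimmed
    mean becomes the common grand target.  ``trim`` is the fraction
    removed from each tail (0 gives plain mean scaling).
    """
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    vals = E.values.to_numpy(dtype=float)
    tm = np.array([_trimmed_mean(vals[:, j], trim) for j in range(vals.shape[1])])
    if (tm == 0).any():
        bad = [E.cell_ids[j] for j in np.flatnonzero(tm == 0)]
        raise ValueError(f"cells with zero trimmed mean: {bad[:5]}")
    target = tm.mean()
    scaled = vals * (target / tm)[None, :]
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=E.values.index, columns=E.values.columns),
        E.sample_of_cell,
    )


def qc_summary(E: ExpressionMatrix) -> dict[str, pd.DataFrame]:
    """Diagnostic tables for between-sample comparability.

    For every pair of samples: per-gene MA values
    (``M = log2(mean_1) - log2(mean_2)``, ``A`` the average of the two
    log-means), matched quantiles of the two samples' per-gene means
    (Q-Q), and all cross-sample cell Pearson correlations on a
    log2(x + 1) scale with distance ``1 - r``.
    """
    samples = E.samples
    if len(samples) < 2:
        raise ValueError("QC summary needs >= 2 samples")
    ma_rows, qq_rows, cor_rows = [], [], []
    logv = np.log2(E.values.to_numpy(dtype=float) + 1.0)
    col_index = {c: i for i, c in enumerate(E.values.columns)}
    for s1, s2 in combinations(samples, 2):
        m1 = E.values[E.cells_in_sample(s1)].mean(axis=1).to_numpy()
        m2 = E.values[E.cells_in_sample(s2)].mean(axis=1).to_numpy()
        with np.errstate(divide="ignore"):
            l1, l2 = np.log2(m1), np.log2(m2)
        ma_rows.append(
            pd.DataFrame(
                {
                    "gene_id": E.gene_ids,
                    "sample_1": s1,
                    "sample_2": s2,
                    "M": l1 - l2,
                    "A": 0.5 * (l1 + l2),
                }
            )
        )
        probs = np.linspace(0, 1, min(len(m1), 1001))
        qq_rows.append(
            pd.DataFrame(
                {
                    "sample_1": s1,
                    "sample_2": s2,
                    "quantile": probs,
                    "q1": np.quantile(m1, probs),
                    "q2": np.quantile(m2, probs),
                }
            )
        )
        idx1 = [col_index[c] for c in E.cells_in_sample(s1)]
        idx2 = [col_index[c] for c in E.cells_in_sample(s2)]
        block1, block2 = logv[:, idx1], logv[:, idx2]
        # cross-sample cell-cell Pearson correlations
        a = block1 - block1.mean(axis=0, keepdims=True)
        b = block2 - block2.mean(axis=0, keepdims=True)
        denom = np.outer(
            np.sqrt((a**2).sum(axis=0)), np.sqrt((b**2).sum(axis=0))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (a.T @ b) / np.where(denom > 0, denom, 1.0), np.nan)
        for i, c1 in enumerate(E.cells_in_sample(s1)):
            for j, c2 in enumerate(E.cells_in_sample(s2)):
                cor_rows.append((s1, s2, c1, c2, r[i, j], 1.0 - r[i, j]))
    cor = pd.DataFrame(
        cor_rows,
        columns=["sample_1", "sample_2", "cell_1", "cell_2", "correlation", "distance"],
    )
    return {
        "ma": pd.concat(ma_rows, ignore_index=True),
        "qq": pd.concat(qq_rows, ignore_index=True),
        "cell_correlation": cor,
    }
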
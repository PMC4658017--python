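import numpy as np
import pandas as pd
import pytest

from cytotype.clustering import (
    cell_distance_matrix,
    hierarchical_clusters,
)
from cytotype.core_io import ExpressionMatrix
from cytotype.diffexpr import cluster_differential_expression
from cytotype.preprocess import prefilter, zscore_normalize
from cytotype.simulate import SimulationConfig, simulate_cells


def make_matrix(values, genes=None, cells=None, samples=None, signed=False):
    """Small helper to build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    samples = samples or ["s1"] * len(cells)
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cells),
        pd.Series(samples, index=cells, name="sample"),
        signed=signed,
    )


@pytest.fixture(scope="session")
def planted():
    """The default three-population cohort with ground truth (seed 1)."""
    return simulate_cells(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def planted_clustering(planted):
    """Prefilter + z-score + hierarchical clustering of the cohort."""
    kept, report = prefilter(planted.expression)
    Z = zscore_normalize(kept)
    D = cell_distance_matrix(Z)
    assignment = hierarchical_clusters(D, threshold=0.5)
    return {"kept": kept, "report": report, "Z": Z, "assignment": assignment}


@pytest.fixture(scope="session")
def planted_de(planted, planted_clustering):
    """One-vs-rest DE over all genes of the cohort (z-scored input)."""
    Zall = zscore_normalize(planted.expression)
    return cluster_differential_expression(
        Zall, planted_clustering["assignment"]
    )


@pytest.fixture(scope="session")
def cluster_truth_map(planted, planted_clustering):
    """Recovered cluster label -> true population label."""
    assignment = planted_clustering["assignment"]
    mapping = {}
    for cl in assignment.cluster_names:
        truth = planted.true_labels.loc[assignment.cells_in(cl)].mode()[0]
        mapping[cl] = truth
    return mapping
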
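"""Shared fixtures: seeded synthetic bundles and small hand-built datasets."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tissuemod import network
from tissuemod.dataset import ExpressionDataset
from tissuemod.pipeline import network_matrix_from_bundle
from tissuemod.simulate import SimulationConfig, simulate_study

#: Soft power used for module detection on the default bundle throughout the
#: desk-scale analyses (strong enough to suppress background correlation).
BUNDLE_POWER = 8


def tom_reference(a: np.ndarray) -> np.ndarray:
    """Direct triple-loop topological overlap, the independent oracle."""
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ell = sum(a0[i, u] * a0[u, j] for u in range(n) if u != i and u != j)
            t[i, j] = (ell + a0[i, j]) / (min(k[i], k[j]) + 1.0 - a0[i, j])
    return t


def make_dataset(values, status, name="toy", tissue="PFC", meta_extra=None):
    """Small ExpressionDataset from a 2-D array and a status list."""
    values = np.asarray(values, float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame(
        {
            "tissue": tissue,
            "status": list(status),
            "batch": name,
            "age": 50.0,
            "sex": 0.0,
            "ph": 7.0,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    if meta_extra:
        for k, v in meta_extra.items():
            meta[k] = v
    expr = pd.DataFrame(values,
                        index=pd.Index([f"G{i}" for i in range(values.shape[0])],
                                       name="gene"),
                        columns=samples)
    return ExpressionDataset(expr, meta, name=name)


@pytest.fixture(scope="session")
def default_bundle():
    """The default study conditions, seed 0: datasets plus ground truth."""
    return simulate_study(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def bundle_matrix(default_bundle):
    """Cross-tissue batch-adjusted matrix (full gene panel) for seed 0."""
    datasets, truth = default_bundle
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = network_matrix_from_bundle(datasets)
    return matrix, truth


@pytest.fixture(scope="session")
def bundle_modules(bundle_matrix):
    """Detected + merged + tissue-correlated modules on the seed-0 bundle."""
    matrix, truth = bundle_matrix
    net = network.build_network(matrix.expr, BUNDLE_POWER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ms = network.detect_modules(net)
        ms = network.merge_similar_modules(matrix.expr, ms)
        ms = network.module_tissue_correlation(matrix.expr, ms, matrix.tissue_labels)
    return net, ms
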
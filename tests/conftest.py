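"""Shared fixtures: synthetic study datasets and derived pipeline stages.

The heavier fixtures are session-scoped so the closed-loop dataset (20
experiments, 5 planted archetypes) is simulated once and reused by the
rates, clustering, conditionality and acceptance tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import phenoclust as pc

logging.getLogger("phenoclust").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def registry():
    return pc.default_registry()


@pytest.fixture(scope="session")
def library(registry):
    return pc.default_archetype_library(registry)


@pytest.fixture(scope="session")
def dataset_noisy(library):
    """The closed-loop study dataset: 20 experiments, sigma = 0.02, seed 7."""
    return pc.generate_dataset(20, library, seed=7, noise_sigma=0.02)


@pytest.fixture(scope="session")
def dataset_clean(library):
    """Noise-free control of the same design (seed 7, sigma = 0)."""
    return pc.generate_dataset(20, library, seed=7, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noisy_vectors(dataset_noisy):
    exps, _ = dataset_noisy
    return pc.compute_all_rate_vectors(exps)


@pytest.fixture(scope="session")
def clean_vectors(dataset_clean):
    exps, _ = dataset_clean
    return pc.compute_all_rate_vectors(exps)


@pytest.fixture(scope="session")
def trimmed(noisy_vectors):
    kept, removed = pc.remove_outliers(noisy_vectors)
    return kept, removed


@pytest.fixture(scope="session")
def zscored(trimmed):
    kept, _ = trimmed
    X = pc.vectors_to_matrix(kept)
    scaler = pc.zscore_fit(X)
    return kept, pc.zscore_apply(scaler, X)


@pytest.fixture(scope="session")
def cd_model(zscored):
    """Reference clustering of the study dataset: cd k-means at the true k."""
    kept, Z = zscored
    return pc.kmeans_cluster(Z, kept, k=5, metric="cd", replicates=20, seed=1)


@pytest.fixture(scope="session")
def blobs():
    """Three well-separated Gaussian blobs in 4 dimensions."""
    rng = np.random.default_rng(0)
    centers = np.array(
        [[8.0, 0, 0, 0], [0, 8.0, 0, 0], [0, 0, 8.0, 0]], dtype=float
    )
    X = np.vstack([rng.normal(c, 0.4, size=(30, 4)) for c in centers])
    labels = np.repeat([0, 1, 2], 30)
    return X, labels
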
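"""Shared fixtures: small synthetic collections and random representations."""

from __future__ import annotations

import numpy as np
import pytest

import cskl
from cskl.synthetic import CollectionSpec, random_covariance_spec


def random_representation(
    n: int, c: int, alpha: float, rng: np.random.Generator, dataset_id: str = "rep"
) -> cskl.CompressedRepresentation:
    """A valid representation with random orthonormal axes and eigenvalues."""
    axes, _ = np.linalg.qr(rng.standard_normal((n, c)))
    lam = np.sort(rng.uniform(0.5, 2.0, c))[::-1]
    lam = lam * (alpha * n / lam.sum())
    return cskl.CompressedRepresentation(
        dataset_id=dataset_id,
        n=n,
        m=n + 5,
        alpha=alpha,
        c=c,
        axes=axes,
        eigenvalues=lam,
        sigma=1.0 - alpha,
    )


def make_dataset(
    values: np.ndarray, dataset_id: str = "ds", platform_id: str = "p"
) -> cskl.Dataset:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return cskl.Dataset(
        dataset_id=dataset_id,
        platform_id=platform_id,
        sample_ids=tuple(f"s{i}" for i in range(m)),
        variable_ids=tuple(f"v{i}" for i in range(n)),
        values=values,
    )


@pytest.fixture(scope="session")
def small_collection():
    """3 disease groups x 3 datasets, n=120, m=40: fast end-to-end fixture."""
    return cskl.default_collection(
        seed=11, n=120, m=40, n_groups=3, datasets_per_group=3
    )


@pytest.fixture(scope="session")
def small_reps(small_collection):
    datasets, _, _ = small_collection
    return [cskl.decompose(cskl.standardize(d), alpha=0.5) for d in datasets]


@pytest.fixture(scope="session")
def fitted_small(small_collection):
    """The small collection fitted with a short bootstrap (shared, read-only)."""
    datasets, labels, _ = small_collection
    model = cskl.DatasetSimilarityModel(datasets, alpha=0.5, labels=labels)
    return model.fit(n_bootstrap=99, seed=5)


@pytest.fixture(scope="session")
def crosslink_collection():
    """Two 2-dataset groups sharing one planted factor on variables 0..19."""
    n = 200
    groups = tuple(
        (f"g{i}", 2, random_covariance_spec(n, 4, signal_fraction=0.3, seed=60 + i))
        for i in range(2)
    )
    spec = CollectionSpec(
        platform_id="p",
        n=n,
        groups=groups,
        cross_links=(cskl.CrossLink("g0", "g1", tuple(range(20)), 0.3),),
        samples_per_dataset=60,
        seed=21,
        loading_jitter=0.5,
    )
    return cskl.generate_collection(spec)
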
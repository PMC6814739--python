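"""Synthetic dataset collections with planted covariance structure.

The generator realizes exactly the model class the divergence assumes:
zero-mean Gaussian samples whose covariance is low-rank-plus-isotropic,

    Sigma = L L^T + noise_variance * I,

with the factor loadings L optionally supported on a subset of "active"
variables (the planted mechanism).  A *collection* emulates a repository
snapshot: several disease groups, each contributing a handful of datasets
that share the group's covariance up to a per-dataset loading jitter, plus
optional cross-group links that inject one shared factor over a common
variable subset into two groups.  The returned ground truth (which pairs
are planted similar, and through which variables) is the oracle for
significance, network and explanation tests.

Defaults are desk-scale but keep the m << n regime the method targets:
n=500 variables, rank-5 structure carrying 60% of total variance, m=60
samples, 4 groups x 5 datasets, loading jitter 0.5.  The jitter sits where
group members remain clearly more similar to each other than to other
groups while every dataset is still a distinct distribution — the regime
the collection is meant to emulate (same disease, different studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import Dataset
from .exceptions import ParameterError, ValidationError

__all__ = [
    "CovarianceSpec",
    "CollectionSpec",
    "CrossLink",
    "random_covariance_spec",
    "sample_dataset",
    "generate_collection",
    "default_collection_spec",
    "default_collection",
]


@dataclass(frozen=True)
class CovarianceSpec:
    """A planted low-rank-plus-isotropic covariance: L L^T + noise * I."""

    n: int
    rank: int
    loadings: np.ndarray  # n x rank
    noise_variance: float
    active_variables: tuple[int, ...]

    def covariance(self) -> np.ndarray:
        """The implied n x n covariance matrix (materialize only at small n)."""
        return self.loadings @ self.loadings.T + self.noise_variance * np.eye(self.n)

    def structured_variance(self) -> float:
        return float((self.loadings**2).sum())


@dataclass(frozen=True)
class CrossLink:
    """A shared factor injected into two disease groups over common variables."""

    label_a: str
    label_b: str
    shared_variables: tuple[int, ...]
    strength: float  # shared-factor variance as a fraction of total variance


@dataclass(frozen=True)
class CollectionSpec:
    """Recipe for a grouped synthetic collection on one platform."""

    platform_id: str
    n: int
    groups: tuple[tuple[str, int, CovarianceSpec], ...]  # (label, n_datasets, spec)
    cross_links: tuple[CrossLink, ...] = ()
    samples_per_dataset: int | tuple[int, int] = 60
    seed: int = 7
    loading_jitter: float = 0.5

    def __post_init__(self) -> None:
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValidationError("group labels must be unique")
        lo = (
            self.samples_per_dataset
            if isinstance(self.samples_per_dataset, int)
            else self.samples_per_dataset[0]
        )
        if lo < 4:
            raise ValidationError("samples_per_dataset must be >= 4")
        for link in self.cross_links:
            if link.label_a not in labels or link.label_b not in labels:
                raise ValidationError(f"cross link references unknown group: {link}")


def random_covariance_spec(
    n: int,
    rank: int,
    signal_fraction: float = 1.0,
    seed: int = 0,
    signal_variance_fraction: float = 0.6,
    noise_variance: float = 1.0,
) -> CovarianceSpec:
    """Draw a random planted covariance.

    ``signal_fraction`` of the variables are active (carry loadings);
    loadings are Gaussian on the active rows and rescaled so the
    structured part contributes ``signal_variance_fraction`` of the total
    variance.  Deterministic per seed.
    """
    if not 1 <= rank < n:
        raise ParameterError(f"rank must be in [1, n), got rank={rank}, n={n}")
    if not 0.0 < signal_fraction <= 1.0:
        raise ParameterError("signal_fraction must be in (0, 1]")
    if not 0.0 < signal_variance_fraction < 1.0:
        raise ParameterError("signal_variance_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_active = int(np.ceil(signal_fraction * n))
    active = np.sort(rng.choice(n, size=n_active, replace=False))
    loadings = np.zeros((n, rank))
    loadings[active] = rng.standard_normal((n_active, rank))
    # structured variance f/(1-f) times the noise total keeps the stated split
    target = signal_variance_fraction / (1.0 - signal_variance_fraction) * noise_variance * n
    loadings *= np.sqrt(target / (loadings**2).sum())
    return CovarianceSpec(
        n=n,
        rank=rank,
        loadings=loadings,
        noise_variance=noise_variance,
        active_variables=tuple(int(i) for i in active),
    )


def sample_dataset(
    spec: CovarianceSpec,
    m: int,
    dataset_id: str,
    seed: int = 0,
    platform_id: str = "synthetic",
) -> Dataset:
    """Draw m zero-mean Gaussian samples with the spec's implied covariance."""
    if m < 2:
        raise ParameterError(f"m must be >= 2, got {m}")
    if spec.noise_variance <= 0:
        raise ValidationError("noise_variance must be positive for a PD covariance")
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((m, spec.rank))
    noise = rng.standard_normal((m, spec.n)) * np.sqrt(spec.noise_variance)
    values = factors @ spec.loadings.T + noise
    return Dataset(
        dataset_id=dataset_id,
        platform_id=platform_id,
        sample_ids=tuple(f"{dataset_id}.s{i}" for i in range(m)),
        variable_ids=tuple(f"v{i:05d}" for i in range(spec.n)),
        values=values,
    )


def _jitter_spec(spec: CovarianceSpec, jitter: float, rng: np.random.Generator) -> CovarianceSpec:
    """Perturb loadings (active rows only) by a relative Gaussian jitter.

    The perturbed loadings are rescaled to preserve the structured
    variance, so jitter changes the *direction* of a dataset's factors —
    group members stay similar but are distinct distributions.
    """
    if jitter == 0.0:
        return spec
    loadings = spec.loadings.copy()
    active = np.array(spec.active_variables)
    scale = np.sqrt((loadings[active] ** 2).mean())
    loadings[active] += jitter * scale * rng.standard_normal((active.size, spec.rank))
    loadings *= np.sqrt(spec.structured_variance() / (loadings**2).sum())
    return CovarianceSpec(
        n=spec.n,
        rank=spec.rank,
        loadings=loadings,
        noise_variance=spec.noise_variance,
        active_variables=spec.active_variables,
    )


def _with_shared_factor(
    spec: CovarianceSpec, shared: np.ndarray, variables: tuple[int, ...]
) -> CovarianceSpec:
    loadings = np.hstack([spec.loadings, shared[:, None]])
    return CovarianceSpec(
        n=spec.n,
        rank=spec.rank + 1,
        loadings=loadings,
        noise_variance=spec.noise_variance,
        active_variables=tuple(sorted(set(spec.active_variables) | set(variables))),
    )


def generate_collection(
    cspec: CollectionSpec,
) -> tuple[list[Dataset], dict[str, str], pd.DataFrame]:
    """Materialize a collection: datasets, disease labels, and ground truth.

    Ground truth lists every within-group pair and every cross-link pair
    (columns: id_a, id_b, relation, label_a, label_b, shared_variables).
    """
    root = np.random.SeedSequence(cspec.seed)
    link_seq, *group_seqs = root.spawn(1 + len(cspec.groups))
    link_rng = np.random.default_rng(link_seq)

    # inject cross-link shared factors into the affected group specs
    group_specs: dict[str, CovarianceSpec] = {g[0]: g[2] for g in cspec.groups}
    link_vars: dict[tuple[str, str], tuple[int, ...]] = {}
    for link in cspec.cross_links:
        base = group_specs[link.label_a]
        shared = np.zeros(base.n)
        idx = np.array(link.shared_variables)
        direction = link_rng.standard_normal(idx.size)
        variance = link.strength * (base.structured_variance() + base.noise_variance * base.n)
        shared[idx] = direction * np.sqrt(variance) / np.linalg.norm(direction)
        for label in (link.label_a, link.label_b):
            group_specs[label] = _with_shared_factor(
                group_specs[label], shared, link.shared_variables
            )
        link_vars[(link.label_a, link.label_b)] = tuple(int(i) for i in link.shared_variables)

    datasets: list[Dataset] = []
    labels: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for (label, count, _), seq in zip(cspec.groups, group_seqs):
        rng = np.random.default_rng(seq)
        members[label] = []
        for d in range(count):
            ds_spec = _jitter_spec(group_specs[label], cspec.loading_jitter, rng)
            if isinstance(cspec.samples_per_dataset, int):
                m = cspec.samples_per_dataset
            else:
                lo, hi = cspec.samples_per_dataset
                m = int(rng.integers(lo, hi + 1))
            ds_id = f"{label}_{d}"
            datasets.append(
                sample_dataset(
                    ds_spec,
                    m,
                    ds_id,
                    seed=int(rng.integers(2**31)),
                    platform_id=cspec.platform_id,
                )
            )
            labels[ds_id] = label
            members[label].append(ds_id)

    truth_rows = []
    for label, ids in members.items():
        shared = group_specs[label].active_variables
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                truth_rows.append(
                    {
                        "id_a": a,
                        "id_b": b,
                        "relation": "within_group",
                        "label_a": label,
                        "label_b": label,
                        "shared_variables": shared,
                    }
                )
    for (la, lb), variables in link_vars.items():
        for a in members[la]:
            for b in members[lb]:
                truth_rows.append(
                    {
                        "id_a": a,
                        "id_b": b,
                        "relation": "cross_link",
                        "label_a": la,
                        "label_b": lb,
                        "shared_variables": variables,
                    }
                )
    columns = ["id_a", "id_b", "relation", "label_a", "label_b", "shared_variables"]
    return datasets, labels, pd.DataFrame(truth_rows, columns=columns)


def default_collection_spec(
    seed: int = 7,
    n: int = 500,
    rank: int = 5,
    m: int = 60,
    n_groups: int = 4,
    datasets_per_group: int = 5,
    loading_jitter: float = 0.5,
) -> CollectionSpec:
    """The standard desk-scale collection: 4 disease groups x 5 datasets."""
    root = np.random.SeedSequence(seed)
    group_seeds = root.spawn(n_groups)
    groups = []
    for g, gseed in enumerate(group_seeds):
        spec = random_covariance_spec(
            n, rank, seed=int(np.random.default_rng(gseed).integers(2**31))
        )
        groups.append((f"disease{g}", datasets_per_group, spec))
    return CollectionSpec(
        platform_id="synthetic_platform",
        n=n,
        groups=tuple(groups),
        samples_per_dataset=m,
        seed=seed,
        loading_jitter=loading_jitter,
    )


def default_collection(
    seed: int = 7, **kwargs
) -> tuple[list[Dataset], dict[str, str], pd.DataFrame]:
    """Generate the standard collection (see :func:`default_collection_spec`)."""
    return generate_collection(default_collection_spec(seed=seed, **kwargs))
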
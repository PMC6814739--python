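"""Sibling-split self-validation of the divergence.

Split every dataset in a collection at random into two sample-halves
("siblings").  The halves of one dataset are, by construction, samples
from the same distribution, so a divergence that works should find each
half's nearest neighbor among all other halves to be its own sibling.
The fraction of halves for which that holds — the *sibling recovery
fraction* — is the collection-scale sanity statistic for the method and
the basis for choosing the compression level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Dataset, standardize
from .decomposition import decompose
from .divergence import pairwise_cskl
from .exceptions import ValidationError

__all__ = ["SiblingExperimentResult", "sibling_split", "sibling_recovery_experiment"]

_HALF_SUFFIXES = ("__half1", "__half2")


@dataclass(frozen=True)
class SiblingExperimentResult:
    """Outcome of one sibling-recovery experiment at a fixed alpha."""

    alpha: float
    n_datasets: int
    recovery_fraction: float
    per_dataset: pd.DataFrame  # dataset_id, sibling_rank_a_to_b, sibling_rank_b_to_a


def sibling_split(dataset: Dataset, seed: int = 0) -> tuple[Dataset, Dataset]:
    """Randomly partition a dataset's samples into two disjoint halves.

    Halves have ceil(m/2) and floor(m/2) samples, keep the full variable
    set, and get ``__half1`` / ``__half2`` ID suffixes.  Deterministic per
    seed.
    """
    m = dataset.n_samples
    if m < 4:
        raise ValidationError(
            f"dataset {dataset.dataset_id!r} has {m} samples; need >= 4 to split"
        )
    order = np.random.default_rng(seed).permutation(m)
    cut = (m + 1) // 2
    halves = []
    for suffix, rows in zip(_HALF_SUFFIXES, (order[:cut], order[cut:])):
        halves.append(
            Dataset(
                dataset_id=dataset.dataset_id + suffix,
                platform_id=dataset.platform_id,
                sample_ids=tuple(dataset.sample_ids[i] for i in rows),
                variable_ids=dataset.variable_ids,
                values=dataset.values[rows],
            )
        )
    return halves[0], halves[1]


def sibling_recovery_experiment(
    datasets: list[Dataset],
    alpha: float = 0.5,
    seed: int = 7,
) -> SiblingExperimentResult:
    """Split, compress and rank every half against all others.

    Each half is re-standardized on its own samples before decomposition.
    For each half, the rank of its sibling among all other halves under
    c-SKL is recorded (rank 1 = nearest neighbor; ties broken by dataset
    ID); the recovery fraction is the share of halves whose sibling ranks
    first.
    """
    if len(datasets) < 3:
        raise ValidationError("need at least 3 datasets for a meaningful ranking")
    rng = np.random.default_rng(seed)
    halves: list[Dataset] = []
    for ds in datasets:
        a, b = sibling_split(ds, seed=int(rng.integers(2**31)))
        halves.extend([a, b])
    reps = [decompose(standardize(h), alpha=alpha) for h in halves]
    matrix = pairwise_cskl(reps)

    def sibling_rank(half_id: str, sibling_id: str) -> int:
        row = matrix.loc[half_id].drop(half_id)
        # sort by divergence, ties by ID, and locate the sibling
        order = sorted(row.index, key=lambda other: (row[other], other))
        return order.index(sibling_id) + 1

    rows = []
    hits = 0
    for ds in datasets:
        id_a = ds.dataset_id + _HALF_SUFFIXES[0]
        id_b = ds.dataset_id + _HALF_SUFFIXES[1]
        rank_ab = sibling_rank(id_a, id_b)
        rank_ba = sibling_rank(id_b, id_a)
        hits += (rank_ab == 1) + (rank_ba == 1)
        rows.append(
            {
                "dataset_id": ds.dataset_id,
                "sibling_rank_a_to_b": rank_ab,
                "sibling_rank_b_to_a": rank_ba,
            }
        )
    return SiblingExperimentResult(
        alpha=alpha,
        n_datasets=len(datasets),
        recovery_fraction=hits / (2 * len(datasets)),
        per_dataset=pd.DataFrame(rows),
    )
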
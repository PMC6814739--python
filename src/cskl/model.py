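"""Model/Results interface over a whole dataset collection.

``DatasetSimilarityModel`` holds an aligned, standardized collection and
the compression level; ``fit`` compresses every dataset, computes all
pairwise divergences and (optionally) their bootstrap significance, and
returns a ``DatasetSimilarityResults`` carrying the pair table, the
divergence matrix, and constructors for the similarity and disease
networks and for pair explanations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import Dataset, align_platform, load_collection, standardize
from .decomposition import CompressedRepresentation, decompose
from .divergence import PairResult, cskl
from .exceptions import ValidationError
from .explanation import ExplanationResult, explain_pair
from .networks import build_dataset_network, build_disease_network
from .significance import (
    BootstrapConfig,
    PooledSamplePool,
    adjust_fdr,
    bootstrap_p_value,
)

__all__ = ["DatasetSimilarityModel", "DatasetSimilarityResults"]


class DatasetSimilarityModel:
    """Pairwise distribution-similarity analysis of one platform's datasets.

    Parameters
    ----------
    datasets:
        Same-platform datasets; they are aligned to their common variables
        and z-scored on construction.
    alpha:
        Compression level: fraction of total variance retained by the
        principal axes of every dataset (default 0.5).
    labels:
        Optional dataset_id -> disease/phenotype label mapping, carried
        through to the network constructors.
    """

    def __init__(
        self,
        datasets: list[Dataset],
        alpha: float = 0.5,
        labels: dict[str, str] | None = None,
    ):
        if len(datasets) < 2:
            raise ValidationError("need at least 2 datasets to compare")
        aligned = align_platform(datasets)
        self.alpha = float(alpha)
        self.labels = dict(labels) if labels else {}
        self.platform_id = aligned[0].platform_id
        self.standardized = [standardize(d) for d in aligned]
        widths = {s.n_variables for s in self.standardized}
        if len(widths) > 1:
            # a zero-variance drop in one dataset breaks comparability
            raise ValidationError(
                "datasets disagree on retained variables after standardization; "
                "re-align after dropping constant columns"
            )

    @classmethod
    def from_manifest(
        cls,
        manifest_path: str | Path,
        platform_id: str | None = None,
        alpha: float = 0.5,
        labels: dict[str, str] | None = None,
    ) -> "DatasetSimilarityModel":
        """Build the model from a (dataset_id, platform_id, path) manifest."""
        return cls(load_collection(manifest_path, platform_id), alpha=alpha, labels=labels)

    def fit(
        self,
        n_bootstrap: int | None = 199,
        seed: int = 0,
        matched_size_policy: str = "mean_of_pair",
    ) -> "DatasetSimilarityResults":
        """Compress every dataset and compute all pairwise divergences.

        With ``n_bootstrap`` set (default 199) every pair also gets a
        semi-parametric bootstrap p-value against the pooled background
        and a BH q-value; pass ``n_bootstrap=None`` to skip testing.
        """
        reps = [decompose(s, alpha=self.alpha) for s in self.standardized]
        ids = [r.dataset_id for r in reps]
        k = len(reps)
        matrix = np.zeros((k, k))
        pairs: list[PairResult] = []
        observed: dict[tuple[int, int], float] = {}
        for i in range(k):
            for j in range(i + 1, k):
                matrix[i, j] = matrix[j, i] = observed[(i, j)] = cskl(reps[i], reps[j])

        p_values: list[float | None]
        if n_bootstrap:
            pool = PooledSamplePool.from_standardized(self.standardized)
            seeds = np.random.SeedSequence(seed).generate_state(len(observed))
            p_values = [
                bootstrap_p_value(
                    reps[i],
                    reps[j],
                    pool,
                    BootstrapConfig(
                        n_iterations=n_bootstrap,
                        seed=int(s),
                        matched_size_policy=matched_size_policy,
                    ),
                    s_obs=observed[(i, j)],
                )
                for (i, j), s in zip(observed, seeds)
            ]
            q_values = adjust_fdr(np.array(p_values))
        else:
            p_values = [None] * len(observed)
            q_values = [None] * len(observed)
        for (i, j), p, q in zip(observed, p_values, q_values):
            pairs.append(
                PairResult(
                    ids[i],
                    ids[j],
                    observed[(i, j)],
                    p,
                    float(q) if q is not None else None,
                )
            )
        return DatasetSimilarityResults(
            model=self,
            representations=reps,
            divergence_matrix=pd.DataFrame(matrix, index=ids, columns=ids),
            pairs=pairs,
        )


class DatasetSimilarityResults:
    """Fitted pairwise similarities with significance and downstream views."""

    def __init__(
        self,
        model: DatasetSimilarityModel,
        representations: list[CompressedRepresentation],
        divergence_matrix: pd.DataFrame,
        pairs: list[PairResult],
    ):
        self.model = model
        self.representations = representations
        self.divergence_matrix = divergence_matrix
        self.pairs = pairs
        self._rep_by_id = {r.dataset_id: r for r in representations}

    @property
    def pair_table(self) -> pd.DataFrame:
        """Long-format pair table (id_a, id_b, cskl, p, q) sorted by c-SKL."""
        frame = pd.DataFrame(
            [
                {
                    "id_a": p.dataset_id_a,
                    "id_b": p.dataset_id_b,
                    "cskl": p.cskl,
                    "p": p.p_value,
                    "q": p.q_value,
                }
                for p in self.pairs
            ]
        )
        return frame.sort_values("cskl", kind="stable").reset_index(drop=True)

    def significant(self, q_threshold: float = 0.05) -> list[PairResult]:
        """Pairs with q below the threshold, most significant first."""
        tested = [p for p in self.pairs if p.q_value is not None]
        return sorted(
            (p for p in tested if p.q_value < q_threshold),
            key=lambda p: (p.q_value, p.cskl, p.key),
        )

    def to_network(self, q_threshold: float = 0.05, top_edges: int | None = None):
        """Dataset similarity network over the significant pairs."""
        return build_dataset_network(
            self.significant(q_threshold),
            top_edges=top_edges,
            labels=self.model.labels or None,
            platform_id=self.model.platform_id,
        )

    def to_disease_network(self, q_threshold: float = 0.05, min_weight: int = 1):
        """Disease-to-disease network aggregated from the significant pairs."""
        if not self.model.labels:
            raise ValidationError("model has no disease labels")
        return build_disease_network(
            self.to_network(q_threshold), self.model.labels, min_weight=min_weight
        )

    def explain(
        self, dataset_id_a: str, dataset_id_b: str, k: int, mode: str = "best", **kwargs
    ) -> ExplanationResult:
        """B(k)/W(k) explanation of one fitted pair's divergence."""
        return explain_pair(
            self._rep_by_id[dataset_id_a], self._rep_by_id[dataset_id_b], k, mode, **kwargs
        )

    def variable_names(self, result: ExplanationResult) -> list[str]:
        """Map an explanation's variable indices back to platform variable IDs."""
        variables = self.model.standardized[0].variable_ids
        return [variables[i] for i in result.selected]

    def summary(self, q_threshold: float = 0.05) -> str:
        """Human-readable fit summary: collection facts and the closest pairs."""
        tested = self.pairs[0].p_value is not None
        lines = [
            "Dataset similarity analysis (c-SKL)",
            "=" * 48,
            f"platform:            {self.model.platform_id}",
            f"datasets:            {len(self.representations)}",
            f"variables (aligned): {self.representations[0].n}",
            f"compression alpha:   {self.model.alpha}",
            f"pairs compared:      {len(self.pairs)}",
        ]
        if tested:
            lines.append(
                f"significant (q<{q_threshold:g}): {len(self.significant(q_threshold))}"
            )
        top = self.pair_table.head(10)
        lines += ["", "closest pairs:", top.to_string(index=False, float_format="%.4g")]
        return "\n".join(lines)

    def plot_divergence_heatmap(self, ax=None):
        """Heatmap of the pairwise divergence matrix (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        ids = list(self.divergence_matrix.index)
        image = ax.imshow(self.divergence_matrix.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=6)
        ax.set_yticks(range(len(ids)), ids, fontsize=6)
        ax.figure.colorbar(image, ax=ax, label="c-SKL")
        return ax
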
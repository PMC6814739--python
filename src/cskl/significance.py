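"""Semi-parametric bootstrap significance of observed c-SKL similarities.

Testing exact equality of two omics distributions is pointless — different
studies never sample identical populations — so the question asked here is
relative: is the observed pair strictly more similar to each other than
either member is to the *pooled background* J, the union of all sample
profiles on the platform?  For each bootstrap iteration a pseudo-dataset
of matched sample size is drawn from the pool, compressed exactly like a
real dataset, and its divergence to each member recorded; the pair's
p-value is the (add-one corrected) fraction of null draws at least as
similar, combined conservatively over the two sides by taking the larger
p.  Benjamini-Hochberg FDR control is then applied across all tested
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datasets import StandardizedDataset
from .decomposition import CompressedRepresentation, _from_spectrum, _spectrum
from .divergence import PairResult, cskl
from .exceptions import InsufficientPoolError, ValidationError

__all__ = [
    "PooledSamplePool",
    "BootstrapConfig",
    "bootstrap_p_value",
    "adjust_fdr",
    "significant_pairs",
]


@dataclass(frozen=True)
class PooledSamplePool:
    """All standardized profiles on one platform, with per-profile provenance."""

    platform_id: str
    profiles: np.ndarray  # (total samples) x n
    source_ids: tuple[str, ...]

    @classmethod
    def from_standardized(cls, stds: list[StandardizedDataset]) -> "PooledSamplePool":
        if not stds:
            raise ValidationError("cannot pool an empty dataset list")
        widths = {s.n_variables for s in stds}
        if len(widths) > 1:
            raise ValidationError(f"pooled datasets have differing variable counts {widths}")
        platform = stds[0].platform_id
        profiles = np.vstack([s.values for s in stds])
        sources = tuple(s.dataset_id for s in stds for _ in range(s.n_samples))
        return cls(platform_id=platform, profiles=profiles, source_ids=sources)

    @property
    def size(self) -> int:
        return self.profiles.shape[0]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: iteration count, seed, and null draw sizing.

    ``matched_size_policy``: ``mean_of_pair`` draws pseudo-datasets of the
    pair's mean sample count on both sides; ``per_side`` matches each
    side's own count.
    """

    n_iterations: int = 199
    seed: int = 0
    matched_size_policy: str = "mean_of_pair"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.matched_size_policy not in ("mean_of_pair", "per_side"):
            raise ValidationError(
                f"unknown matched_size_policy {self.matched_size_policy!r}"
            )


def _zscore(values: np.ndarray) -> np.ndarray:
    """Z-score columns (ddof=1); constant columns become zeros."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0
    return (values - mean) / sd


def _null_divergences(
    rep: CompressedRepresentation,
    pool: PooledSamplePool,
    draw_size: int,
    n_iterations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Divergences of ``rep`` to pseudo-datasets drawn from the pool.

    Profiles originating from ``rep``'s own dataset are excluded so a null
    draw cannot partially reproduce the dataset under test; draws are
    without replacement, re-standardized, and compressed at the same alpha.
    """
    eligible = np.flatnonzero(np.asarray(pool.source_ids) != rep.dataset_id)
    if eligible.size < draw_size:
        raise InsufficientPoolError(
            f"pool holds {eligible.size} eligible profiles for {rep.dataset_id!r}, "
            f"need {draw_size}"
        )
    out = np.empty(n_iterations)
    for b in range(n_iterations):
        rows = rng.choice(eligible, size=draw_size, replace=False)
        Z = _zscore(pool.profiles[rows])
        lam_raw, vt = _spectrum(Z)
        null_rep = _from_spectrum("__null__", draw_size, lam_raw, vt, rep.alpha)
        out[b] = cskl(rep, null_rep)
    return out


def _draw_sizes(
    repP: CompressedRepresentation,
    repQ: CompressedRepresentation,
    cfg: BootstrapConfig,
) -> tuple[int, int]:
    if cfg.matched_size_policy == "per_side":
        return repP.m, repQ.m
    size = int(round((repP.m + repQ.m) / 2))
    return size, size


def bootstrap_p_value(
    repP: CompressedRepresentation,
    repQ: CompressedRepresentation,
    pool: PooledSamplePool,
    cfg: BootstrapConfig,
    s_obs: float | None = None,
) -> float:
    """Bootstrap p-value for the pair (P, Q) being closer than background.

    The alternative is conjunctive — the observed divergence is smaller
    than both P-vs-pool and Q-vs-pool null divergences — so the two
    one-sided p-values are combined by their maximum (intersection-union).
    The add-one correction keeps p >= 1/(n_iterations+1); deterministic
    given ``cfg.seed``.
    """
    if s_obs is None:
        s_obs = cskl(repP, repQ)
    rng = np.random.default_rng(cfg.seed)
    size_p, size_q = _draw_sizes(repP, repQ, cfg)
    d_p = _null_divergences(repP, pool, size_p, cfg.n_iterations, rng)
    d_q = _null_divergences(repQ, pool, size_q, cfg.n_iterations, rng)
    p_p = (1.0 + np.count_nonzero(d_p <= s_obs)) / (cfg.n_iterations + 1.0)
    p_q = (1.0 + np.count_nonzero(d_q <= s_obs)) / (cfg.n_iterations + 1.0)
    return max(p_p, p_q)


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, same order as the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def significant_pairs(pairs: list[PairResult], q_threshold: float = 0.05) -> list[PairResult]:
    """Attach BH q-values over all pairs and keep those with q < threshold.

    The surviving pairs are sorted by ascending q, then ascending c-SKL,
    then pair IDs.
    """
    if any(p.p_value is None for p in pairs):
        raise ValidationError("every pair must carry a p-value")
    if not pairs:
        return []
    q = adjust_fdr(np.array([p.p_value for p in pairs]))
    adjusted = [
        PairResult(p.dataset_id_a, p.dataset_id_b, p.cskl, p.p_value, float(qv))
        for p, qv in zip(pairs, q)
    ]
    kept = [p for p in adjusted if p.q_value < q_threshold]
    return sorted(kept, key=lambda p: (p.q_value, p.cskl, p.key))
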
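"""The curated symmetric Kullback-Leibler (c-SKL) divergence.

Both datasets are modelled as zero-mean Gaussians with compressed
covariances Sigma_P = P Lambda^P P^T + sigma I and likewise for Q, with a
shared compression level alpha and sigma = 1 - alpha.  Their symmetric KL
divergence is then approximated from the cross-projections of the two
principal subspaces alone:

    c-SKL(P, Q) = 1 / (2 (1 - a)) * [ 2 a n
                    - sum_ij lambda_i^P (P_i . Q_j)^2
                    - sum_ij lambda_j^Q (P_i . Q_j)^2 ]

The double sums measure the squared lengths of the eigenvalue-weighted
axes of one dataset projected onto the subspace of the other, so the
divergence is 0 when the compressed covariances coincide and reaches its
maximum a n / (1 - a) when the two subspaces are orthogonal.  It is
symmetric and non-negative but does not satisfy the triangle inequality,
so it is not a metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .decomposition import CompressedRepresentation
from .exceptions import ComparabilityError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PairResult",
    "cskl",
    "exact_skl_gaussian",
    "pairwise_cskl",
    "write_pairwise_long",
    "write_pairwise_matrix",
]

# a bracket more negative than this indicates an upstream invariant violation
_NEGATIVE_ERROR = -1e-6
_NEGATIVE_WARN = -1e-9


@dataclass(frozen=True)
class PairResult:
    """One unordered dataset pair with its divergence and (optional) test results."""

    dataset_id_a: str
    dataset_id_b: str
    cskl: float
    p_value: float | None = None
    q_value: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered pair key."""
        return tuple(sorted((self.dataset_id_a, self.dataset_id_b)))  # type: ignore[return-value]


def _check_comparable(repP: CompressedRepresentation, repQ: CompressedRepresentation) -> None:
    if repP.n != repQ.n:
        raise ComparabilityError(
            f"representations have different variable counts: {repP.n} vs {repQ.n}"
        )
    if repP.alpha != repQ.alpha:
        raise ComparabilityError(
            f"representations have different compression levels: "
            f"{repP.alpha} vs {repQ.alpha}"
        )


def _clamp(value: float, context: str) -> float:
    if value >= 0.0:
        return value
    if value < _NEGATIVE_ERROR:
        raise ValidationError(
            f"{context}: divergence {value} is negative beyond floating-point "
            "tolerance; an upstream invariant is violated"
        )
    if value < _NEGATIVE_WARN:
        logger.warning("%s: clamping slightly negative divergence %g to 0", context, value)
    return 0.0


def cskl(repP: CompressedRepresentation, repQ: CompressedRepresentation) -> float:
    """c-SKL divergence between two compressed representations.

    Requires identical n and alpha (and identical variable order, enforced
    upstream by platform alignment).  Non-negative; 0 for identical
    representations; at most alpha*n/(1-alpha).
    """
    _check_comparable(repP, repQ)
    a, n = repP.alpha, repP.n
    G = repP.axes.T @ repQ.axes  # c_P x c_Q cross-projection matrix
    G2 = G * G
    bracket = 2.0 * a * n - repP.eigenvalues @ G2.sum(axis=1) - G2.sum(axis=0) @ repQ.eigenvalues
    value = bracket / (2.0 * (1.0 - a))
    return _clamp(value, f"cskl({repP.dataset_id}, {repQ.dataset_id})")


def exact_skl_gaussian(covP: np.ndarray, covQ: np.ndarray) -> float:
    """Exact symmetric KL between zero-mean Gaussians with the given covariances.

    Closed form ``0.5 * trace(covP^-1 covQ + covQ^-1 covP) - n``; the
    full-covariance quantity the compressed estimator approximates.  Used
    as a small-n oracle; infeasible at omics scale.
    """
    covP = np.asarray(covP, dtype=float)
    covQ = np.asarray(covQ, dtype=float)
    if covP.shape != covQ.shape or covP.ndim != 2 or covP.shape[0] != covP.shape[1]:
        raise ValidationError(f"covariance shapes differ: {covP.shape} vs {covQ.shape}")
    for name, cov in (("covP", covP), ("covQ", covQ)):
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValidationError(f"{name} is not symmetric")
    n = covP.shape[0]
    try:
        cP = scipy.linalg.cho_factor(covP)
        cQ = scipy.linalg.cho_factor(covQ)
    except scipy.linalg.LinAlgError as exc:
        raise ValidationError(f"covariance is not positive definite: {exc}") from exc
    trace = np.trace(scipy.linalg.cho_solve(cP, covQ)) + np.trace(
        scipy.linalg.cho_solve(cQ, covP)
    )
    return _clamp(0.5 * float(trace) - n, "exact_skl_gaussian")


def pairwise_cskl(reps: list[CompressedRepresentation]) -> pd.DataFrame:
    """Symmetric c-SKL matrix over a list of comparable representations."""
    if len(reps) < 2:
        raise ValidationError("need at least 2 representations for a pairwise matrix")
    ids = [r.dataset_id for r in reps]
    k = len(reps)
    matrix = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            matrix[i, j] = matrix[j, i] = cskl(reps[i], reps[j])
    return pd.DataFrame(matrix, index=ids, columns=ids)


def write_pairwise_long(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a pairwise matrix as a long-format TSV (id_a, id_b, cskl)."""
    rows = []
    ids = list(matrix.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            rows.append((a, b, matrix.loc[a, b]))
    pd.DataFrame(rows, columns=["id_a", "id_b", "cskl"]).to_csv(path, sep="\t", index=False)


def write_pairwise_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a pairwise matrix as a square TSV with ID row/column headers."""
    matrix.to_csv(path, sep="\t", index_label="dataset_id")
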
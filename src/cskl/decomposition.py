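"""Low-rank-plus-isotropic compression of a standardized dataset's covariance.

For a standardized dataset the sample covariance equals the sample
correlation matrix and has total variance n (one unit per variable).  With
far fewer samples than variables that matrix is rank deficient, so it is
modelled as

    Sigma = P Lambda P^T + sigma I

with P the leading principal axes, Lambda their eigenvalues and sigma an
isotropic noise floor.  The number of retained axes c is the smallest c
whose eigenvalues reach a fraction alpha of the total variance; the
retained eigenvalues are then rescaled to sum to exactly alpha * n and the
remaining per-variable variance 1 - alpha becomes sigma.  Using one alpha
for a whole collection makes every pairwise divergence comparable, and the
representation of each dataset can be computed once and cached.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .datasets import StandardizedDataset
from .exceptions import DegenerateDataError, ParameterError, ValidationError

__all__ = [
    "CompressedRepresentation",
    "decompose",
    "explained_variance_curve",
    "save_representation",
    "load_representation",
]

# eigenvalues below this are numerical zeros and never retained
_RANK_GUARD = 1e-10


@dataclass(frozen=True)
class CompressedRepresentation:
    """Truncated decomposition of one standardized dataset's covariance.

    ``axes`` is n x c orthonormal, ``eigenvalues`` the c normalized
    eigenvalues (non-increasing, summing to ``alpha * n``), ``sigma`` the
    isotropic noise variance ``1 - alpha``.
    """

    dataset_id: str
    n: int
    m: int
    alpha: float
    c: int
    axes: np.ndarray
    eigenvalues: np.ndarray
    sigma: float

    def validate(self, atol: float = 1e-8) -> None:
        """Check the structural invariants; raise ValidationError on failure."""
        if self.axes.shape != (self.n, self.c):
            raise ValidationError(f"axes shape {self.axes.shape} != ({self.n}, {self.c})")
        gram = self.axes.T @ self.axes
        if not np.allclose(gram, np.eye(self.c), atol=atol):
            raise ValidationError("principal axes are not orthonormal")
        lam = self.eigenvalues
        if lam.shape != (self.c,) or (lam <= 0).any() or (np.diff(lam) > atol).any():
            raise ValidationError("eigenvalues must be positive and non-increasing")
        if abs(lam.sum() - self.alpha * self.n) > 1e-6:
            raise ValidationError(
                f"eigenvalue sum {lam.sum()} != alpha*n = {self.alpha * self.n}"
            )
        if abs(self.sigma - (1.0 - self.alpha)) > 1e-12:
            raise ValidationError("sigma != 1 - alpha")
        if self.c > min(self.m - 1, self.n):
            raise ValidationError(f"c={self.c} exceeds min(m-1, n)")


def _spectrum(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the sample covariance and right singular vectors.

    Computed from the thin SVD of the data matrix — the n x n covariance is
    never materialized (n may be tens of thousands while m < 200).
    """
    m = values.shape[0]
    _, s, vt = scipy.linalg.svd(values, full_matrices=False)
    return s * s / (m - 1), vt


def decompose(std: StandardizedDataset, alpha: float = 0.5) -> CompressedRepresentation:
    """Compress a standardized dataset at compression level ``alpha``.

    ``alpha`` in (0,1) is the fraction of total variance the retained axes
    must explain; 0.5 is the collection-scale operating value.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    lam_raw, vt = _spectrum(std.values)
    return _from_spectrum(std.dataset_id, std.n_samples, lam_raw, vt, alpha)


def _from_spectrum(
    dataset_id: str,
    m: int,
    lam_raw: np.ndarray,
    vt: np.ndarray,
    alpha: float,
) -> CompressedRepresentation:
    n = vt.shape[1]
    positive = int((lam_raw > _RANK_GUARD).sum())
    if positive == 0:
        raise DegenerateDataError(f"dataset {dataset_id!r}: all eigenvalues are zero")
    target = alpha * n
    cumulative = np.cumsum(lam_raw[:positive])
    if cumulative[-1] >= target:
        c = int(np.searchsorted(cumulative, target) + 1)
    else:
        c = positive
    lam = lam_raw[:c] * (target / lam_raw[:c].sum())
    return CompressedRepresentation(
        dataset_id=dataset_id,
        n=n,
        m=m,
        alpha=alpha,
        c=c,
        axes=np.ascontiguousarray(vt[:c].T),
        eigenvalues=lam,
        sigma=1.0 - alpha,
    )


def explained_variance_curve(std: StandardizedDataset) -> np.ndarray:
    """Cumulative fraction of total variance explained by the leading axes.

    Entry j is (sum of the first j+1 covariance eigenvalues) / n; the
    curve is non-decreasing and ends at (numerically) 1 for standardized
    data.  Diagnostic for choosing alpha.
    """
    lam_raw, _ = _spectrum(std.values)
    return np.cumsum(lam_raw) / std.n_variables


def save_representation(rep: CompressedRepresentation, path: str | Path) -> None:
    """Cache a representation as an .npz archive (axes, eigenvalues, metadata)."""
    np.savez(
        path,
        dataset_id=np.array(rep.dataset_id),
        n=np.array(rep.n),
        m=np.array(rep.m),
        alpha=np.array(rep.alpha),
        c=np.array(rep.c),
        axes=rep.axes,
        eigenvalues=rep.eigenvalues,
        sigma=np.array(rep.sigma),
    )


def load_representation(path: str | Path) -> CompressedRepresentation:
    with np.load(path) as archive:
        return CompressedRepresentation(
            dataset_id=str(archive["dataset_id"]),
            n=int(archive["n"]),
            m=int(archive["m"]),
            alpha=float(archive["alpha"]),
            c=int(archive["c"]),
            axes=archive["axes"],
            eigenvalues=archive["eigenvalues"],
            sigma=float(archive["sigma"]),
        )
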
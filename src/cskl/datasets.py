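"""Loading, aligning and standardizing expression-style matrices.

A *dataset* is a samples x variables numeric matrix (e.g. one microarray
study: rows are profiled samples, columns are probe sets or genes) tagged
with the measurement *platform* that defines its variable set.  Only
datasets on the same platform are comparable, so loading is followed by
:func:`align_platform` (restrict every dataset to the common variables, in
one fixed order) and :func:`standardize` (z-score each variable), after
which each dataset is a zero-mean, unit-variance cloud whose distribution
is summarized by its correlation structure alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "StandardizedDataset",
    "load_expression_matrix",
    "load_label_table",
    "load_manifest",
    "load_collection",
    "align_platform",
    "standardize",
]


@dataclass(frozen=True)
class Dataset:
    """A samples x variables numeric matrix with identifiers and a platform tag."""

    dataset_id: str
    platform_id: str
    sample_ids: tuple[str, ...]
    variable_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "variable_ids", tuple(str(v) for v in self.variable_ids))
        m, n = values.shape if values.ndim == 2 else (0, 0)
        if values.ndim != 2 or m < 2 or n < 2:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: need a 2-D matrix with >=2 samples "
                f"and >=2 variables, got shape {values.shape}"
            )
        if len(self.sample_ids) != m:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: {len(self.sample_ids)} sample IDs "
                f"for {m} rows"
            )
        if len(self.variable_ids) != n:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: {len(self.variable_ids)} variable IDs "
                f"for {n} columns"
            )
        for kind, ids in (("sample", self.sample_ids), ("variable", self.variable_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(
                    f"dataset {self.dataset_id!r}: duplicate {kind} IDs {dupes[:5]}"
                )
        if not np.isfinite(values).all():
            bad = int(np.size(values) - np.isfinite(values).sum())
            raise ValidationError(
                f"dataset {self.dataset_id!r}: {bad} missing/non-finite entries; "
                "no imputation is performed"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class StandardizedDataset:
    """A dataset whose retained columns are z-scored (mean 0, sd 1, ddof=1)."""

    dataset_id: str
    platform_id: str
    sample_ids: tuple[str, ...]
    variable_ids: tuple[str, ...]
    values: np.ndarray
    dropped_variables: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed layout
        raise ParseError(f"{path}: cannot parse delimited matrix: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ParseError(f"{path}: empty matrix body")
    # pandas silently mangles duplicate header names; check the raw header
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(delimiter)[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate column IDs {dupes[:5]}")
    non_numeric = frame.columns[
        [not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]
    ]
    if len(non_numeric):
        coerced = frame[non_numeric].apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna() & frame[non_numeric].notna()
        if bad.any().any():
            row = bad.any(axis=1).idxmax()
            col = bad.loc[row].idxmax()
            raise ParseError(
                f"{path}: non-numeric entry {frame.loc[row, col]!r} at row "
                f"{row!r}, column {col!r}"
            )
        frame[non_numeric] = coerced
    if frame.isna().any().any():
        row = frame.isna().any(axis=1).idxmax()
        raise ParseError(f"{path}: missing value in row {row!r}; no imputation is performed")
    return frame


def load_expression_matrix(
    path: str | Path,
    delimiter: str = "\t",
    orientation: str = "samples_in_rows",
    dataset_id: str | None = None,
    platform_id: str = "",
) -> Dataset:
    """Read a delimited matrix into a :class:`Dataset`.

    The file must have a header row and an ID first column; ``orientation``
    says whether file rows are samples (``samples_in_rows``) or variables
    (``variables_in_rows``).  The returned matrix is always samples x
    variables.  Any non-numeric or missing entry is an error.
    """
    if orientation not in ("samples_in_rows", "variables_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    frame = _read_table(path, delimiter)
    if orientation == "variables_in_rows":
        frame = frame.T
    return Dataset(
        dataset_id=dataset_id or Path(path).stem,
        platform_id=platform_id,
        sample_ids=tuple(map(str, frame.index)),
        variable_ids=tuple(map(str, frame.columns)),
        values=frame.to_numpy(dtype=float),
    )


def load_label_table(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Read a two-column (dataset_id, label) table; first label wins on duplicates."""
    frame = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: label table needs two columns (dataset_id, label)")
    labels: dict[str, str] = {}
    for ds, lab in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        if ds in labels:
            if labels[ds] != lab:
                logger.warning(
                    "duplicate label for %s: keeping %r, ignoring %r", ds, labels[ds], lab
                )
            continue
        labels[str(ds)] = str(lab)
    return labels


def load_manifest(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a platform manifest with columns dataset_id, platform_id, path."""
    frame = pd.read_csv(path, sep=delimiter, header=0, dtype=str)
    required = {"dataset_id", "platform_id", "path"}
    if not required.issubset(frame.columns):
        raise ParseError(
            f"{path}: manifest must have columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    if frame["dataset_id"].duplicated().any():
        dupes = frame.loc[frame["dataset_id"].duplicated(), "dataset_id"].tolist()
        raise ValidationError(f"{path}: duplicate dataset_id(s) {dupes[:5]}")
    return frame


def load_collection(
    manifest_path: str | Path,
    platform_id: str | None = None,
    delimiter: str = "\t",
    orientation: str = "samples_in_rows",
) -> list[Dataset]:
    """Load every dataset listed in a manifest, optionally one platform only.

    Paths in the manifest are resolved relative to the manifest file.
    """
    manifest = load_manifest(manifest_path)
    if platform_id is not None:
        manifest = manifest[manifest["platform_id"] == platform_id]
    base = Path(manifest_path).parent
    datasets = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        datasets.append(
            load_expression_matrix(
                p,
                delimiter=delimiter,
                orientation=orientation,
                dataset_id=row.dataset_id,
                platform_id=row.platform_id,
            )
        )
    return datasets


def align_platform(datasets: list[Dataset]) -> list[Dataset]:
    """Restrict same-platform datasets to their common variables, sorted.

    Variables are matched by exact string ID; the aligned order is the
    lexicographically sorted intersection, identical for every output.
    """
    if not datasets:
        return []
    platforms = {d.platform_id for d in datasets}
    if len(platforms) > 1:
        raise AlignmentError(f"datasets span multiple platforms: {sorted(platforms)}")
    common = set(datasets[0].variable_ids)
    for d in datasets[1:]:
        common &= set(d.variable_ids)
    if not common:
        counts = {d.dataset_id: d.n_variables for d in datasets}
        raise AlignmentError(
            f"no variables shared by all datasets; per-dataset counts: {counts}"
        )
    order = tuple(sorted(common))
    aligned = []
    for d in datasets:
        pos = {v: i for i, v in enumerate(d.variable_ids)}
        idx = np.array([pos[v] for v in order])
        aligned.append(
            Dataset(
                dataset_id=d.dataset_id,
                platform_id=d.platform_id,
                sample_ids=d.sample_ids,
                variable_ids=order,
                values=d.values[:, idx],
            )
        )
    return aligned


def standardize(dataset: Dataset, zero_variance_policy: str = "drop") -> StandardizedDataset:
    """Z-score every variable (mean 0, sd 1 with the ddof=1 denominator).

    Constant columns have no z-score; with ``zero_variance_policy='drop'``
    they are removed (and recorded in ``dropped_variables``), with
    ``'error'`` they raise.
    """
    if zero_variance_policy not in ("drop", "error"):
        raise ValidationError(f"unknown zero_variance_policy {zero_variance_policy!r}")
    X = dataset.values
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0.0
    if constant.any():
        names = [v for v, c in zip(dataset.variable_ids, constant) if c]
        if zero_variance_policy == "error":
            raise ValidationError(
                f"dataset {dataset.dataset_id!r}: zero-variance column(s) {names[:5]}"
            )
        logger.warning(
            "dataset %s: dropping %d zero-variance column(s)", dataset.dataset_id, len(names)
        )
    keep = ~constant
    Z = (X[:, keep] - mean[keep]) / sd[keep]
    return StandardizedDataset(
        dataset_id=dataset.dataset_id,
        platform_id=dataset.platform_id,
        sample_ids=dataset.sample_ids,
        variable_ids=tuple(v for v, k in zip(dataset.variable_ids, keep) if k),
        values=Z,
        dropped_variables=tuple(v for v, k in zip(dataset.variable_ids, keep) if not k),
    )
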
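"""Categorical encoding, min-max normalization, PCA and the stratified split.

Normalization fits per-column minima/maxima on training rows only and maps
each cell to ``(x - min) / (max - min)``; constant columns map to 0 and
out-of-range cells (validation rows beyond the fitted range) are clipped to
[0, 1]. PCA, when requested, is likewise fitted on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .errors import ConfigurationError, InputError
from .io_tabular import CATEGORICAL, NUMERIC, ColumnSchema, TabularDataset

__all__ = [
    "NormalizedMatrix",
    "SplitIndex",
    "PCAReduction",
    "encode_categorical",
    "encode_dataset",
    "fit_minmax",
    "apply_minmax",
    "normalize_dataset",
    "pca_reduce",
    "stratified_split",
]

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """An ``m x n`` matrix with all values in [0, 1] plus the fitted stats."""

    values: np.ndarray
    schema: list[ColumnSchema] = field(default_factory=list)
    minima: np.ndarray | None = None
    maxima: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise InputError("normalized values must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint train/validation row indices covering all rows."""

    train_rows: np.ndarray
    val_rows: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "train_rows", np.asarray(self.train_rows, dtype=int)
        )
        object.__setattr__(self, "val_rows", np.asarray(self.val_rows, dtype=int))
        overlap = np.intersect1d(self.train_rows, self.val_rows)
        if overlap.size:
            raise ConfigurationError("train and validation rows overlap")


@dataclass
class PCAReduction:
    """A fitted principal-component projection.

    ``components`` holds the loadings as orthonormal columns (``n x k``);
    ``explained_variance_ratio`` is non-increasing.
    """

    n_components: int
    mean: np.ndarray
    components: np.ndarray  # n x k, orthonormal columns
    explained_variance_ratio: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        """Project rows onto the fitted axes (mean-centered)."""
        matrix = np.asarray(matrix, dtype=float)
        return (matrix - self.mean) @ self.components


def encode_categorical(values: Sequence[str], schema: ColumnSchema) -> np.ndarray:
    """Map category strings to integer codes by lexicographic position."""
    if schema.kind != CATEGORICAL:
        raise ConfigurationError(f"column {schema.name!r} is not categorical")
    code = {cat: i for i, cat in enumerate(schema.categories)}
    out = np.empty(len(values), dtype=int)
    for i, v in enumerate(values):
        v = str(v)
        if v not in code:
            raise InputError(
                f"unseen category {v!r} in column {schema.name!r} "
                f"(known: {list(schema.categories)})"
            )
        out[i] = code[v]
    return out


def encode_dataset(dataset: TabularDataset) -> np.ndarray:
    """Feature table as a float matrix: categorical columns label-encoded."""
    cols = []
    for col in dataset.schema:
        raw = dataset.values[col.name]
        if col.kind == NUMERIC:
            cols.append(raw.to_numpy(dtype=float))
        else:
            cols.append(encode_categorical(raw.tolist(), col).astype(float))
    return np.column_stack(cols)


def fit_minmax(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column minima and maxima over the given (training) rows."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise InputError("min-max fitting needs a 2-D matrix with >= 1 row")
    if not np.isfinite(matrix).all():
        bad = np.argwhere(~np.isfinite(matrix))[0]
        raise InputError(f"non-finite cell at row {bad[0]}, column {bad[1]}")
    return matrix.min(axis=0), matrix.max(axis=0)


def apply_minmax(
    matrix: np.ndarray,
    minima: np.ndarray,
    maxima: np.ndarray,
    schema: list[ColumnSchema] | None = None,
) -> NormalizedMatrix:
    """Rescale each column to [0, 1] with the fitted statistics.

    Constant columns (max == min) map to 0.0; cells beyond the fitted
    range are clipped into [0, 1].
    """
    matrix = np.asarray(matrix, dtype=float)
    minima = np.asarray(minima, dtype=float)
    maxima = np.asarray(maxima, dtype=float)
    if matrix.shape[1] != minima.shape[0] or minima.shape != maxima.shape:
        raise InputError("column counts of matrix and fitted stats differ")
    span = maxima - minima
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (matrix - minima) / safe_span
    scaled[:, constant] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return NormalizedMatrix(scaled, schema or [], minima, maxima)


def normalize_dataset(
    dataset: TabularDataset, train_rows: np.ndarray | None = None
) -> NormalizedMatrix:
    """Encode categoricals and min-max normalize, fitting on ``train_rows``.

    With ``train_rows=None`` the statistics are fitted on all rows.
    """
    encoded = encode_dataset(dataset)
    fit_on = encoded if train_rows is None else encoded[np.asarray(train_rows)]
    minima, maxima = fit_minmax(fit_on)
    return apply_minmax(encoded, minima, maxima, dataset.schema)


def pca_reduce(
    matrix: np.ndarray,
    n_components: int | None = None,
    variance: float | None = None,
) -> tuple[PCAReduction, np.ndarray]:
    """Fit PCA on ``matrix`` and return the reduction plus projected rows.

    Exactly one of ``n_components`` (a count) or ``variance`` (a fraction
    ``v``; the smallest k whose cumulative explained-variance ratio >= v is
    kept) must be given. Fit on training rows only and reuse
    :meth:`PCAReduction.transform` for validation rows.
    """
    matrix = np.asarray(matrix, dtype=float)
    m, n = matrix.shape
    if (n_components is None) == (variance is None):
        raise ConfigurationError("give exactly one of n_components or variance")
    rank_bound = min(m - 1, n) if m > 1 else 1
    if n_components is not None:
        if not 1 <= n_components <= rank_bound:
            raise ConfigurationError(
                f"n_components={n_components} outside [1, {rank_bound}]"
            )
        k = int(n_components)
    else:
        if not 0 < variance <= 1:
            raise ConfigurationError(f"variance fraction {variance} outside (0, 1]")
        k = None

    fitted = PCA(n_components=rank_bound, svd_solver="full")
    fitted.fit(matrix)
    ratios = fitted.explained_variance_ratio_
    if k is None:
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, variance - 1e-12) + 1)
        k = min(k, rank_bound)
    reduction = PCAReduction(
        n_components=k,
        mean=fitted.mean_.copy(),
        components=fitted.components_[:k].T.copy(),
        explained_variance_ratio=ratios[:k].copy(),
    )
    return reduction, reduction.transform(matrix)


def stratified_split(
    labels: Sequence, ratio: float = 0.8, seed: int = 0
) -> SplitIndex:
    """Seeded per-class 80:20 (by default) partition of row indices.

    Each class ``c`` with ``m_c`` rows contributes ``floor(ratio * m_c)``
    rows (at least 1) to training; single-row classes go entirely to
    training with a logged warning.
    """
    if not 0 < ratio < 1:
        raise ConfigurationError(f"split ratio {ratio} outside (0, 1)")
    labels = np.asarray([str(c) for c in labels], dtype=object)
    m = labels.shape[0]
    if m < 2:
        raise InputError("need at least two rows to split")
    rng = np.random.default_rng(seed)
    train: list[np.ndarray] = []
    val: list[np.ndarray] = []
    for cls in sorted(set(labels)):
        rows = np.flatnonzero(labels == cls)
        rng.shuffle(rows)
        if rows.size == 1:
            logger.warning(
                "class %r has a single row; assigning it to training", cls
            )
            train.append(rows)
            continue
        n_train = max(1, int(np.floor(ratio * rows.size)))
        train.append(rows[:n_train])
        val.append(rows[n_train:])
    train_rows = np.sort(np.concatenate(train))
    val_rows = np.sort(np.concatenate(val)) if val else np.array([], dtype=int)
    return SplitIndex(train_rows, val_rows, seed)
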
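"""Reading labeled tabular data and writing grayscale image stacks.

A dataset is an ``m x n`` table of numeric and categorical cells plus a
length-``m`` label vector. Column kinds are inferred on ingestion: a column
is categorical iff at least one cell fails numeric parsing (overridable).
Image stacks are written as 8-bit single-channel PNGs, one file per table
row, together with a ``manifest.csv`` mapping file -> row -> label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ConfigurationError, ContractViolation, InputError, ParseError

__all__ = [
    "ColumnSchema",
    "TabularDataset",
    "ImageManifest",
    "read_csv_dataset",
    "write_image_stack",
    "read_image_stack",
    "quantize_to_bytes",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class ColumnSchema:
    """Schema of one feature column.

    ``categories`` is the sorted, duplicate-free list of category strings;
    it is empty for numeric columns.
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, CATEGORICAL):
            raise ConfigurationError(f"unknown column kind {self.kind!r}")
        if self.kind == NUMERIC and self.categories:
            raise ConfigurationError(
                f"numeric column {self.name!r} must not carry categories"
            )
        cats = tuple(self.categories)
        if list(cats) != sorted(set(cats)):
            raise ConfigurationError(
                f"categories of column {self.name!r} must be sorted and unique"
            )


@dataclass
class TabularDataset:
    """A labeled feature table.

    ``values`` keeps one column per :class:`ColumnSchema`: float64 for
    numeric columns, plain strings for categorical ones. ``labels`` are
    class identifiers as strings.
    """

    values: pd.DataFrame
    labels: np.ndarray
    schema: list[ColumnSchema]
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise InputError("dataset must have at least one row and one column")
        if len(self.labels) != m:
            raise InputError(
                f"label count {len(self.labels)} does not match row count {m}"
            )
        if n != len(self.schema):
            raise InputError("schema length does not match column count")
        for col in self.schema:
            if col.kind == CATEGORICAL:
                seen = set(self.values[col.name].astype(str))
                extra = seen - set(col.categories)
                if extra:
                    raise InputError(
                        f"column {col.name!r} holds values outside its "
                        f"categories: {sorted(extra)}"
                    )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(str(c) for c in self.labels))

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        """Feature table plus the label column, ready for CSV export."""
        df = self.values.copy()
        df[label_column] = [str(c) for c in self.labels]
        return df

    def write_csv(self, path: str | Path, label_column: str = "label") -> None:
        self.to_dataframe(label_column).to_csv(path, index=False)


@dataclass
class ImageManifest:
    """Index of a written image stack: one (file, row, label) per dataset row."""

    entries: list[tuple[str, int, str]]
    side: int
    bit_depth: int = 8

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["file", "row", "label"]).to_csv(
            path, index=False
        )


def _parses_numeric(cell: str) -> bool:
    try:
        float(cell)
        return True
    except (TypeError, ValueError):
        return False


def read_csv_dataset(
    path: str | Path,
    label_column: str,
    schema_override: Mapping[str, str] | None = None,
) -> TabularDataset:
    """Read a header-row CSV into a :class:`TabularDataset`.

    The label column is removed from the features. A feature column is
    inferred categorical iff any cell fails numeric parsing, unless
    ``schema_override`` pins its kind. Missing/empty cells are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty file") from exc
    if label_column not in df.columns:
        raise ConfigurationError(
            f"label column {label_column!r} not among headers {list(df.columns)}"
        )
    if df.shape[0] == 0:
        raise InputError(f"{path}: table has a header but no rows")

    for col in df.columns:
        series = df[col]
        bad = series.isna() | (series.astype(str).str.strip() == "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputError(
                f"{path}: missing value in column {col!r}, data row {row}"
            )

    labels = df[label_column].astype(str).to_numpy(dtype=object)
    features = df.drop(columns=[label_column])
    if features.shape[1] == 0:
        raise InputError(f"{path}: no feature columns besides the label")

    override = dict(schema_override or {})
    unknown = set(override) - set(features.columns)
    if unknown:
        raise ConfigurationError(f"schema override names unknown columns {sorted(unknown)}")

    schema: list[ColumnSchema] = []
    out = {}
    for col in features.columns:
        cells = features[col].astype(str)
        kind = override.get(col)
        if kind is None:
            kind = NUMERIC if cells.map(_parses_numeric).all() else CATEGORICAL
        elif kind not in (NUMERIC, CATEGORICAL):
            raise ConfigurationError(f"override for {col!r} must be numeric|categorical")
        if kind == NUMERIC:
            bad = ~cells.map(_parses_numeric)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise InputError(
                    f"{path}: column {col!r} forced numeric but cell at data "
                    f"row {row} ({cells.iloc[row]!r}) does not parse"
                )
            schema.append(ColumnSchema(col, NUMERIC))
            out[col] = cells.astype(float)
        else:
            cats = tuple(sorted(set(cells)))
            schema.append(ColumnSchema(col, CATEGORICAL, cats))
            out[col] = cells
    return TabularDataset(pd.DataFrame(out), labels, schema, name=path.stem)


def quantize_to_bytes(pixels: np.ndarray) -> np.ndarray:
    """Map real pixels in [0, 1] to uint8 with round-half-up at 255 scale."""
    arr = np.asarray(pixels, dtype=float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ContractViolation(
            f"pixel values outside [0, 1]: range [{arr.min()}, {arr.max()}]"
        )
    return np.floor(arr * 255.0 + 0.5).astype(np.uint8)


def write_image_stack(
    images: Sequence,
    labels: Iterable,
    out_dir: str | Path,
) -> ImageManifest:
    """Write one 8-bit grayscale PNG per image plus ``manifest.csv``.

    Each image may be a :class:`~nctd.transform.SyntheticImage` or a bare
    square matrix; files are named ``row{index:06d}.png`` by source row.
    Output is byte-identical for identical input.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}") from exc
    labels = [str(c) for c in labels]
    if len(labels) != len(images):
        raise InputError("one label per image is required")

    sides = set()
    entries: list[tuple[str, int, str]] = []
    for pos, img in enumerate(images):
        pixels = getattr(img, "pixels", img)
        index = getattr(img, "source_index", pos)
        arr = quantize_to_bytes(pixels)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ContractViolation(f"image {index} is not square: {arr.shape}")
        sides.add(arr.shape[0])
        fname = f"row{index:06d}.png"
        Image.fromarray(arr, mode="L").save(out_dir / fname)
        entries.append((fname, index, labels[pos]))
    if len(sides) > 1:
        raise ContractViolation(f"mixed image sides in one stack: {sorted(sides)}")
    manifest = ImageManifest(entries, side=sides.pop() if sides else 0)
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest


def read_image_stack(dir_path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a PNG stack written by :func:`write_image_stack`.

    Returns ``(images, labels)`` with images as an ``m x S x S`` float
    array in [0, 1] (bytes divided by 255), ordered as in the manifest.
    """
    dir_path = Path(dir_path)
    manifest = pd.read_csv(dir_path / "manifest.csv", dtype=str)
    stacks = []
    for fname in manifest["file"]:
        with Image.open(dir_path / fname) as im:
            stacks.append(np.asarray(im, dtype=float) / 255.0)
    return np.stack(stacks), manifest["label"].to_numpy(dtype=object)
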
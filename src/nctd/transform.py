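"""The tabular-to-image transform: duplication, progressive cyclic rotation
and quadrant tiling.

Each normalized row (length ``N``, values in [0, 1]) becomes a grayscale
pixel vector, is expanded into an ``N x N`` matrix — either by plain
duplication or by stacking progressively rotated copies, so that row ``i``
is the source vector cyclically shifted by ``i`` positions — and is
optionally tiled into all four quadrants of a ``2N x 2N`` image. Under
progressive rotation every feature visits every column exactly once, giving
the square a Latin-square structure: all row sums and all column sums equal
the source row's sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ContractViolation
from .preprocess import NormalizedMatrix

__all__ = [
    "GrayscaleRow",
    "TransformConfig",
    "SyntheticImage",
    "row_to_grayscale",
    "rotate_array",
    "build_square_image",
    "tile_quadrants",
    "transform_dataset",
]

MODES = ("duplicate", "rotate", "duplicate_rotate")
TILES = ("none", "quad")
DIRECTIONS = ("left", "right")


@dataclass(frozen=True)
class TransformConfig:
    """How a row becomes an image.

    mode
        ``duplicate`` copies the row across N matrix rows; ``rotate`` and
        ``duplicate_rotate`` stack the N progressive cyclic rotations.
    tile
        ``none`` keeps the ``N x N`` square; ``quad`` tiles it into a
        ``2N x 2N`` image (the default end-to-end configuration).
    direction
        Rotation direction; ``left`` means output position ``j`` holds
        input position ``(j + k) mod N``.
    """

    mode: str = "duplicate_rotate"
    tile: str = "quad"
    direction: str = "left"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.tile not in TILES:
            raise ConfigurationError(f"tile must be one of {TILES}, got {self.tile!r}")
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(
                f"direction must be one of {DIRECTIONS}, got {self.direction!r}"
            )


@dataclass(frozen=True)
class GrayscaleRow:
    """One sample as a length-N pixel vector in [0, 1]."""

    pixels: np.ndarray
    source_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pixels", np.asarray(self.pixels, dtype=float).ravel()
        )


@dataclass(frozen=True)
class SyntheticImage:
    """A square grayscale image (side N or 2N) built from one table row."""

    pixels: np.ndarray
    config: TransformConfig
    source_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ContractViolation(f"image must be square, got {self.pixels.shape}")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def row_to_grayscale(row: Sequence[float], index: int = 0) -> GrayscaleRow:
    """Identity mapping of a normalized row into pixels, order preserved."""
    pixels = np.asarray(row, dtype=float).ravel()
    if pixels.size == 0:
        raise ContractViolation("empty row")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ContractViolation(
            f"row {index}: values outside [0, 1] "
            f"(range [{pixels.min()}, {pixels.max()}])"
        )
    return GrayscaleRow(pixels, index)


def rotate_array(
    pixels: Sequence[float], k: int, direction: str = "left"
) -> np.ndarray:
    """Cyclically shift a vector by ``k`` positions.

    Left: output[j] = input[(j + k) mod N]; right: output[j] =
    input[(j - k) mod N]. ``k`` is reduced mod N, so k = 0 and k = N are
    both the identity.
    """
    if direction not in DIRECTIONS:
        raise ConfigurationError(f"direction must be one of {DIRECTIONS}")
    pixels = np.asarray(pixels)
    shift = -k if direction == "left" else k
    return np.roll(pixels, shift)


def build_square_image(row: GrayscaleRow, config: TransformConfig) -> SyntheticImage:
    """Expand a length-N pixel row into an ``N x N`` matrix."""
    src = row.pixels
    n = src.size
    if config.mode == "duplicate":
        square = np.tile(src, (n, 1))
    else:
        shifts = np.arange(n)[:, None]
        cols = np.arange(n)[None, :]
        if config.direction == "left":
            idx = (cols + shifts) % n
        else:
            idx = (cols - shifts) % n
        square = src[idx]
    return SyntheticImage(square, config, row.source_index)


def tile_quadrants(image: SyntheticImage) -> SyntheticImage:
    """Copy an ``N x N`` image into all four quadrants of a ``2N x 2N`` one."""
    return SyntheticImage(
        np.tile(image.pixels, (2, 2)), image.config, image.source_index
    )


def transform_dataset(
    matrix: NormalizedMatrix | np.ndarray,
    config: TransformConfig | None = None,
) -> list[SyntheticImage]:
    """Transform every row of a normalized matrix into one image.

    Rows are processed independently (no cross-row statistics); all output
    images share the same side (N, or 2N when ``tile='quad'``).
    """
    config = config or TransformConfig()
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else np.asarray(matrix)
    if values.ndim != 2:
        raise ContractViolation("expected an m x n matrix")
    images = []
    for i in range(values.shape[0]):
        try:
            row = row_to_grayscale(values[i], i)
        except ContractViolation as exc:
            raise ContractViolation(f"row {i}: {exc}") from exc
        img = build_square_image(row, config)
        if config.tile == "quad":
            img = tile_quadrants(img)
        images.append(img)
    return images
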
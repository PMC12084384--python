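"""Seeded generators for labeled tabular data with known structure.

Three families cover the pipeline's code paths:

* ``ringnorm``-style data: two multivariate normal classes with the
  canonical DELVE parameterization — class 0 ~ N(0, 4I), class 1 ~
  N((2/sqrt(d))·1, I) — a hard binary problem in which neither class
  separates by any single feature.
* ``gaussian_blobs``: K isotropic Gaussians at ``separation`` times the
  standard basis directions, a tunable-difficulty fixture.
* ``categorical_mix``: mixed numeric/categorical columns exercising the
  label-encoding branch of normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_tabular import CATEGORICAL, NUMERIC, ColumnSchema, TabularDataset

__all__ = [
    "GeneratorConfig",
    "generate_ringnorm_like",
    "generate_gaussian_blobs",
    "generate_categorical_mix",
    "generate",
]

FAMILIES = ("ringnorm", "gaussian_blobs", "categorical_mix")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic dataset."""

    n_samples: int
    n_features: int
    n_classes: int = 2
    seed: int = 0
    family: str = "gaussian_blobs"
    separation: float = 4.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family must be one of {FAMILIES}")
        if self.n_features < 1:
            raise ConfigurationError("need at least one feature")
        if self.n_samples < 2 * self.n_classes:
            raise ConfigurationError("need at least two samples per class")


def _numeric_dataset(x: np.ndarray, y: np.ndarray, name: str) -> TabularDataset:
    cols = [f"f{j:02d}" for j in range(x.shape[1])]
    schema = [ColumnSchema(c, NUMERIC) for c in cols]
    labels = np.array([str(int(c)) for c in y], dtype=object)
    return TabularDataset(pd.DataFrame(x, columns=cols), labels, schema, name=name)


def _balanced_labels(n: int, k: int) -> np.ndarray:
    """Class sizes differ by at most one; earlier classes take the remainder."""
    base, extra = divmod(n, k)
    return np.repeat(np.arange(k), [base + (i < extra) for i in range(k)])


def generate_ringnorm_like(n: int, d: int = 20, seed: int = 0) -> TabularDataset:
    """Two balanced multivariate-normal classes, DELVE ringnorm style.

    Class 0 has covariance ``4·I`` about the origin; class 1 has identity
    covariance about the constant mean vector ``(2/sqrt(d))·1``. Rows are
    shuffled by the seed.
    """
    rng = np.random.default_rng(seed)
    y = _balanced_labels(n, 2)
    n0 = int((y == 0).sum())
    x0 = rng.normal(0.0, 2.0, size=(n0, d))
    x1 = rng.normal(2.0 / np.sqrt(d), 1.0, size=(n - n0, d))
    x = np.vstack([x0, x1])
    order = rng.permutation(n)
    return _numeric_dataset(x[order], y[order], name="ringnorm")


def generate_gaussian_blobs(config: GeneratorConfig) -> TabularDataset:
    """K isotropic unit-noise Gaussians at separation·(basis directions).

    Class ``i < d`` sits at ``separation * e_i``; a (d+1)-th class, when
    requested, sits at the origin. More classes than d+1 cannot be placed
    orthogonally and raise a configuration error.
    """
    n, d, k = config.n_samples, config.n_features, config.n_classes
    if k > d + 1:
        raise ConfigurationError(
            f"{k} classes cannot be placed orthogonally in {d} dimensions "
            f"(at most {d + 1})"
        )
    rng = np.random.default_rng(config.seed)
    means = np.zeros((k, d))
    for i in range(min(k, d)):
        means[i, i] = config.separation
    y = _balanced_labels(n, k)
    x = rng.normal(0.0, 1.0, size=(n, d)) + means[y]
    order = rng.permutation(n)
    return _numeric_dataset(x[order], y[order], name="gaussian_blobs")


def generate_categorical_mix(
    n: int, d1: int, d2: int, seed: int = 0
) -> TabularDataset:
    """Mixed-kind table: d1 uniform[0, 100] numeric and d2 categorical
    columns (2-5 string categories each); the label thresholds the first
    numeric column (or the first categorical code when d1 = 0) so the
    pipeline has learnable signal.
    """
    if d1 + d2 < 1:
        raise ConfigurationError("need at least one column")
    if n < 2:
        raise ConfigurationError("need at least two rows")
    rng = np.random.default_rng(seed)
    frame = {}
    schema: list[ColumnSchema] = []
    numeric = rng.uniform(0.0, 100.0, size=(n, d1))
    for j in range(d1):
        name = f"num{j:02d}"
        frame[name] = numeric[:, j]
        schema.append(ColumnSchema(name, NUMERIC))
    cat_codes = np.zeros((n, max(d2, 1)), dtype=int)
    for j in range(d2):
        name = f"cat{j:02d}"
        n_cats = int(rng.integers(2, 6))
        cats = tuple(f"c{letter}" for letter in "abcde"[:n_cats])
        codes = rng.integers(0, n_cats, size=n)
        cat_codes[:, j] = codes
        frame[name] = pd.Series([cats[c] for c in codes])
        schema.append(ColumnSchema(name, CATEGORICAL, cats))
    if d1 > 0:
        y = (numeric[:, 0] > 50.0).astype(int)
    else:
        y = (cat_codes[:, 0] >= 1).astype(int)
    labels = np.array([str(c) for c in y], dtype=object)
    return TabularDataset(
        pd.DataFrame(frame), labels, schema, name="categorical_mix"
    )


def generate(config: GeneratorConfig) -> TabularDataset:
    """Dispatch on ``config.family``."""
    if config.family == "ringnorm":
        return generate_ringnorm_like(config.n_samples, config.n_features, config.seed)
    if config.family == "gaussian_blobs":
        return generate_gaussian_blobs(config)
    # mixed columns: split features roughly 2:1 numeric:categorical
    d2 = max(1, config.n_features // 3)
    return generate_categorical_mix(
        config.n_samples, config.n_features - d2, d2, config.seed
    )
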
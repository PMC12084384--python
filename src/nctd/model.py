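"""High-level modelling interface: an end-to-end tabular-image CNN model.

:class:`NCTDClassifier` bundles the full pipeline — categorical encoding,
min-max normalization, optional PCA, the row-to-image transform and the CNN
— behind a statsmodels-style surface: build the model from data, call
:meth:`NCTDClassifier.fit`, and read estimates and diagnostics off the
returned :class:`NCTDResults` (``summary()``, ``predict()``...).

All statistics (min/max, PCA axes) are fitted on the training rows of a
seeded stratified 80:20 split and applied unchanged to validation rows, so
the reported validation metrics are leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import io_tabular, preprocess, transform
from .errors import ConfigurationError, InputError

__all__ = ["NCTDClassifier", "NCTDResults"]


class NCTDClassifier:
    """CNN classifier over image-transformed tabular data.

    Parameters
    ----------
    data
        A :class:`~nctd.io_tabular.TabularDataset`.
    transform_config
        Row-to-image settings; defaults to progressive left rotation with
        quadrant tiling (a 2N x 2N image per row).
    pca_components, pca_variance
        Optional dimensionality reduction before imaging: a fixed component
        count, or the smallest count retaining the given variance fraction.
    split_ratio
        Training fraction of the stratified split (default 0.8).
    train_config
        Optimization settings; defaults to the published ones (Adam,
        learning rate 8e-4, batch size 64, 30 epochs).
    """

    def __init__(
        self,
        data: io_tabular.TabularDataset,
        *,
        transform_config: transform.TransformConfig | None = None,
        pca_components: int | None = None,
        pca_variance: float | None = None,
        split_ratio: float = 0.8,
        train_config: clf.TrainConfig | None = None,
        hidden_width: int = 64,
    ):
        if pca_components is not None and pca_variance is not None:
            raise ConfigurationError("give at most one of pca_components/pca_variance")
        self.data = data
        self.transform_config = transform_config or transform.TransformConfig()
        self.pca_components = pca_components
        self.pca_variance = pca_variance
        self.split_ratio = split_ratio
        self.train_config = train_config or clf.TrainConfig()
        self.hidden_width = hidden_width

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "label", name: str = "", **kwargs
    ) -> "NCTDClassifier":
        """Build from a pandas DataFrame holding features plus a label column."""
        if label_column not in df.columns:
            raise ConfigurationError(f"label column {label_column!r} not in frame")
        import tempfile

        # Route through the CSV reader so schema inference matches file input.
        with tempfile.NamedTemporaryFile(
            "w", suffix=".csv", delete=False
        ) as handle:
            df.to_csv(handle, index=False)
            path = handle.name
        try:
            data = io_tabular.read_csv_dataset(path, label_column)
        finally:
            Path(path).unlink(missing_ok=True)
        if name:
            data.name = name
        return cls(data, **kwargs)

    @classmethod
    def from_csv(
        cls, path: str | Path, label_column: str = "label", **kwargs
    ) -> "NCTDClassifier":
        return cls(io_tabular.read_csv_dataset(path, label_column), **kwargs)

    def prepare_images(
        self, split: preprocess.SplitIndex | None = None
    ) -> tuple[list[transform.SyntheticImage], dict]:
        """Run encode -> normalize -> (PCA) -> image transform for all rows.

        Statistics are fitted on ``split.train_rows`` when a split is given,
        else on all rows. Returns the images plus the fitted state needed to
        transform new data identically.
        """
        train_rows = split.train_rows if split is not None else None
        encoded = preprocess.encode_dataset(self.data)
        fit_on = encoded if train_rows is None else encoded[train_rows]
        minima, maxima = preprocess.fit_minmax(fit_on)
        normalized = preprocess.apply_minmax(encoded, minima, maxima, self.data.schema)
        state: dict = {"minima": minima, "maxima": maxima, "pca": None}

        values = normalized.values
        if self.pca_components is not None or self.pca_variance is not None:
            fit_vals = values if train_rows is None else values[train_rows]
            reduction, _ = preprocess.pca_reduce(
                fit_vals,
                n_components=self.pca_components,
                variance=self.pca_variance,
            )
            scores = reduction.transform(values)
            # PCA scores leave [0, 1]; re-normalize on the same training rows
            fit_scores = scores if train_rows is None else scores[train_rows]
            pmin, pmax = preprocess.fit_minmax(fit_scores)
            values = preprocess.apply_minmax(scores, pmin, pmax).values
            state["pca"] = reduction
            state["pca_minima"], state["pca_maxima"] = pmin, pmax

        images = transform.transform_dataset(values, self.transform_config)
        return images, state

    def fit(self, seed: int | None = None) -> "NCTDResults":
        """Split, transform, train, and evaluate at the best epoch."""
        config = self.train_config
        if seed is not None:
            config = clf.TrainConfig(
                learning_rate=config.learning_rate,
                batch_size=config.batch_size,
                optimizer=config.optimizer,
                loss=config.loss,
                epochs=config.epochs,
                seed=seed,
            )
        split = preprocess.stratified_split(
            self.data.labels, ratio=self.split_ratio, seed=config.seed
        )
        images, state = self.prepare_images(split)
        side = images[0].side
        spec = clf.build_architecture(
            side, len(self.data.classes), hidden_width=self.hidden_width
        )
        network, report = clf.train(
            images, self.data.labels, split, spec, config
        )
        return NCTDResults(self, spec, network, report, split, state, config)


@dataclass
class NCTDResults:
    """Fit results: the trained network, the split, and best-epoch metrics."""

    model: NCTDClassifier
    spec: clf.CNNSpec
    network: object
    report: clf.EvalReport
    split: preprocess.SplitIndex
    state: dict
    train_config: clf.TrainConfig

    def _transform_new(self, data: io_tabular.TabularDataset) -> np.ndarray:
        """Apply the fitted preprocessing to new rows, returning image stack."""
        if [c.name for c in data.schema] != [c.name for c in self.model.data.schema]:
            raise InputError("new data columns do not match the fitted schema")
        merged_schema = self.model.data.schema
        cols = []
        for col in merged_schema:
            raw = data.values[col.name]
            if col.kind == io_tabular.NUMERIC:
                cols.append(raw.to_numpy(dtype=float))
            else:
                cols.append(
                    preprocess.encode_categorical(raw.tolist(), col).astype(float)
                )
        encoded = np.column_stack(cols)
        values = preprocess.apply_minmax(
            encoded, self.state["minima"], self.state["maxima"]
        ).values
        if self.state["pca"] is not None:
            scores = self.state["pca"].transform(values)
            values = preprocess.apply_minmax(
                scores, self.state["pca_minima"], self.state["pca_maxima"]
            ).values
        images = transform.transform_dataset(values, self.model.transform_config)
        return np.stack([img.pixels for img in images])[:, None].astype(np.float32)

    def predict_proba(self, data: io_tabular.TabularDataset) -> np.ndarray:
        return self.network.predict_proba(self._transform_new(data))

    def predict(self, data: io_tabular.TabularDataset) -> np.ndarray:
        probs = self.predict_proba(data)
        classes = self.report.class_labels
        return np.array([classes[i] for i in probs.argmax(axis=1)], dtype=object)

    def save(self, path: str | Path) -> None:
        clf.save_checkpoint(path, self.network, self.spec, self.report.class_labels)

    def summary(self) -> str:
        """Plain-text fit summary in the statsmodels style."""
        r = self.report
        m = self.model
        lines = [
            "          Tabular-to-Image CNN Classification Results",
            "=" * 62,
            f"{'Dataset:':<22}{m.data.name or '<unnamed>':<18}"
            f"{'No. samples:':<16}{m.data.n_rows}",
            f"{'No. features:':<22}{m.data.n_features:<18}"
            f"{'No. classes:':<16}{len(r.class_labels)}",
            f"{'Image side:':<22}{self.spec.input_side:<18}"
            f"{'Feature maps:':<16}"
            + "->".join(str(s) for s in self.spec.feature_map_sides),
            f"{'Transform:':<22}{m.transform_config.mode} / tile="
            f"{m.transform_config.tile} / {m.transform_config.direction}",
            f"{'Optimizer:':<22}{'Adam':<18}{'Learning rate:':<16}"
            f"{self.train_config.learning_rate}",
            f"{'Batch size:':<22}{self.train_config.batch_size:<18}"
            f"{'Epochs:':<16}{self.train_config.epochs}",
            f"{'Train rows:':<22}{len(self.split.train_rows):<18}"
            f"{'Val. rows:':<16}{len(self.split.val_rows)}",
            "-" * 62,
            f"{'Best epoch:':<22}{r.best_epoch:<18}{'Val. accuracy:':<16}"
            f"{r.accuracy:.4f}",
            f"{'Macro precision:':<22}{r.macro_precision:<18.4f}"
            f"{'Macro recall:':<16}{r.macro_recall:.4f}",
            f"{'Macro F1:':<22}{r.macro_f1:<18.4f}",
            "=" * 62,
        ]
        return "\n".join(lines)
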
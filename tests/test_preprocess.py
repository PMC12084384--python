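"""Encoding, min-max normalization, PCA and the stratified split."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nctd.errors import ConfigurationError, InputError
from nctd.io_tabular import ColumnSchema
from nctd.preprocess import (
    apply_minmax,
    encode_categorical,
    fit_minmax,
    pca_reduce,
    stratified_split,
)

CAT_AB = ColumnSchema("c", "categorical", ("a", "b"))


class TestEncodeCategorical:
    @pytest.mark.parametrize(
        "values,categories,expected",
        [
            (["b", "a", "b"], ("a", "b"), [1, 0, 1]),
            (["x", "x"], ("x",), [0, 0]),
            (["M", "F", "F", "M"], ("F", "M"), [1, 0, 0, 1]),
        ],
    )
    def test_lexicographic_codes(self, values, categories, expected):
        schema = ColumnSchema("c", "categorical", categories)
        assert encode_categorical(values, schema).tolist() == expected

    def test_unseen_category_named_in_error(self):
        with pytest.raises(InputError, match="'z'"):
            encode_categorical(["a", "z"], CAT_AB)


class TestMinMax:
    def test_fit_examples(self):
        mins, maxs = fit_minmax(np.array([[0.0, 10.0], [1.0, 20.0], [0.5, 15.0]]))
        assert mins.tolist() == [0.0, 10.0]
        assert maxs.tolist() == [1.0, 20.0]

    def test_apply_basic_and_constant_and_clip(self):
        mins, maxs = np.array([2.0]), np.array([6.0])
        out = apply_minmax(np.array([[2.0], [4.0], [6.0]]), mins, maxs)
        assert out.values.ravel().tolist() == [0.0, 0.5, 1.0]
        const = apply_minmax(np.array([[5.0], [5.0]]), np.array([5.0]), np.array([5.0]))
        assert const.values.ravel().tolist() == [0.0, 0.0]
        clipped = apply_minmax(np.array([[8.0], [1.0]]), mins, maxs)
        assert clipped.values.ravel().tolist() == [1.0, 0.0]

    def test_non_finite_rejected(self):
        with pytest.raises(InputError, match="non-finite"):
            fit_minmax(np.array([[1.0], [np.nan]]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=20,
        )
    )
    def test_idempotent_on_nonconstant_columns(self, column):
        col = np.asarray(column)[:, None]
        mins, maxs = fit_minmax(col)
        once = apply_minmax(col, mins, maxs).values
        m2, x2 = fit_minmax(once)
        twice = apply_minmax(once, m2, x2).values
        assert np.allclose(once, twice, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=2,
            max_size=20,
        # spread must survive the affine map in floating point
        ).filter(lambda xs: max(xs) - min(xs) > 1e-2)
    )
    def test_affine_invariance(self, column):
        col = np.asarray(column)[:, None]
        scaled = 3.0 * col + 7.0
        a = apply_minmax(col, *fit_minmax(col)).values
        b = apply_minmax(scaled, *fit_minmax(scaled)).values
        assert np.allclose(a, b, atol=1e-8)


class TestPCA:
    def test_collinear_data_needs_one_component(self):
        x = np.linspace(0, 1, 10)[:, None] * np.array([1.0, 2.0])
        reduction, scores = pca_reduce(x, variance=0.95)
        assert reduction.n_components == 1
        assert reduction.explained_variance_ratio[0] == pytest.approx(1.0)
        assert scores.shape == (10, 1)

    def test_full_rank_projection_preserves_total_variance(self, rng):
        x = rng.normal(size=(30, 4))
        reduction, scores = pca_reduce(x, n_components=4)
        assert np.allclose(scores.var(axis=0, ddof=1).sum(),
                           x.var(axis=0, ddof=1).sum())
        # orthonormal loadings
        assert np.allclose(
            reduction.components.T @ reduction.components, np.eye(4), atol=1e-10
        )

    def test_ratios_match_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(50, 3)) @ np.diag([3.0, 1.0, 0.2])
        cov = np.cov(x, rowvar=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eigvals / eigvals.sum()
        reduction, _ = pca_reduce(x, n_components=3)
        assert np.allclose(reduction.explained_variance_ratio, expected, atol=1e-10)

    def test_full_variance_reconstructs_centered_matrix(self, rng):
        x = rng.normal(size=(20, 5))
        reduction, scores = pca_reduce(x, variance=1.0)
        recon = scores @ reduction.components.T + reduction.mean
        assert np.allclose(recon, x, atol=1e-8)

    def test_component_count_beyond_rank_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            pca_reduce(rng.normal(size=(5, 10)), n_components=5)


class TestStratifiedSplit:
    def test_exact_divisibility(self):
        labels = ["a"] * 5 + ["b"] * 5
        split = stratified_split(labels, 0.8, seed=3)
        assert len(split.train_rows) == 8
        assert len(split.val_rows) == 2
        train_labels = [labels[i] for i in split.train_rows]
        assert train_labels.count("a") == 4 and train_labels.count("b") == 4

    def test_single_row_class_goes_to_training(self, caplog):
        labels = ["a"] * 6 + ["b"]
        with caplog.at_level(logging.WARNING, logger="nctd.preprocess"):
            split = stratified_split(labels, 0.8, seed=0)
        assert 6 in split.train_rows
        assert any("single row" in r.message for r in caplog.records)

    def test_deterministic_and_covering(self):
        labels = list("aabbbccccc") * 3
        s1 = stratified_split(labels, 0.8, seed=9)
        s2 = stratified_split(labels, 0.8, seed=9)
        assert s1.train_rows.tolist() == s2.train_rows.tolist()
        assert s1.val_rows.tolist() == s2.val_rows.tolist()
        union = sorted(set(s1.train_rows) | set(s1.val_rows))
        assert union == list(range(len(labels)))

    def test_per_class_proportions_within_one_row(self):
        labels = ["a"] * 13 + ["b"] * 27 + ["c"] * 7
        split = stratified_split(labels, 0.8, seed=5)
        for cls, m_c in (("a", 13), ("b", 27), ("c", 7)):
            got = sum(1 for i in split.train_rows if labels[i] == cls)
            assert abs(got - 0.8 * m_c) <= 1

    def test_bad_ratio_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_split(["a", "b"], ratio=1.5)
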
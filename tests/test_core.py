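"""Domain types, embedding normalization and the evaluation metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from embedmap.core import (
    DegenerateInputError,
    Embedding,
    FeatureMatrix,
    PixelGeometry,
    embedding_r2,
    normalize_embedding,
    rand_index,
)


class TestFeatureMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureMatrix(np.ones((2, 2)), [1.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError, match="increasing"):
            FeatureMatrix(np.ones((1, 2)), [2.0, 1.0], ["a"])
        with pytest.raises(ValueError, match="nonnegative"):
            FeatureMatrix(np.array([[-1.0, 0.0]]), [1.0, 2.0], ["a"])
        with pytest.raises(ValueError, match="length"):
            FeatureMatrix(np.ones((2, 2)), [1.0, 2.0, 3.0], ["a", "b"])

    def test_subset_preserves_axis_and_labels(self):
        fm = FeatureMatrix(
            np.arange(6.0).reshape(3, 2), [1.0, 2.0], ["a", "b", "c"],
            group_labels=["x", "y", "z"],
        )
        sub = fm.subset([2, 0])
        assert sub.sample_ids == ["c", "a"]
        assert sub.group_labels == ["z", "x"]
        np.testing.assert_array_equal(sub.feature_axis, fm.feature_axis)


class TestPixelGeometry:
    def test_rejects_out_of_range_and_duplicates(self):
        with pytest.raises(ValueError, match="outside"):
            PixelGeometry(positions=[[0, 0], [2, 0]], image_shape=(1, 2))
        with pytest.raises(ValueError, match="unique"):
            PixelGeometry(positions=[[0, 0], [0, 0]], image_shape=(2, 2))


class TestNormalizeEmbedding:
    @pytest.mark.parametrize(
        "coords,expected",
        [
            ([[0.0, 0.0], [1.0, 1.0]], [[0.0, 0.0], [1.0, 1.0]]),  # unit range
            ([[-2.0], [0.0], [2.0]], [[0.0], [0.5], [1.0]]),  # affine min-max
            ([[5.0], [5.0], [5.0]], [[0.0], [0.0], [0.0]]),  # degenerate dim
        ],
    )
    def test_examples(self, coords, expected):
        e = normalize_embedding(Embedding(coords=np.array(coords), method="tsne"))
        np.testing.assert_allclose(e.coords, expected)
        assert e.normalized

    def test_invertible_for_nondegenerate_dims(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(20, 3)) * [3.0, 0.5, 10.0] + [1.0, -4.0, 0.0]
        e = normalize_embedding(Embedding(coords=raw, method="tsne"))
        back = e.coords * e.norm_ranges + e.norm_mins
        np.testing.assert_allclose(back, raw, atol=1e-12)

    @given(
        st.integers(1, 30),
        st.integers(1, 3),
        st.integers(0, 10_000),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_idempotent(self, n, d, seed):
        coords = np.random.default_rng(seed).normal(size=(n, d)) * 7 - 3
        once = normalize_embedding(Embedding(coords=coords, method="tsne"))
        twice = normalize_embedding(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-14)


def _pearson_r2_oracle(x, y):
    """Textbook Pearson correlation, written independently with loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return (num / (dx * dy)) ** 2


class TestEmbeddingR2:
    def test_identity_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(25, 3))
        r2, r2min = embedding_r2(a, a)
        np.testing.assert_allclose(r2, 1.0)
        r2, r2min = embedding_r2(a, 2.0 * a + 7.0)
        np.testing.assert_allclose(r2, 1.0)
        assert r2min == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        a = np.array([[1.0], [2.0], [3.0], [4.0]])
        b = np.array([[1.0], [2.0], [3.0], [5.0]])
        r2, _ = embedding_r2(a, b)
        assert r2[0] == pytest.approx(_pearson_r2_oracle(a[:, 0], b[:, 0]), abs=1e-12)

    def test_random_matrices_match_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(50, 3))
        b = a * 0.5 + rng.normal(size=(50, 3))
        r2, r2min = embedding_r2(a, b)
        expected = [_pearson_r2_oracle(a[:, j], b[:, j]) for j in range(3)]
        np.testing.assert_allclose(r2, expected, atol=1e-12)
        assert r2min == pytest.approx(min(expected), abs=1e-12)

    def test_zero_variance_dimension_raises(self):
        a = np.zeros((5, 2))
        a[:, 1] = np.arange(5)
        b = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(DegenerateInputError):
            embedding_r2(a, b)


def _rand_index_oracle(a, b):
    """Brute-force pair enumeration."""
    n = len(a)
    agree = 0
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += 1
        if (a[i] == a[j]) == (b[i] == b[j]):
            agree += 1
    return agree / total


def _set_partitions(n):
    """All partitions of range(n) as canonical label vectors."""
    if n == 1:
        yield [0]
        return
    for rest in _set_partitions(n - 1):
        k = max(rest) + 1
        for c in range(k + 1):
            yield rest + [c]


class TestRandIndex:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([0, 0, 1, 1], [0, 0, 1, 1], 1.0),
            ([0, 0, 1, 1], [0, 1, 0, 1], 2 / 6),
            ([0, 1], [0, 0], 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert rand_index(a, b) == pytest.approx(expected)

    def test_symmetric_and_relabel_invariant(self):
        a = [0, 0, 1, 2, 2, 1]
        b = [1, 1, 0, 0, 2, 2]
        assert rand_index(a, b) == pytest.approx(rand_index(b, a))
        relabeled = ["x" if v == 0 else ("y" if v == 1 else "z") for v in a]
        assert rand_index(relabeled, b) == pytest.approx(rand_index(a, b))

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_all_partitions_match_pair_enumeration(self, n):
        parts = list(_set_partitions(n))
        rng = np.random.default_rng(n)
        # all pairs for small n; a seeded sample of pairs for n >= 5
        pairs = (
            list(itertools.product(parts, parts))
            if len(parts) ** 2 <= 4000
            else [
                (parts[i], parts[j])
                for i, j in rng.integers(0, len(parts), size=(600, 2))
            ]
        )
        for a, b in pairs:
            assert rand_index(a, b) == pytest.approx(_rand_index_oracle(a, b))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rand_index([0, 1], [0, 1, 2])
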
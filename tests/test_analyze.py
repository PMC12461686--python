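"""Rendering, box segmentation and leave-one-out LDA."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from embedmap.analyze import BoxRegion, box_mask, lda_loo, rgb_render
from embedmap.core import Embedding, PixelGeometry


def _emb(coords):
    return Embedding(coords=np.asarray(coords, float), method="network",
                     normalized=True)


class TestRgbRender:
    def test_channel_mapping_pure_red(self):
        e = _emb([[1.0, 0.0, 0.0]])
        geom = PixelGeometry(positions=[[0, 0]], image_shape=(1, 1))
        img = rgb_render(e, geom)
        np.testing.assert_allclose(img[0, 0], [1.0, 0.0, 0.0])

    def test_channels_recover_coordinates_exactly(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(size=(12, 3))
        pos = [[i % 4, i // 4] for i in range(12)]
        geom = PixelGeometry(positions=pos, image_shape=(3, 4))
        img = rgb_render(_emb(coords), geom)
        for i, (x, y) in enumerate(pos):
            np.testing.assert_array_equal(img[y, x], coords[i])

    def test_same_coordinates_same_color_across_sections(self):
        coords = np.array([[0.2, 0.7, 0.4]])
        g1 = PixelGeometry(positions=[[0, 0]], image_shape=(1, 1))
        g2 = PixelGeometry(positions=[[4, 2]], image_shape=(5, 5))
        c1 = rgb_render(_emb(coords), g1)[0, 0]
        c2 = rgb_render(_emb(coords), g2)[2, 4]
        np.testing.assert_array_equal(c1, c2)

    def test_empty_cells_black(self):
        e = _emb([[1.0, 1.0, 1.0]])
        geom = PixelGeometry(positions=[[1, 1]], image_shape=(2, 2))
        img = rgb_render(e, geom)
        assert img[0, 0].sum() == 0.0

    def test_2d_color_square_corners(self):
        e = _emb([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        geom = PixelGeometry(positions=[[0, 0], [1, 0], [0, 1], [1, 1]],
                             image_shape=(2, 2))
        img = rgb_render(e, geom)
        np.testing.assert_allclose(img[0, 0], [0, 0, 1])  # blue
        np.testing.assert_allclose(img[0, 1], [1, 0, 0])  # red
        np.testing.assert_allclose(img[1, 0], [0, 1, 0])  # green
        np.testing.assert_allclose(img[1, 1], [1, 1, 0])  # yellow

    def test_requires_normalized(self):
        e = Embedding(coords=np.zeros((1, 3)), method="tsne")
        geom = PixelGeometry(positions=[[0, 0]], image_shape=(1, 1))
        with pytest.raises(ValueError, match="normalized"):
            rgb_render(e, geom)


class TestBoxMask:
    def test_full_box_all_true(self):
        e = _emb(np.random.default_rng(0).uniform(size=(20, 3)))
        mask = box_mask(e, BoxRegion(bounds=[[0, 1]] * 3))
        assert mask.all()

    def test_degenerate_box_hits_exact_point(self):
        e = _emb([[0.2, 0.4], [0.6, 0.8]])
        region = BoxRegion(bounds=[[0.2, 0.2], [0.4, 0.4]])
        np.testing.assert_array_equal(box_mask(e, region), [True, False])

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        e = _emb(rng.uniform(size=(50, 3)))
        for _ in range(10):
            lo = rng.uniform(0, 0.6, 3)
            hi = lo + rng.uniform(0, 0.4, 3)
            region = BoxRegion(bounds=np.column_stack([lo, hi]))
            mask = box_mask(e, region)
            brute = [
                all(lo[j] <= e.coords[i, j] <= hi[j] for j in range(3))
                for i in range(50)
            ]
            np.testing.assert_array_equal(mask, brute)

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            BoxRegion(bounds=[[1.0, 0.0]])


class TestLdaLoo:
    def test_separable_classes_perfect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 2)) * 0.1
        b = rng.normal(size=(20, 2)) * 0.1 + 10.0
        coords = np.vstack([a, b])
        labels = np.array([0] * 20 + [1] * 20)
        acc, confusion = lda_loo(coords, labels)
        assert acc == 1.0
        assert confusion.loc[0, 0] == 20 and confusion.loc[1, 1] == 20

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(200, 3))
        labels = np.array([0, 1] * 100)
        acc, _ = lda_loo(coords, labels)
        # binomial(200, 0.5) 99% bounds on the accuracy
        assert 0.5 - 2.58 * 0.5 / np.sqrt(200) < acc < 0.5 + 2.58 * 0.5 / np.sqrt(200)

    def test_matches_sklearn_lda_oracle(self):
        # small hand dataset, well-conditioned: closed-form LDA should agree
        coords = np.array(
            [[0.0, 0.1], [0.2, -0.1], [0.1, 0.05], [2.0, 1.9], [2.2, 2.1],
             [1.9, 2.0], [0.1, 2.0], [-0.1, 2.2], [0.0, 1.9]]
        )
        labels = np.array(["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        acc, _ = lda_loo(coords, labels)
        hits = 0
        for i in range(len(labels)):
            keep = np.arange(len(labels)) != i
            clf = LinearDiscriminantAnalysis(solver="svd")
            clf.fit(coords[keep], labels[keep])
            hits += clf.predict(coords[i : i + 1])[0] == labels[i]
        assert acc == pytest.approx(hits / len(labels))

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(30, 2))
        labels = np.array([0, 1, 2] * 10)
        a1, _ = lda_loo(coords, labels)
        a2, _ = lda_loo(coords, labels)
        assert a1 == a2

    def test_preconditions(self):
        with pytest.raises(ValueError, match="2 classes"):
            lda_loo(np.zeros((4, 2)), [0, 0, 0, 0])
        with pytest.raises(ValueError, match="2 members"):
            lda_loo(np.zeros((3, 2)), [0, 0, 1])
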
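"""Rendering, embedding-space segmentation and reduced-space classification.

A 3-D normalized embedding renders directly as an RGB image (coordinates are
the color channels, so identical coordinates always mean identical colors
across sections); 2-D embeddings use a four-corner color-square convention
(blue/red/green/yellow at the corners). Segmentation is by axis-aligned
bounding boxes in embedding space; classification on reduced coordinates is
leave-one-out linear discriminant analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Embedding, PixelGeometry

__all__ = ["BoxRegion", "rgb_render", "box_mask", "lda_loo"]


@dataclass
class BoxRegion:
    """Axis-aligned box in normalized embedding units: bounds[(d, 2)]."""

    bounds: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.ndim != 2 or self.bounds.shape[1] != 2:
            raise ValueError("bounds must be (d, 2) [lo, hi] rows")
        if np.any(self.bounds[:, 0] > self.bounds[:, 1]):
            raise ValueError("each lo must be <= hi")


def _corner_square_colors(coords: np.ndarray) -> np.ndarray:
    """Bilinear blend of corner colors blue/red/green/yellow for 2-D coords."""
    u = coords[:, 0][:, None]
    v = coords[:, 1][:, None]
    blue = np.array([0.0, 0.0, 1.0])
    red = np.array([1.0, 0.0, 0.0])
    green = np.array([0.0, 1.0, 0.0])
    yellow = np.array([1.0, 1.0, 0.0])
    return (1 - u) * (1 - v) * blue + u * (1 - v) * red + (1 - u) * v * green + u * v * yellow


def rgb_render(e: Embedding, geometry: PixelGeometry) -> np.ndarray:
    """Paint embedding coordinates as pixel colors; empty cells are black.

    For d=3 the channels are the coordinates themselves (reading a sample's
    pixel recovers its coordinates exactly); for d=2 the color-square
    convention applies.
    """
    if not e.normalized:
        raise ValueError("embedding must be normalized to [0,1] for rendering")
    if geometry.n != e.n:
        raise ValueError("geometry and embedding sample counts differ")
    if e.d == 3:
        colors = e.coords
    elif e.d == 2:
        colors = _corner_square_colors(e.coords)
    else:
        raise ValueError("rendering requires a 2-D or 3-D embedding")
    h, w = geometry.image_shape[-2], geometry.image_shape[-1]
    img = np.zeros((h, w, 3))
    img[geometry.positions[:, 1], geometry.positions[:, 0]] = colors
    return img


def box_mask(e: Embedding, region: BoxRegion) -> np.ndarray:
    """Boolean mask of samples inside the closed box."""
    if region.bounds.shape[0] != e.d:
        raise ValueError("region dimensionality must match embedding")
    lo = region.bounds[:, 0]
    hi = region.bounds[:, 1]
    return np.all((e.coords >= lo) & (e.coords <= hi), axis=1)


def _lda_fit(x: np.ndarray, y: np.ndarray, classes: np.ndarray):
    """Closed-form Gaussian LDA: class means, ridged pooled covariance,
    empirical priors."""
    d = x.shape[1]
    means = np.vstack([x[y == c].mean(axis=0) for c in classes])
    pooled = np.zeros((d, d))
    for c, mu in zip(classes, means):
        xc = x[y == c] - mu
        pooled += xc.T @ xc
    pooled /= max(len(x) - len(classes), 1)
    eps = 1e-6 * np.trace(pooled) / d
    pooled += np.eye(d) * max(eps, 1e-12)
    w = np.linalg.solve(pooled, means.T)  # (d, K)
    priors = np.array([(y == c).sum() for c in classes], dtype=float) / len(y)
    b = -0.5 * np.einsum("kd,dk->k", means, w) + np.log(priors)
    return w, b


def lda_loo(coords: np.ndarray, labels) -> tuple[float, pd.DataFrame]:
    """Leave-one-out LDA accuracy on reduced coordinates, with confusion.

    Within-class covariance is regularized by ``eps * I`` with
    ``eps = 1e-6 * trace / d``; priors are proportional to class frequency.
    Deterministic given the input (argmax ties resolve to the first class in
    sorted label order).
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 members")
    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    idx_all = np.arange(n)
    for i in range(n):
        keep = idx_all != i
        w, b = _lda_fit(x[keep], y[keep], classes)
        scores = x[i] @ w + b
        pred[i] = classes[int(np.argmax(scores))]
    acc = float((pred == y).mean())
    confusion = pd.DataFrame(
        0, index=pd.Index(classes, name="true"), columns=pd.Index(classes, name="predicted")
    )
    for t, p in zip(y, pred):
        confusion.loc[t, p] += 1
    return acc, confusion
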
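"""Shared domain types and evaluation metrics.

The containers here are deliberately thin: a :class:`FeatureMatrix` is an
``n x p`` nonnegative intensity matrix with a feature axis (m/z values in Da,
or genomic bin starts in bp) and unique sample identifiers; an
:class:`Embedding` is the ``n x d`` output of a nonlinear reduction together
with enough provenance (method, parameters, normalization constants) to apply
downstream maps consistently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import rand_score

__all__ = [
    "DegenerateInputError",
    "FeatureMatrix",
    "Embedding",
    "PixelGeometry",
    "PseudoSpectrum",
    "normalize_embedding",
    "embedding_r2",
    "rand_index",
]


class DegenerateInputError(ValueError):
    """Raised when an input has no variance where variance is required."""


@dataclass
class FeatureMatrix:
    """Samples-by-features intensity matrix with a feature axis.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Nonnegative intensities (arbitrary units).
    feature_axis : ndarray of shape (p,)
        m/z values in Da (strictly increasing) or genomic bin start
        coordinates in bp (non-decreasing), depending on ``axis_kind``.
    sample_ids : sequence of str
        Unique identifier per sample (pixel, locus, cell pellet, ...).
    group_labels : sequence of str, optional
        Categorical label per sample (region, genotype, class, ...).
    axis_kind : {"mz", "bins"}
        Interpretation of the feature axis. Only ``"mz"`` enforces strict
        monotonicity.
    """

    values: np.ndarray
    feature_axis: np.ndarray
    sample_ids: Sequence[str]
    group_labels: Sequence[str] | None = None
    axis_kind: str = "mz"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_axis = np.asarray(self.feature_axis, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        # (0, 0) is permitted only as the explicit empty result of binning ops
        if self.values.size == 0 and (n, p) != (0, 0):
            raise ValueError("empty FeatureMatrix must have shape (0, 0)")
        if self.values.size and (n < 1 or p < 1):
            raise ValueError("FeatureMatrix requires n >= 1 and p >= 1")
        if self.feature_axis.shape != (p,):
            raise ValueError("feature_axis length must equal number of features")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal number of samples")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.axis_kind not in ("mz", "bins"):
            raise ValueError("axis_kind must be 'mz' or 'bins'")
        if self.axis_kind == "mz" and p > 1 and not np.all(np.diff(self.feature_axis) > 0):
            raise ValueError("m/z feature axis must be strictly increasing")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.values.size and self.values.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if self.group_labels is not None:
            self.group_labels = list(self.group_labels)
            if len(self.group_labels) != n:
                raise ValueError("group_labels length must equal number of samples")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        """Row subset preserving the feature axis."""
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            values=self.values[indices],
            feature_axis=self.feature_axis,
            sample_ids=[self.sample_ids[i] for i in indices],
            group_labels=None
            if self.group_labels is None
            else [self.group_labels[i] for i in indices],
            axis_kind=self.axis_kind,
        )


@dataclass
class Embedding:
    """Low-dimensional coordinates with provenance.

    ``norm_mins``/``norm_ranges`` are populated by
    :func:`normalize_embedding` so the unit-cube transform is invertible for
    non-degenerate dimensions.
    """

    coords: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    normalized: bool = False
    norm_mins: np.ndarray | None = None
    norm_ranges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] < 1:
            raise ValueError("coords must be a 2-D array with >= 1 row")
        if self.normalized and (
            self.coords.min() < -1e-12 or self.coords.max() > 1 + 1e-12
        ):
            raise ValueError("normalized embedding coordinates must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices: np.ndarray) -> "Embedding":
        return dataclasses.replace(self, coords=self.coords[np.asarray(indices, int)])


@dataclass
class PixelGeometry:
    """Raster positions for image-shaped data.

    ``positions[i]`` is the (x, y) or (x, y, z) pixel of sample ``i``;
    ``image_shape`` is (n_rows, n_cols) i.e. (y extent, x extent), with an
    optional leading z extent for 3-D stacks.
    """

    positions: np.ndarray
    image_shape: tuple

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be (n, 2) or (n, 3)")
        self.image_shape = tuple(int(s) for s in self.image_shape)
        xy = self.positions[:, :2]
        h, w = self.image_shape[-2], self.image_shape[-1]
        if xy.size and (
            xy[:, 0].min() < 0
            or xy[:, 1].min() < 0
            or xy[:, 0].max() >= w
            or xy[:, 1].max() >= h
        ):
            raise ValueError("positions fall outside image_shape")
        seen = {tuple(r) for r in self.positions}
        if len(seen) != len(self.positions):
            raise ValueError("positions must be unique per sample")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class PseudoSpectrum:
    """Signed per-feature contributions returned by an inverse query.

    Contributions may be negative: they are relative contributions at a point
    of embedding space, not measured intensities.
    """

    feature_axis: np.ndarray
    contributions: np.ndarray
    query_point: np.ndarray

    def __post_init__(self) -> None:
        self.feature_axis = np.asarray(self.feature_axis, dtype=float)
        self.contributions = np.asarray(self.contributions, dtype=float)
        self.query_point = np.asarray(self.query_point, dtype=float)
        if self.feature_axis.shape != self.contributions.shape:
            raise ValueError("feature_axis and contributions must have equal length")


def normalize_embedding(e: Embedding) -> Embedding:
    """Min-max scale each embedding dimension to [0, 1].

    A dimension with zero range maps to the constant 0 (its recorded range is
    0, flagging it as non-invertible). Idempotent: normalizing an already
    unit-range embedding leaves it unchanged.
    """
    coords = e.coords
    mins = coords.min(axis=0)
    ranges = coords.max(axis=0) - mins
    scaled = np.zeros_like(coords)
    ok = ranges > 0
    scaled[:, ok] = (coords[:, ok] - mins[ok]) / ranges[ok]
    return Embedding(
        coords=scaled,
        method=e.method,
        params=dict(e.params),
        normalized=True,
        norm_mins=mins,
        norm_ranges=ranges,
    )


def embedding_r2(e_true: np.ndarray, e_pred: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-dimension squared Pearson correlation and its minimum.

    Invariant under any per-dimension affine rescaling of either argument.
    Raises :class:`DegenerateInputError` if any dimension of either input has
    zero variance (correlation undefined).
    """
    a = np.asarray(e_true, dtype=float)
    b = np.asarray(e_pred, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.ndim == 1:
        a, b = a[:, None], b[:, None]
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    va = (ac**2).sum(axis=0)
    vb = (bc**2).sum(axis=0)
    if np.any(va == 0) or np.any(vb == 0):
        raise DegenerateInputError("zero-variance dimension")
    r2 = (ac * bc).sum(axis=0) ** 2 / (va * vb)
    return r2, float(r2.min())


def rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Plain (unadjusted) Rand index between two partitions.

    The fraction of the ``n(n-1)/2`` sample pairs on which the two partitions
    agree — both co-clustered or both separated.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    if labels_a.ndim != 1 or len(labels_a) < 2:
        raise ValueError("need at least 2 samples")
    return float(rand_score(labels_a, labels_b))
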
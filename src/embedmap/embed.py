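"""Reference nonlinear embeddings of the training subset.

Two interchangeable backends: exact-gradient t-SNE (perplexity 30,
exaggeration 4) and UMAP (30 neighbors, min_dist 0.3), both with the
correlation distance metric (1 - Pearson correlation between sample
vectors) and 3 output dimensions by default. The downstream neural maps are
agnostic to which backend produced the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import DegenerateInputError, Embedding, FeatureMatrix

__all__ = ["EmbedParams", "tsne_embed", "umap_embed", "embed"]


@dataclass
class EmbedParams:
    """Embedding backend parameters.

    Defaults follow common practice for omics data: t-SNE with the exact
    algorithm, perplexity 30 and (early) exaggeration 4; UMAP with 30 nearest
    neighbors and minimum distance 0.3; correlation metric; 3 output
    dimensions (supporting direct RGB rendering), 2 also allowed.
    """

    method: str = "tsne"
    out_dims: int = 3
    metric: str = "correlation"
    perplexity: float = 30.0
    exaggeration: float = 4.0
    n_neighbors: int = 30
    min_dist: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("tsne", "umap"):
            raise ValueError("method must be 'tsne' or 'umap'")
        if self.out_dims not in (2, 3):
            raise ValueError("out_dims must be 2 or 3")
        if self.metric not in ("correlation", "euclidean"):
            raise ValueError("metric must be 'correlation' or 'euclidean'")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if not 0 < self.min_dist < 1:
            raise ValueError("min_dist must be in (0, 1)")


def _as_array(x) -> np.ndarray:
    values = x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("input contains non-finite values")
    return values


def _check_correlation_ok(values: np.ndarray, metric: str) -> None:
    if metric == "correlation" and np.any(values.std(axis=1) == 0):
        raise DegenerateInputError(
            "zero-variance sample vector: correlation distance undefined"
        )


def tsne_embed(x, params: EmbedParams | None = None) -> Embedding:
    """Exact-algorithm t-SNE of the subset.

    Requires at least ``3 * perplexity`` rows. Reproducible for a fixed seed
    and backend version.
    """
    from sklearn.manifold import TSNE

    params = params or EmbedParams(method="tsne")
    values = _as_array(x)
    if values.shape[0] < 3 * params.perplexity:
        raise ValueError(
            f"need >= 3*perplexity = {int(3 * params.perplexity)} samples, "
            f"got {values.shape[0]}"
        )
    _check_correlation_ok(values, params.metric)
    tsne = TSNE(
        n_components=params.out_dims,
        perplexity=params.perplexity,
        early_exaggeration=params.exaggeration,
        metric=params.metric,
        method="exact",
        init="pca",
        random_state=params.seed,
    )
    coords = tsne.fit_transform(values)
    return Embedding(coords=coords, method="tsne", params=asdict(params))


def umap_embed(x, params: EmbedParams | None = None) -> Embedding:
    """UMAP embedding of the subset (requires rows > n_neighbors)."""
    import umap  # deferred: numba compilation makes this import heavy

    params = params or EmbedParams(method="umap")
    values = _as_array(x)
    if values.shape[0] <= params.n_neighbors:
        raise ValueError(
            f"need > n_neighbors = {params.n_neighbors} samples, got {values.shape[0]}"
        )
    _check_correlation_ok(values, params.metric)
    reducer = umap.UMAP(
        n_components=params.out_dims,
        n_neighbors=params.n_neighbors,
        min_dist=params.min_dist,
        metric=params.metric,
        random_state=params.seed,
    )
    coords = np.asarray(reducer.fit_transform(values), dtype=float)
    return Embedding(coords=coords, method="umap", params=asdict(params))


def embed(x, params: EmbedParams) -> Embedding:
    """Dispatch to the backend named in ``params.method``."""
    return tsne_embed(x, params) if params.method == "tsne" else umap_embed(x, params)
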
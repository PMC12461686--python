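"""Novelty flagging for newly projected data.

New samples dissimilar to everything in the training data (novel tissue
types, acquisition artifacts) are flagged from their position in embedding
space: the primary score is the Euclidean distance from each projected sample
to its k-th nearest training embedding point; an optional secondary score is
the correlation distance between a sample and its round-trip reconstruction
``inverse(forward(x))``. The threshold is calibrated as an empirical quantile
of the training set's own leave-self-out scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .core import Embedding, FeatureMatrix
from .netmap import NeuralMapResults

__all__ = [
    "NoveltyScores",
    "NoveltyReport",
    "novelty_score",
    "training_self_scores",
    "calibrate_threshold",
    "novelty_report",
]


@dataclass
class NoveltyScores:
    knn: np.ndarray
    roundtrip: np.ndarray | None = None


@dataclass
class NoveltyReport:
    scores: np.ndarray
    threshold: float
    flags: np.ndarray
    definition: str

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.scores) > self.threshold


def novelty_score(
    fwd: NeuralMapResults,
    e_train: Embedding,
    x_new,
    k: int = 10,
    inv: NeuralMapResults | None = None,
) -> NoveltyScores:
    """Score new samples against the training embedding.

    Primary: distance to the k-th nearest training embedding point after
    projecting ``x_new`` through the forward map. Secondary (if ``inv`` is
    given): correlation distance between each new spectrum and its round-trip
    reconstruction.
    """
    if k < 1 or k > e_train.n:
        raise ValueError("require 1 <= k <= number of training samples")
    values = x_new.values if isinstance(x_new, FeatureMatrix) else np.asarray(x_new, float)
    coords = fwd.predict(values)
    nn = NearestNeighbors(n_neighbors=k).fit(e_train.coords)
    dist, _ = nn.kneighbors(coords)
    knn = dist[:, -1]
    roundtrip = None
    if inv is not None:
        recon = inv.predict(coords)
        a = values - values.mean(axis=1, keepdims=True)
        b = recon - recon.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        r = np.zeros(len(values))
        ok = denom > 0
        r[ok] = (a * b).sum(axis=1)[ok] / denom[ok]
        roundtrip = 1.0 - r
    return NoveltyScores(knn=knn, roundtrip=roundtrip)


def training_self_scores(e_train: Embedding, k: int = 10) -> np.ndarray:
    """Leave-self-out k-NN distances of the training embedding points."""
    if k < 1 or k >= e_train.n:
        raise ValueError("require 1 <= k < number of training samples")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(e_train.coords)
    dist, _ = nn.kneighbors(e_train.coords)
    return dist[:, -1]  # first neighbor is the point itself at distance 0


def calibrate_threshold(scores_train: np.ndarray, quantile: float = 0.99) -> float:
    """Empirical quantile (linear-interpolation estimator) of self-scores."""
    scores_train = np.asarray(scores_train, dtype=float)
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if len(scores_train) < 20:
        raise ValueError("need at least 20 training scores to calibrate")
    return float(np.quantile(scores_train, quantile, method="linear"))


def novelty_report(
    fwd: NeuralMapResults,
    e_train: Embedding,
    x_new,
    k: int = 10,
    quantile: float = 0.99,
) -> NoveltyReport:
    """Scores, calibrated threshold and flags in one call (k-NN definition)."""
    scores = novelty_score(fwd, e_train, x_new, k=k).knn
    threshold = calibrate_threshold(training_self_scores(e_train, k=k), quantile)
    return NoveltyReport(
        scores=scores,
        threshold=threshold,
        flags=scores > threshold,
        definition=f"knn(k={k})",
    )
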
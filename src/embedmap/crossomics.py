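"""Cross-omics integration: map one modality into another's embedding.

For matched samples (e.g. metabolomics and transcriptomics of the same cell
pellets), a cross map is trained from modality-A feature vectors to the
reduced-space coordinates of modality B. Projected A data then inherits the
class structure that B's embedding resolves, which can sharpen downstream
classification of A-only samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Embedding, FeatureMatrix
from .netmap import NeuralMapModel, NeuralMapResults, TrainConfig

__all__ = ["MatchedPair", "train_cross", "project_cross"]


@dataclass
class MatchedPair:
    """Two modalities with an explicit one-to-one sample-id pairing.

    ``pairing`` is a list of ``(id_in_a, id_in_b)`` tuples. Pairing is by id,
    never by row order: silent misalignment is the dominant failure mode in
    matched-omics work.
    """

    x_a: FeatureMatrix
    x_b: FeatureMatrix
    pairing: list

    def __post_init__(self) -> None:
        self.pairing = [(str(a), str(b)) for a, b in self.pairing]
        ids_a = {s: i for i, s in enumerate(self.x_a.sample_ids)}
        ids_b = {s: i for i, s in enumerate(self.x_b.sample_ids)}
        a_seen, b_seen = set(), set()
        for a, b in self.pairing:
            if a not in ids_a:
                raise ValueError(f"paired id {a!r} missing from modality A")
            if b not in ids_b:
                raise ValueError(f"paired id {b!r} missing from modality B")
            if a in a_seen or b in b_seen:
                raise ValueError("pairing must be one-to-one")
            a_seen.add(a)
            b_seen.add(b)
        self._rows_a = np.array([ids_a[a] for a, _ in self.pairing], dtype=int)
        self._rows_b = np.array([ids_b[b] for _, b in self.pairing], dtype=int)

    @classmethod
    def from_shared_ids(cls, x_a: FeatureMatrix, x_b: FeatureMatrix) -> "MatchedPair":
        shared = [s for s in x_a.sample_ids if s in set(x_b.sample_ids)]
        return cls(x_a, x_b, [(s, s) for s in shared])

    @property
    def n_pairs(self) -> int:
        return len(self.pairing)

    def aligned(self) -> tuple[np.ndarray, np.ndarray]:
        """A-rows and B-rows reordered into pairing order."""
        return self.x_a.values[self._rows_a], self._rows_b


def train_cross(
    pair: MatchedPair, e_b: Embedding, config: TrainConfig | None = None
) -> NeuralMapResults:
    """Train modality-A features -> modality-B embedding coordinates.

    ``e_b`` must be the (normalized) embedding of ``pair.x_b`` with rows in
    ``x_b`` sample order; either backend (t-SNE or UMAP) may have produced it.
    """
    if not e_b.normalized:
        raise ValueError("modality-B embedding must be normalized first")
    if e_b.n != pair.x_b.n:
        raise ValueError("embedding rows must correspond to modality-B samples")
    if pair.n_pairs < 10:
        raise ValueError("need at least 10 matched pairs")
    a_rows, b_idx = pair.aligned()
    model = NeuralMapModel(
        a_rows,
        e_b.coords[b_idx],
        direction="cross",
        config=config,
        feature_axis=pair.x_a.feature_axis,
    )
    res = model.fit()
    res.meta = {"embedding_method": e_b.method, "embedding_params": dict(e_b.params)}
    return res


def project_cross(
    map_: NeuralMapResults, x_a_new, chunk_size: int | None = None
) -> np.ndarray:
    """Project new modality-A rows into the modality-B embedding space."""
    if map_.direction != "cross":
        raise ValueError("map direction must be 'cross'")
    values = x_a_new.values if isinstance(x_a_new, FeatureMatrix) else x_a_new
    return map_.predict(values, chunk_size=chunk_size)
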
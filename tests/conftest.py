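"""Shared fixtures: small synthetic datasets and cheaply trained maps."""

import numpy as np
import pytest

from embedmap.core import Embedding, normalize_embedding
from embedmap.netmap import TrainConfig, train_forward, train_inverse
from embedmap.synth import SynthSpec, make_msi_like


@pytest.fixture(scope="session")
def small_msi():
    """Tiny MSI-like dataset (no embedding needed) for unit tests."""
    spec = SynthSpec(n_pixels=400, n_features=60, n_regions=4, seed=11)
    return make_msi_like(spec)


@pytest.fixture(scope="session")
def toy_maps(small_msi):
    """Forward and inverse maps trained against a smooth synthetic embedding.

    The 'embedding' is an analytic smooth function of the region label and
    spatial position (not t-SNE) so unit tests of the map machinery stay
    fast; embedding-backend fidelity is exercised elsewhere.
    """
    ds = small_msi
    pos = ds.geometry.positions.astype(float)
    pos = pos / pos.max(axis=0)
    coords = np.column_stack(
        [
            ds.labels / max(ds.labels.max(), 1),
            pos[:, 0],
            pos[:, 1],
        ]
    )
    e = normalize_embedding(Embedding(coords=coords, method="network"))
    cfg = TrainConfig(max_epochs=200, seed=0)
    fwd = train_forward(ds.matrix, e, cfg)
    inv = train_inverse(e, ds.matrix, cfg)
    return {"dataset": ds, "embedding": e, "forward": fwd, "inverse": inv}
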
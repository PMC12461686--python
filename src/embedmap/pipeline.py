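"""End-to-end workflow: subsample -> embed -> train maps -> apply to all data.

This is the orchestration used by the command-line interface; each stage is
an ordinary library call, so the pieces can also be run individually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .analyze import rgb_render
from .core import Embedding, FeatureMatrix, PixelGeometry, normalize_embedding
from .embed import EmbedParams, embed
from .netmap import NeuralMapResults, TrainConfig, train_forward, train_inverse
from .subsample import SubsampleResult, every_nth, random_subset

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    subset: SubsampleResult
    embedding: Embedding
    forward: NeuralMapResults
    inverse: NeuralMapResults
    coords_full: np.ndarray
    outdir: Path | None = None


def run_pipeline(
    fm: FeatureMatrix,
    outdir=None,
    geometry: PixelGeometry | None = None,
    subsample: str = "every_nth:10",
    embed_params: EmbedParams | None = None,
    train_config: TrainConfig | None = None,
    chunk_size: int | None = 100_000,
) -> PipelineResult:
    """Run the full workflow on one feature matrix.

    ``subsample`` is ``"every_nth:<n>"`` or ``"random:<k>:<seed>"``. If
    ``outdir`` is given, writes subset indices, the reference embedding, the
    serialized forward/inverse maps, full-data coordinates, a rendered RGB
    image (when geometry is available) and a machine-readable diagnostics
    record sufficient to repeat the run.
    """
    embed_params = embed_params or EmbedParams()
    train_config = train_config or TrainConfig()

    parts = subsample.split(":")
    try:
        if parts[0] == "every_nth":
            sub = every_nth(fm.n, int(parts[1]))
        elif parts[0] == "random":
            sub = random_subset(fm.n, int(parts[1]), int(parts[2]))
        else:
            raise ValueError
    except (ValueError, IndexError):
        raise ValueError(
            f"invalid subsample spec {subsample!r}; use every_nth:<n> or random:<k>:<seed>"
        ) from None

    x_sub = fm.subset(sub.indices)
    e_sub = normalize_embedding(embed(x_sub, embed_params))
    fwd = train_forward(x_sub, e_sub, train_config)
    inv = train_inverse(e_sub, x_sub, train_config)
    coords_full = fwd.predict(fm.values, chunk_size=chunk_size)

    result = PipelineResult(
        subset=sub, embedding=e_sub, forward=fwd, inverse=inv,
        coords_full=coords_full,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "subset_indices.txt", sub.indices, fmt="%d")
        np.savetxt(outdir / "embedding_subset.csv", e_sub.coords, delimiter=",")
        fwd.save(outdir / "forward_map.npz")
        inv.save(outdir / "inverse_map.npz")
        np.savetxt(outdir / "coords_full.csv", coords_full, delimiter=",")
        if geometry is not None and e_sub.d in (2, 3):
            full_e = Embedding(
                coords=np.clip(coords_full, 0.0, 1.0),
                method="network",
                params=dict(e_sub.params),
                normalized=True,
            )
            img = rgb_render(full_e, geometry)
            try:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                plt.imsave(outdir / "segmentation_rgb.png", img)
            except Exception:  # rendering is best-effort; data artifacts matter
                pass
        diagnostics = {
            "n_total": fm.n,
            "n_features": fm.p,
            "subsample": {"scheme": sub.scheme, "parameters": sub.parameters,
                          "n_subset": len(sub)},
            "embed_params": asdict(embed_params),
            "train_config": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in asdict(train_config).items()},
            "forward_diagnostics": _jsonable(fwd.diagnostics),
            "inverse_diagnostics": _jsonable(inv.diagnostics),
        }
        with open(outdir / "diagnostics.json", "w") as fh:
            json.dump(diagnostics, fh, indent=2)
        result.outdir = outdir
    return result


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, tuple):
            out[k] = list(v)
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out
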
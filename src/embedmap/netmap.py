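"""Neural surrogates for nonlinear embeddings: the package core.

A :class:`NeuralMapModel` learns a regression between feature space and
embedding space in either direction:

* ``forward``  — features -> embedding coordinates, so the reference
  embedding computed on a tractable subset can be applied to the remaining
  (or newly acquired) samples;
* ``inverse``  — embedding coordinates -> features, so any point of the
  reduced space can be turned back into a pseudo-spectrum;
* ``cross``    — features of one omics modality -> embedding coordinates of
  another, for matched samples.

``fit()`` returns a :class:`NeuralMapResults` carrying the trained weights,
the normalization constants needed to apply the map, per-dimension r-squared
diagnostics on the held-out test split, and a ``summary()`` table.

Training follows a 70/15/15 train/test/validation split with at most 1000
epochs; regularization is an L2 weight penalty combined with early stopping
on the validation split (shrinkage in the same spirit as Bayesian-regularized
backpropagation, with the strength exposed as a config knob).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.neural_network import MLPRegressor

from .core import Embedding, FeatureMatrix

__all__ = [
    "TrainConfig",
    "split_data",
    "NeuralMapModel",
    "NeuralMapResults",
    "train_forward",
    "train_inverse",
    "apply_map",
]

# Predictions are computed in fixed tiles padded to this many rows so each
# output row is a pure function of its input row (BLAS kernels are not
# bitwise reproducible across batch shapes).
_TILE = 512


@dataclass
class TrainConfig:
    """Training hyperparameters for the neural maps.

    ``train_frac``/``test_frac``/``val_frac`` must be positive and sum to 1
    (default 0.70/0.15/0.15). ``alpha`` is the L2 weight penalty; the default
    ``"auto"`` selects it from a small grid (1e-4, 1e-2, 1.0) by validation
    loss, adapting the shrinkage to the problem the way evidence-based
    Bayesian regularization does. ``hidden`` is the hidden layer layout; the
    default (128, 64) is recorded in the fitted map so applications are
    self-describing.
    """

    train_frac: float = 0.70
    test_frac: float = 0.15
    val_frac: float = 0.15
    max_epochs: int = 1000
    alpha: float | str = "auto"
    hidden: tuple = (128, 64)
    activation: str = "tanh"
    patience: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.train_frac, self.test_frac, self.val_frac)
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if isinstance(self.alpha, str):
            if self.alpha != "auto":
                raise ValueError("alpha must be a nonnegative float or 'auto'")
        elif self.alpha < 0:
            raise ValueError("alpha must be a nonnegative float or 'auto'")
        self.hidden = tuple(int(h) for h in self.hidden)

    @property
    def alpha_grid(self) -> tuple:
        return (1e-4, 1e-2, 1.0) if self.alpha == "auto" else (float(self.alpha),)


def split_data(n: int, config: TrainConfig | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test/validation index sets.

    Sizes are within one sample of the target fractions; reproducible from
    ``config.seed``.
    """
    config = config or TrainConfig()
    if n < 10:
        raise ValueError("need n >= 10 to populate all three splits")
    n_train = int(round(config.train_frac * n))
    n_test = int(round(config.test_frac * n))
    n_val = n - n_train - n_test
    if min(n_train, n_test, n_val) < 1:
        raise ValueError("n too small for the requested split fractions")
    perm = np.random.default_rng(config.seed).permutation(n)
    return (
        perm[:n_train],
        perm[n_train : n_train + n_test],
        perm[n_train + n_test :],
    )


def _safe_r2_per_dim(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per output dimension; NaN where the true
    dimension has no variance (undefined, excluded from summaries)."""
    yt = y_true - y_true.mean(axis=0)
    yp = y_pred - y_pred.mean(axis=0)
    vt = (yt**2).sum(axis=0)
    vp = (yp**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (yt * yp).sum(axis=0) ** 2 / (vt * vp)
    r2[vt == 0] = np.nan
    r2[(vt > 0) & (vp == 0)] = 0.0
    return r2


def _per_sample_r2(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between each true and predicted row."""
    yt = y_true - y_true.mean(axis=1, keepdims=True)
    yp = y_pred - y_pred.mean(axis=1, keepdims=True)
    num = (yt * yp).sum(axis=1) ** 2
    den = (yt**2).sum(axis=1) * (yp**2).sum(axis=1)
    out = np.full(len(y_true), np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


class NeuralMapModel:
    """Feed-forward regression model between feature and embedding space.

    Parameters
    ----------
    x : ndarray of shape (n, input_dim)
        Input rows (standardized internally using training-split statistics).
    y : ndarray of shape (n, output_dim)
        Target rows (min-max scaled internally using training-split ranges).
    direction : {"forward", "inverse", "cross"}
        Semantic direction of the map; recorded in the results.
    config : TrainConfig, optional
    feature_axis : ndarray, optional
        m/z axis carried through to results whose outputs (inverse maps) or
        inputs are spectra.
    """

    def __init__(self, x, y, direction: str = "forward",
                 config: TrainConfig | None = None, feature_axis=None):
        if direction not in ("forward", "inverse", "cross"):
            raise ValueError("direction must be forward, inverse or cross")
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.x.ndim != 2 or self.y.ndim != 2:
            raise ValueError("x and y must be 2-D")
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y row counts differ")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("non-finite values in training data")
        self.direction = direction
        self.config = config or TrainConfig()
        self.feature_axis = None if feature_axis is None else np.asarray(feature_axis, float)

    @classmethod
    def from_matrices(cls, x: FeatureMatrix, e: Embedding,
                      direction: str = "forward",
                      config: TrainConfig | None = None) -> "NeuralMapModel":
        """Build from domain containers; embedding must be unit-cube normalized."""
        if not e.normalized:
            raise ValueError("embedding must be normalized (unit cube) first")
        if x.n != e.n:
            raise ValueError("matrix and embedding row counts differ")
        if direction == "inverse":
            return cls(e.coords, x.values, "inverse", config, feature_axis=x.feature_axis)
        return cls(x.values, e.coords, direction, config, feature_axis=x.feature_axis)

    def fit(self) -> "NeuralMapResults":
        cfg = self.config
        n = self.x.shape[0]
        idx_train, idx_test, idx_val = split_data(n, cfg)

        x_mean = self.x[idx_train].mean(axis=0)
        x_std = self.x[idx_train].std(axis=0)
        x_std[x_std == 0] = 1.0
        y_min = self.y[idx_train].min(axis=0)
        y_range = self.y[idx_train].max(axis=0) - y_min
        y_range[y_range == 0] = 1.0

        xs = (self.x - x_mean) / x_std
        ys = (self.y - y_min) / y_range
        xtr, ytr = xs[idx_train], ys[idx_train]
        xval, yval = xs[idx_val], ys[idx_val]

        mlp = None
        best_val = np.inf
        epochs_run = 0
        alpha_selected = None
        for alpha in cfg.alpha_grid:
            cand, cand_val, cand_epochs = self._train_one(
                alpha, xtr, ytr, xval, yval, cfg
            )
            if cand_val < best_val or mlp is None:
                mlp, best_val, epochs_run = cand, cand_val, cand_epochs
                alpha_selected = alpha

        baseline_val = float(np.mean((ytr.mean(axis=0) - yval) ** 2))
        if best_val >= baseline_val:
            warnings.warn(
                "validation loss never improved on the constant-predictor "
                "baseline; the map is uninformative",
                category=UserWarning,
            )

        results = NeuralMapResults(
            direction=self.direction,
            config=cfg,
            mlp=mlp,
            x_mean=x_mean,
            x_std=x_std,
            y_min=y_min,
            y_range=y_range,
            feature_axis=self.feature_axis,
            diagnostics={},
        )
        diag = {
            "epochs_run": epochs_run,
            "best_val_mse": best_val,
            "baseline_val_mse": baseline_val,
            "alpha_selected": alpha_selected,
        }
        for name, idx in (("train", idx_train), ("test", idx_test), ("val", idx_val)):
            pred = results.predict(self.x[idx])
            r2 = _safe_r2_per_dim(self.y[idx], pred)
            diag[f"r2_{name}"] = r2
            diag[f"r2_{name}_min"] = float(np.nanmin(r2))
            diag[f"r2_{name}_mean"] = float(np.nanmean(r2))
            if self.direction == "inverse" and self.y.shape[1] >= 2:
                ps = _per_sample_r2(self.y[idx], pred)
                diag[f"reconstruction_r2_{name}_mean"] = float(np.nanmean(ps))
                diag[f"reconstruction_r2_{name}_min"] = float(np.nanmin(ps))
        diag["split_sizes"] = (len(idx_train), len(idx_test), len(idx_val))
        results.diagnostics = diag
        return results

    def _train_one(self, alpha, xtr, ytr, xval, yval, cfg):
        """Minibatch training with early stopping; returns the best-epoch
        network, its validation MSE and the number of epochs run."""
        bs = min(cfg.batch_size, len(xtr))
        mlp = MLPRegressor(
            hidden_layer_sizes=cfg.hidden,
            activation=cfg.activation,
            solver="adam",
            alpha=alpha,
            batch_size=bs,
            learning_rate_init=cfg.learning_rate,
            random_state=cfg.seed,
            max_iter=1,
        )
        rng = np.random.default_rng(cfg.seed)
        best_val = np.inf
        best_weights = None
        bad = 0
        epochs_run = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-minibatch ConvergenceWarnings
            for epoch in range(cfg.max_epochs):
                order = rng.permutation(len(xtr))
                for start in range(0, len(order), bs):
                    batch = order[start : start + bs]
                    mlp.partial_fit(xtr[batch], ytr[batch])
                epochs_run = epoch + 1
                val_mse = float(np.mean((self._raw_predict(mlp, xval) - yval) ** 2))
                if val_mse < best_val * (1 - 1e-5):
                    best_val = val_mse
                    best_weights = (
                        [c.copy() for c in mlp.coefs_],
                        [b.copy() for b in mlp.intercepts_],
                    )
                    bad = 0
                else:
                    bad += 1
                    if bad > cfg.patience:
                        break
        if best_weights is not None:
            mlp.coefs_, mlp.intercepts_ = best_weights
        return mlp, best_val, epochs_run

    @staticmethod
    def _raw_predict(mlp: MLPRegressor, xs: np.ndarray) -> np.ndarray:
        out = np.empty((xs.shape[0], mlp.n_outputs_))
        for start in range(0, xs.shape[0], _TILE):
            block = xs[start : start + _TILE]
            m = block.shape[0]
            if m < _TILE:
                block = np.vstack([block, np.zeros((_TILE - m, xs.shape[1]))])
            pred = mlp.predict(block)
            if pred.ndim == 1:
                pred = pred[:, None]
            out[start : start + m] = pred[:m]
        return out


@dataclass
class NeuralMapResults:
    """A trained map with its normalization constants and diagnostics.

    ``predict`` standardizes inputs with the stored training statistics,
    evaluates the network in fixed 512-row tiles (so results are independent
    of how the data is chunked), and undoes the target scaling.
    """

    direction: str
    config: TrainConfig
    mlp: MLPRegressor
    x_mean: np.ndarray
    x_std: np.ndarray
    y_min: np.ndarray
    y_range: np.ndarray
    feature_axis: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def input_dim(self) -> int:
        return len(self.x_mean)

    @property
    def output_dim(self) -> int:
        return len(self.y_min)

    def predict(self, x, chunk_size: int | None = None) -> np.ndarray:
        """Apply the map; deterministic and chunk-size independent.

        ``chunk_size`` caps how many rows are materialized at once (for
        streaming large datasets); it is rounded up to the internal tile
        size, so any value yields bit-identical output.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input columns, got {x.shape[1]}"
            )
        if np.any(~np.isfinite(x)):
            raise ValueError("non-finite input")
        if chunk_size is None:
            chunk = x.shape[0]
        else:
            chunk = max(_TILE, (int(chunk_size) + _TILE - 1) // _TILE * _TILE)
        out = np.empty((x.shape[0], self.output_dim))
        for start in range(0, x.shape[0], chunk):
            xs = (x[start : start + chunk] - self.x_mean) / self.x_std
            raw = NeuralMapModel._raw_predict(self.mlp, xs)
            out[start : start + chunk] = raw * self.y_range + self.y_min
        return out

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Neural embedding map",
            "=" * 56,
            f"direction:      {self.direction}",
            f"input dim:      {self.input_dim}",
            f"output dim:     {self.output_dim}",
            f"hidden layout:  {self.config.hidden}  ({self.config.activation})",
            f"L2 alpha:       {self.config.alpha}"
            + (
                f" (selected {d['alpha_selected']:g})"
                if d.get("alpha_selected") is not None and self.config.alpha == "auto"
                else ""
            ),
            f"epochs run:     {d.get('epochs_run', '?')} (max {self.config.max_epochs})",
            f"split sizes:    {d.get('split_sizes', '?')} (train/test/val)",
            "-" * 56,
            f"{'split':8s}{'r2 min':>12s}{'r2 mean':>12s}",
        ]
        for name in ("train", "test", "val"):
            if f"r2_{name}_min" in d:
                lines.append(
                    f"{name:8s}{d[f'r2_{name}_min']:12.4f}{d[f'r2_{name}_mean']:12.4f}"
                )
        if self.direction == "inverse" and "reconstruction_r2_test_mean" in d:
            lines.append("-" * 56)
            lines.append(
                "reconstruction r2 (per held-out spectrum): "
                f"mean {d['reconstruction_r2_test_mean']:.4f}, "
                f"min {d['reconstruction_r2_test_min']:.4f}"
            )
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        """Serialize to a single .npz container (weights + metadata JSON)."""
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, tuple):
                return list(v)
            return v

        meta = {
            "direction": self.direction,
            "config": {k: _clean(v) for k, v in asdict(self.config).items()},
            "diagnostics": {k: _clean(v) for k, v in self.diagnostics.items()},
            "meta": self.meta,
            "n_layers": len(self.mlp.coefs_),
            "has_feature_axis": self.feature_axis is not None,
        }
        arrays = {
            "x_mean": self.x_mean,
            "x_std": self.x_std,
            "y_min": self.y_min,
            "y_range": self.y_range,
        }
        for i, (c, b) in enumerate(zip(self.mlp.coefs_, self.mlp.intercepts_)):
            arrays[f"coef_{i}"] = c
            arrays[f"intercept_{i}"] = b
        if self.feature_axis is not None:
            arrays["feature_axis"] = self.feature_axis
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "NeuralMapResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            cfg_d = dict(meta["config"])
            cfg_d["hidden"] = tuple(cfg_d["hidden"])
            cfg = TrainConfig(**cfg_d)
            coefs = [z[f"coef_{i}"] for i in range(meta["n_layers"])]
            intercepts = [z[f"intercept_{i}"] for i in range(meta["n_layers"])]
            mlp = MLPRegressor(
                hidden_layer_sizes=cfg.hidden, activation=cfg.activation
            )
            mlp.coefs_ = coefs
            mlp.intercepts_ = intercepts
            mlp.n_layers_ = len(coefs) + 1
            mlp.n_outputs_ = coefs[-1].shape[1]
            mlp.n_features_in_ = coefs[0].shape[0]
            mlp.out_activation_ = "identity"
            diag = meta["diagnostics"]
            for k in list(diag):
                if k.startswith("r2_") and isinstance(diag[k], list):
                    diag[k] = np.asarray(diag[k])
            return cls(
                direction=meta["direction"],
                config=cfg,
                mlp=mlp,
                x_mean=z["x_mean"],
                x_std=z["x_std"],
                y_min=z["y_min"],
                y_range=z["y_range"],
                feature_axis=z["feature_axis"] if meta["has_feature_axis"] else None,
                diagnostics=diag,
                meta=meta.get("meta", {}),
            )


def train_forward(x: FeatureMatrix, e: Embedding,
                  config: TrainConfig | None = None) -> NeuralMapResults:
    """Train the features -> embedding map on the reference subset."""
    res = NeuralMapModel.from_matrices(x, e, "forward", config).fit()
    res.meta = {"embedding_method": e.method, "embedding_params": dict(e.params)}
    return res


def train_inverse(e: Embedding, x: FeatureMatrix,
                  config: TrainConfig | None = None) -> NeuralMapResults:
    """Train the embedding -> features map (pseudo-spectrum generator)."""
    res = NeuralMapModel.from_matrices(x, e, "inverse", config).fit()
    res.meta = {"embedding_method": e.method, "embedding_params": dict(e.params)}
    return res


def apply_map(map_: NeuralMapResults, x, chunk_size: int | None = None) -> np.ndarray:
    """Apply a trained map to rows of length ``input_dim``."""
    return map_.predict(x, chunk_size=chunk_size)
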
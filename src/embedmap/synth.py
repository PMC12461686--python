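"""Synthetic datasets emulating the statistical structure of the real inputs.

Three generators:

* :func:`make_msi_like` — clustered, nonnegative "spectra" laid out on an
  image raster with contiguous regions, each region carrying a planted
  marker feature unique to it (a desk-scale stand-in for tissue MSI data);
* :func:`make_matched_omics` — two modalities sharing a latent class
  variable, where modality B (transcriptomics-like) separates the classes
  cleanly and modality A (metabolomics-like) only weakly;
* :func:`make_outlier_set` — a clustered training set plus an
  in-distribution replicate and a novel cluster displaced from all training
  clusters, with truth flags.

All generators are pure functions of their spec and seeds. The noise model is
multiplicative log-normal with an additive Gaussian floor, clipped at zero —
a standard caricature of mass-spectrometry intensity noise. Region structure
(mean spectra, marker placement) derives from ``spec.seed`` alone, so a
replicate "serial section" drawn with a different ``noise_seed`` shares its
region chemistry exactly and differs only in noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import FeatureMatrix, PixelGeometry
from .crossomics import MatchedPair

__all__ = [
    "SynthSpec",
    "MSIDataset",
    "OutlierSet",
    "make_msi_like",
    "make_matched_omics",
    "make_outlier_set",
    "write_toy_contact_list",
]


@dataclass
class SynthSpec:
    """Parameters of the MSI-like generator.

    ``region_sigma`` is the log-scale spread of per-region modulation of the
    base spectrum (how chemically distinct regions are); ``gradient_sigma``
    the log-scale loading of the smooth within-region spatial gradients that
    emulate the intensity gradients of real tissue sections;
    ``noise_mult_sigma`` the log-normal multiplicative pixel noise;
    ``noise_floor`` the additive Gaussian floor as a fraction of the median
    region-mean intensity; ``marker_boost`` the fold elevation of each
    region's planted marker.
    """

    n_pixels: int = 50_000
    n_features: int = 500
    n_regions: int = 6
    marker_boost: float = 8.0
    region_sigma: float = 0.6
    gradient_sigma: float = 0.4
    noise_mult_sigma: float = 0.15
    noise_floor: float = 0.02
    mz_range: tuple = (200.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions > self.n_pixels:
            raise ValueError("regions exceed pixels")
        if self.n_regions > self.n_features:
            raise ValueError("need at least one feature per region")


class MSIDataset(NamedTuple):
    matrix: FeatureMatrix
    geometry: PixelGeometry
    labels: np.ndarray
    markers: dict
    region_means: np.ndarray


class OutlierSet(NamedTuple):
    train: FeatureMatrix
    replicate: FeatureMatrix
    novel: FeatureMatrix
    eval_matrix: FeatureMatrix
    truth_flags: np.ndarray


def _region_structure(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray, dict, np.ndarray]:
    """Deterministic chemistry: feature axis, region mean spectra, markers,
    and per-region spatial-gradient loadings."""
    rng = np.random.default_rng(spec.seed)
    axis = np.linspace(spec.mz_range[0], spec.mz_range[1], spec.n_features)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_features)
    modulation = rng.lognormal(
        mean=0.0, sigma=spec.region_sigma, size=(spec.n_regions, spec.n_features)
    )
    means = base[None, :] * modulation
    markers = {}
    ref = float(means.max())  # fixed reference so all markers are comparable
    step = spec.n_features // spec.n_regions
    for r in range(spec.n_regions):
        f = r * step + step // 2
        markers[r] = f
        # marker uniquely high in its region, suppressed everywhere else
        suppressed = 0.1 * float(means[:, f].mean())
        means[:, f] = suppressed
        means[r, f] = ref * spec.marker_boost
    gradients = rng.normal(
        0.0, spec.gradient_sigma, size=(spec.n_regions, 2, spec.n_features)
    )
    return axis, means, markers, gradients


def _pixel_means(
    means: np.ndarray, gradients: np.ndarray, labels: np.ndarray,
    u: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Per-sample expected spectra: region mean modulated by the smooth
    spatial gradient at latent position (u, v) in [0, 1]^2."""
    logmod = (
        gradients[labels, 0, :] * (u - 0.5)[:, None]
        + gradients[labels, 1, :] * (v - 0.5)[:, None]
    )
    return means[labels] * np.exp(logmod)


def _noisy_pixels(
    pixel_means: np.ndarray, spec: SynthSpec, rng: np.random.Generator
) -> np.ndarray:
    x = pixel_means
    if spec.noise_mult_sigma > 0:
        x = x * rng.lognormal(0.0, spec.noise_mult_sigma, size=x.shape)
    if spec.noise_floor > 0:
        x = x + rng.normal(0.0, spec.noise_floor * np.median(pixel_means), size=x.shape)
    return np.clip(x, 0.0, None)


def make_msi_like(spec: SynthSpec, noise_seed: int | None = None) -> MSIDataset:
    """Image-grid dataset with contiguous regions and planted markers.

    Passing a different ``noise_seed`` (default: ``spec.seed``) produces a
    statistically matching serial section: identical region layout, mean
    spectra and spatial gradients, fresh noise.
    """
    axis, means, markers, gradients = _region_structure(spec)
    w = int(np.ceil(np.sqrt(spec.n_pixels)))
    h = int(np.ceil(spec.n_pixels / w))
    flat = np.arange(spec.n_pixels)
    xs = flat % w
    ys = flat // w
    labels = np.minimum(xs * spec.n_regions // w, spec.n_regions - 1)
    rng = np.random.default_rng(spec.seed if noise_seed is None else noise_seed)
    pixel_means = _pixel_means(means, gradients, labels, xs / w, ys / h)
    values = _noisy_pixels(pixel_means, spec, rng)
    fm = FeatureMatrix(
        values=values,
        feature_axis=axis,
        sample_ids=[f"px{i}" for i in flat],
        group_labels=[f"region{r}" for r in labels],
    )
    geom = PixelGeometry(positions=np.column_stack([xs, ys]), image_shape=(h, w))
    return MSIDataset(matrix=fm, geometry=geom, labels=labels, markers=markers,
                      region_means=means)


def make_matched_omics(
    n: int = 200,
    n_classes: int = 3,
    p_a: int = 300,
    p_b: int = 2000,
    sep_a: float = 3.0,
    sep_b: float = 20.0,
    nuisance_a: float = 8.0,
    nuisance_rank: int = 4,
    seed: int = 0,
) -> tuple[MatchedPair, np.ndarray]:
    """Matched two-modality dataset sharing latent classes.

    Separability is the aggregate (whole-profile Mahalanobis) offset between
    class means, independent of feature count; modality B (``sep_b``)
    separates cleanly, modality A (``sep_a``) weakly. Modality A additionally
    carries a strong low-rank nuisance component (``nuisance_a``,
    ``nuisance_rank``) emulating the dominant cell-line/batch variation of
    real metabolic profiles: A's own embedding organizes by nuisance, burying
    the class signal that a supervised projection into B's space can recover.
    Intensities are exponentiated to keep them nonnegative. ``sep_a`` may be
    0 (A carries no class signal) but must be below ``sep_b``.
    """
    if not sep_b > sep_a >= 0:
        raise ValueError("require sep_b > sep_a >= 0")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_classes
    rng.shuffle(labels)
    ids = [f"s{i:04d}" for i in range(n)]

    def modality(p: int, sep: float, nuisance: float) -> FeatureMatrix:
        class_means = rng.normal(0.0, 1.0, size=(n_classes, p)) * sep / np.sqrt(p)
        latent = class_means[labels] + rng.normal(0.0, 1.0, size=(n, p))
        if nuisance > 0:
            factors = rng.normal(size=(n, nuisance_rank))
            loadings = rng.normal(size=(nuisance_rank, p))
            latent += factors @ loadings * nuisance / np.sqrt(nuisance_rank * p)
        return FeatureMatrix(
            values=np.exp(0.25 * latent),
            feature_axis=np.linspace(100.0, 1000.0, p),
            sample_ids=ids,
            group_labels=[f"class{c}" for c in labels],
        )

    x_a = modality(p_a, sep_a, nuisance_a)
    x_b = modality(p_b, sep_b, 0.0)
    pair = MatchedPair(x_a=x_a, x_b=x_b, pairing=[(s, s) for s in ids])
    return pair, labels


def make_outlier_set(
    n_train: int = 1500,
    n_features: int = 100,
    n_clusters: int = 4,
    n_novel: int = 150,
    offset: float = 5.0,
    seed: int = 0,
    spec: SynthSpec | None = None,
) -> OutlierSet:
    """Training clusters, an in-distribution replicate, and a novel cluster.

    The novel cluster's mean is displaced from its parent training cluster by
    ``offset`` multiplicative-noise standard deviations per feature (log
    scale), i.e. ``offset = 0`` is statistically indistinguishable from
    training data and large offsets are trivially separable. Truth flags mark
    the novel rows of the concatenated evaluation matrix (replicate followed
    by novel).
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    spec = spec or SynthSpec(
        n_pixels=n_train, n_features=n_features, n_regions=n_clusters,
        marker_boost=4.0, seed=seed,
    )
    axis, means, _markers, gradients = _region_structure(spec)
    rng = np.random.default_rng(seed)

    def draw(labels, region_means):
        u = rng.uniform(size=len(labels))
        v = rng.uniform(size=len(labels))
        pm = _pixel_means(region_means, gradients, labels, u, v)
        return _noisy_pixels(pm, spec, rng)

    labels_train = rng.integers(0, n_clusters, size=n_train)
    labels_rep = rng.integers(0, n_clusters, size=n_train)
    train_vals = draw(labels_train, means)
    rep_vals = draw(labels_rep, means)
    # displace a copy of cluster 0's mean by `offset` log-sigma per feature
    signs = rng.choice([-1.0, 1.0], size=spec.n_features)
    novel_means = means.copy()
    novel_means[0] = means[0] * np.exp(offset * spec.noise_mult_sigma * signs)
    novel_vals = draw(np.zeros(n_novel, dtype=int), novel_means)

    def fm(vals, prefix):
        return FeatureMatrix(
            values=vals, feature_axis=axis,
            sample_ids=[f"{prefix}{i}" for i in range(len(vals))],
        )

    eval_vals = np.vstack([rep_vals, novel_vals])
    flags = np.concatenate(
        [np.zeros(len(rep_vals), dtype=bool), np.ones(n_novel, dtype=bool)]
    )
    return OutlierSet(
        train=fm(train_vals, "tr"),
        replicate=fm(rep_vals, "rep"),
        novel=fm(novel_vals, "nov"),
        eval_matrix=fm(eval_vals, "ev"),
        truth_flags=flags,
    )


def write_toy_contact_list(path, n_records: int = 50, seed: int = 0,
                           max_pos: int = 1_000_000, bin_size: int = 1000) -> None:
    """Write a small ``pos1 pos2 count`` contact list for I/O tests."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for _ in range(n_records):
            p1 = int(rng.integers(0, max_pos // bin_size)) * bin_size
            p2 = int(rng.integers(0, max_pos // bin_size)) * bin_size
            if p2 < p1:
                p1, p2 = p2, p1
            fh.write(f"{p1}\t{p2}\t{int(rng.integers(1, 20))}\n")
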
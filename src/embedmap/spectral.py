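"""Inverse queries: pseudo-spectra, driver ranking and ppm annotation.

Querying the inverse map at the unit-cube corners red ``[1,0,0]``, green
``[0,1,0]`` and blue ``[0,0,1]`` (and yellow ``[1,1,0]``) returns the
relative spectral contributions along the color dimensions of an RGB-rendered
segmentation; querying at cluster centroids returns the spectrum a region
would be expected to produce. Contributions are signed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Embedding, PseudoSpectrum
from .io import AnnotationTable
from .netmap import NeuralMapResults

__all__ = [
    "DriverList",
    "reverse_query",
    "centroid_spectrum",
    "rank_drivers",
    "ppm_match",
    "CORNERS_3D",
    "CORNERS_2D",
]

# Color-corner conventions for reverse queries of a normalized embedding.
CORNERS_3D = {
    "red": np.array([1.0, 0.0, 0.0]),
    "green": np.array([0.0, 1.0, 0.0]),
    "blue": np.array([0.0, 0.0, 1.0]),
    "yellow": np.array([1.0, 1.0, 0.0]),
}
CORNERS_2D = {
    "blue": np.array([0.0, 0.0]),
    "red": np.array([1.0, 0.0]),
    "green": np.array([0.0, 1.0]),
    "yellow": np.array([1.0, 1.0]),
}


@dataclass
class DriverList:
    """Features ranked by |contribution| (rank 1 = strongest driver)."""

    indices: np.ndarray
    mz: np.ndarray
    contributions: np.ndarray
    ranks: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "feature_index": self.indices,
                "mz": self.mz,
                "contribution": self.contributions,
            }
        )

    def __len__(self) -> int:
        return len(self.indices)


def reverse_query(inv: NeuralMapResults, point) -> PseudoSpectrum:
    """Pseudo-spectrum at a point of (normalized) embedding space."""
    if inv.direction != "inverse":
        raise ValueError("map direction must be 'inverse'")
    point = np.asarray(point, dtype=float).ravel()
    if len(point) != inv.input_dim:
        raise ValueError(f"point must have length {inv.input_dim}")
    if np.any(point < -0.5) or np.any(point > 1.5):
        warnings.warn(
            "query point far outside the unit cube; extrapolating the map"
        )
    contributions = inv.predict(point[None, :])[0]
    axis = (
        inv.feature_axis
        if inv.feature_axis is not None
        else np.arange(inv.output_dim, dtype=float)
    )
    return PseudoSpectrum(feature_axis=axis, contributions=contributions, query_point=point)


def centroid_spectrum(inv: NeuralMapResults, e: Embedding, mask) -> PseudoSpectrum:
    """Pseudo-spectrum at the centroid of the selected embedding points."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (e.n,):
        raise ValueError("mask length must equal embedding sample count")
    if not mask.any():
        raise ValueError("mask selects no samples")
    return reverse_query(inv, e.coords[mask].mean(axis=0))


def rank_drivers(ps: PseudoSpectrum, k: int, sign: str = "both") -> DriverList:
    """Top-k features by absolute contribution after sign filtering.

    Ties in |contribution| are broken by ascending m/z. ``k`` larger than the
    number of eligible features clips with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if sign not in ("positive", "negative", "both"):
        raise ValueError("sign must be positive, negative or both")
    c = ps.contributions
    if sign == "positive":
        eligible = np.flatnonzero(c > 0)
    elif sign == "negative":
        eligible = np.flatnonzero(c < 0)
    else:
        eligible = np.arange(len(c))
    if k > len(eligible):
        warnings.warn(f"k={k} exceeds {len(eligible)} eligible features; clipping")
        k = len(eligible)
    # lexsort: last key is primary -> sort by -|c|, tie-break ascending m/z
    order = eligible[np.lexsort((ps.feature_axis[eligible], -np.abs(c[eligible])))][:k]
    return DriverList(
        indices=order,
        mz=ps.feature_axis[order],
        contributions=c[order],
        ranks=np.arange(1, len(order) + 1),
    )


def ppm_match(
    mz_query: float, table: AnnotationTable, tol_ppm: float = 5.0
) -> pd.DataFrame:
    """Annotation entries within ``tol_ppm`` of the query mass.

    Returns a DataFrame (name, mass, adduct, ppm_error) sorted by |ppm
    error|; ppm error is signed, ``(mass - query) / query * 1e6``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if len(table) == 0:
        return pd.DataFrame(columns=["name", "mass", "adduct", "ppm_error"])
    ppm = (table.masses - mz_query) / mz_query * 1e6
    hit = np.abs(ppm) <= tol_ppm
    df = pd.DataFrame(
        {
            "name": [table.names[i] for i in np.flatnonzero(hit)],
            "mass": table.masses[hit],
            "adduct": [table.adducts[i] for i in np.flatnonzero(hit)],
            "ppm_error": ppm[hit],
        }
    )
    return df.iloc[np.argsort(np.abs(df["ppm_error"].to_numpy()), kind="stable")].reset_index(
        drop=True
    )
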
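"""Readers, writers and preprocessing for the formats the workflow touches.

Covers delimited intensity matrices, imzML mass spectrometry images
(via pyimzml), interpolated spectrum rebinning, ion-image generation,
Hi-C 3-column contact lists (``.RAWobserved``-style) with asymmetric
row/column binning, and metabolite annotation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureMatrix, PixelGeometry

__all__ = [
    "SparseContacts",
    "AnnotationTable",
    "DropZeroResult",
    "read_delimited_matrix",
    "write_delimited_matrix",
    "read_imzml",
    "rebin_spectrum",
    "ion_image",
    "read_contact_list",
    "bin_contacts",
    "drop_zero",
    "read_annotation_table",
]


@dataclass
class SparseContacts:
    """Sparse Hi-C contacts: parallel arrays of (pos1, pos2, count).

    Positions are 0-based bin-start coordinates in bp; counts are raw
    (un-normalized) and strictly positive.
    """

    pos1: np.ndarray
    pos2: np.ndarray
    count: np.ndarray
    chromosome: str | None = None

    def __post_init__(self) -> None:
        self.pos1 = np.asarray(self.pos1, dtype=np.int64)
        self.pos2 = np.asarray(self.pos2, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=float)
        if not (len(self.pos1) == len(self.pos2) == len(self.count)):
            raise ValueError("pos1, pos2, count must have equal length")
        if len(self.count) and (self.count.min() <= 0):
            raise ValueError("counts must be positive")
        if len(self.pos1) and (self.pos1.min() < 0 or self.pos2.min() < 0):
            raise ValueError("positions must be nonnegative")

    def __len__(self) -> int:
        return len(self.count)


@dataclass
class AnnotationTable:
    """Metabolite annotation entries: (name, mass in Da, adduct label)."""

    names: list
    masses: np.ndarray
    adducts: list

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if not (len(self.names) == len(self.masses) == len(self.adducts)):
            raise ValueError("columns must have equal length")
        if len(self.masses) and self.masses.min() <= 0:
            raise ValueError("masses must be positive")
        if any(not str(n) for n in self.names):
            raise ValueError("names must be non-empty")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class DropZeroResult:
    matrix: FeatureMatrix | None
    kept_rows: np.ndarray
    kept_cols: np.ndarray

    @property
    def empty(self) -> bool:
        return self.matrix is None


def read_delimited_matrix(
    path, orientation: str = "samples_rows", delimiter: str = ",", axis_kind: str = "mz"
) -> FeatureMatrix:
    """Read a delimited intensity matrix into a :class:`FeatureMatrix`.

    With ``orientation="samples_rows"`` the header row holds the feature axis
    (first cell is a free label) and each subsequent row is
    ``sample_id, v1, v2, ...``. ``"features_rows"`` reads the transpose.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or unreadable delimited file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError("orientation must be 'samples_rows' or 'features_rows'")
    try:
        axis = np.asarray([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: feature axis header is not numeric") from exc
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: non-numeric or missing cells")
    return FeatureMatrix(
        values=values,
        feature_axis=axis,
        sample_ids=[str(i) for i in df.index],
        axis_kind=axis_kind,
    )


def write_delimited_matrix(fm: FeatureMatrix, path, delimiter: str = ",") -> None:
    """Write a matrix so :func:`read_delimited_matrix` round-trips it exactly.

    Uses 17-significant-digit floats, which round-trip IEEE doubles.
    """
    df = pd.DataFrame(
        fm.values,
        index=pd.Index(fm.sample_ids, name="id"),
        columns=[np.format_float_scientific(v, precision=16) for v in fm.feature_axis],
    )
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def read_imzml(path, bin_edges: np.ndarray) -> tuple[FeatureMatrix, PixelGeometry]:
    """Read an imzML/.ibd pair and resample every pixel onto common bins.

    Each pixel spectrum is aggregated onto the supplied bin edges (intensity
    summed within each bin), which makes continuous- and processed-mode files
    of identical content yield identical matrices. The returned feature axis
    holds bin centers; pixel raster positions go into the geometry.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or len(bin_edges) < 2 or not np.all(np.diff(bin_edges) > 0):
        raise ValueError("bin_edges must be a strictly increasing 1-D array")
    parser = ImzMLParser(str(path))
    if not parser.coordinates:
        raise ValueError(f"{path}: no pixel coordinates present")
    n = len(parser.coordinates)
    k = len(bin_edges) - 1
    values = np.zeros((n, k))
    positions = np.zeros((n, 2), dtype=int)
    ids = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        values[i], _ = np.histogram(mz, bins=bin_edges, weights=inten)
        positions[i] = (x - 1, y - 1)  # imzML coordinates are 1-based
        ids.append(f"x{x - 1}_y{y - 1}")
    shape = (int(positions[:, 1].max()) + 1, int(positions[:, 0].max()) + 1)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    fm = FeatureMatrix(values=values, feature_axis=centers, sample_ids=ids)
    return fm, PixelGeometry(positions=positions, image_shape=shape)


def rebin_spectrum(
    mz: np.ndarray, intensity: np.ndarray, bin_width: float = 0.002
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated rebinning onto a uniform grid of spacing ``bin_width``.

    The grid spans [min(mz), max(mz)]; intensities are linearly interpolated
    at the grid points. Default width 0.002 Da.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.ndim != 1 or len(mz) < 2:
        raise ValueError("need at least 2 spectrum points")
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have equal length")
    if not np.all(np.diff(mz) > 0):
        raise ValueError("mz must be strictly increasing")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    span = mz[-1] - mz[0]
    n_bins = int(np.floor(span / bin_width * (1 + 1e-12))) + 1
    grid = mz[0] + bin_width * np.arange(n_bins)
    return grid, np.interp(grid, mz, intensity)


def ion_image(
    fm: FeatureMatrix, geometry: PixelGeometry, window: tuple[float, float]
) -> np.ndarray:
    """Integrate intensities across a peak window and paint per pixel.

    Sums the columns with ``mz_lo <= m/z <= mz_hi`` for each sample and
    rasterizes the totals; raster cells without a sample are 0. An empty
    window yields an all-zero image with a warning.
    """
    lo, hi = window
    if geometry.n != fm.n:
        raise ValueError("geometry and matrix sample counts differ")
    sel = (fm.feature_axis >= lo) & (fm.feature_axis <= hi)
    h, w = geometry.image_shape[-2], geometry.image_shape[-1]
    img = np.zeros((h, w))
    if not sel.any():
        warnings.warn(f"no features in window [{lo}, {hi}]; returning zeros")
        return img
    totals = fm.values[:, sel].sum(axis=1)
    img[geometry.positions[:, 1], geometry.positions[:, 0]] = totals
    return img


def read_contact_list(path, chromosome: str | None = None) -> SparseContacts:
    """Parse a whitespace/tab-delimited ``pos1 pos2 count`` contact list.

    Counts are retained as given (un-normalized). Malformed rows raise a
    parse error naming the line number.
    """
    p1, p2, ct = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                a, b, c = int(float(parts[0])), int(float(parts[1])), float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            p1.append(a)
            p2.append(b)
            ct.append(c)
    return SparseContacts(
        pos1=np.asarray(p1, dtype=np.int64),
        pos2=np.asarray(p2, dtype=np.int64),
        count=np.asarray(ct, dtype=float),
        chromosome=chromosome,
    )


def bin_contacts(
    contacts: SparseContacts, row_bin: int, col_bin: int, mirror: bool = True
) -> FeatureMatrix:
    """Additively bin sparse contacts into a dense loci-by-bins matrix.

    Rows are ``row_bin``-bp loci (the samples, e.g. 1 kb), columns are
    ``col_bin``-bp bins (the features, e.g. 50 kb); each contact
    ``(p1, p2, c)`` adds ``c`` at ``(p1 // row_bin, p2 // col_bin)``. With
    ``mirror`` on (the convention for intrachromosomal upper-triangle lists),
    off-diagonal contacts are also added at the transposed location; exact
    diagonal records are added once.
    """
    if row_bin <= 0 or col_bin <= 0:
        raise ValueError("bin sizes must be positive")
    if col_bin % row_bin != 0:
        raise ValueError("col_bin must be an integer multiple of row_bin")
    if len(contacts) == 0:
        return FeatureMatrix(
            values=np.zeros((0, 0)), feature_axis=np.zeros(0),
            sample_ids=[], axis_kind="bins",
        )
    r1 = contacts.pos1 // row_bin
    c1 = contacts.pos2 // col_bin
    rows = [r1]
    cols = [c1]
    cnts = [contacts.count]
    if mirror:
        off = contacts.pos1 != contacts.pos2
        rows.append(contacts.pos2[off] // row_bin)
        cols.append(contacts.pos1[off] // col_bin)
        cnts.append(contacts.count[off])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    cnts = np.concatenate(cnts)
    n = int(rows.max()) + 1
    p = int(cols.max()) + 1
    values = np.zeros((n, p))
    np.add.at(values, (rows, cols), cnts)
    return FeatureMatrix(
        values=values,
        feature_axis=np.arange(p, dtype=float) * col_bin,
        sample_ids=[str(i * row_bin) for i in range(n)],
        axis_kind="bins",
    )


def drop_zero(fm: FeatureMatrix) -> DropZeroResult:
    """Remove fully zero rows and columns, returning surviving index lists."""
    row_ok = np.flatnonzero(fm.values.any(axis=1))
    col_ok = np.flatnonzero(fm.values.any(axis=0))
    if len(row_ok) == 0 or len(col_ok) == 0:
        return DropZeroResult(None, row_ok, col_ok)
    out = FeatureMatrix(
        values=fm.values[np.ix_(row_ok, col_ok)],
        feature_axis=fm.feature_axis[col_ok],
        sample_ids=[fm.sample_ids[i] for i in row_ok],
        group_labels=None
        if fm.group_labels is None
        else [fm.group_labels[i] for i in row_ok],
        axis_kind=fm.axis_kind,
    )
    return DropZeroResult(out, row_ok, col_ok)


def read_annotation_table(path, delimiter: str = ",") -> AnnotationTable:
    """Read a ``name, mass, adduct`` annotation table (header row required)."""
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected columns name, mass, adduct")
    return AnnotationTable(
        names=[str(v) for v in df.iloc[:, 0]],
        masses=df.iloc[:, 1].to_numpy(dtype=float),
        adducts=[str(v) for v in df.iloc[:, 2]],
    )
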
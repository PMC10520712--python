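"""Spatial weight matrices: binary contiguity, row standardization, subsetting.

The binary geographical adjacency matrix W has W[i, j] = 1 when regions i
and j share a border and 0 otherwise, with a zero diagonal.  Row
standardization divides each nonzero row by its sum, which bounds the
admissible spatial-autoregressive parameter above by 1 and makes spatial
lags interpretable as neighbour averages.  Regions with no neighbours
("islands") keep all-zero rows and are reported, never silently rewired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import RegionMap


@dataclass
class SpatialWeights:
    """An n x n nonnegative weight matrix with a fixed region ordering."""

    matrix: np.ndarray
    region_order: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("weight matrix must be square")
        if m.shape[0] != len(self.region_order):
            raise ValueError("region_order length does not match matrix size")
        if len(set(self.region_order)) != len(self.region_order):
            raise ValueError("region_order contains duplicates")
        if (m < 0).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(np.diag(m)).max(initial=0.0) > 0:
            raise ValueError("weight matrix must have a zero diagonal")
        self.matrix = m
        self.region_order = tuple(self.region_order)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def islands(self) -> list[str]:
        """Regions with zero row sum (no neighbours)."""
        rs = self.matrix.sum(axis=1)
        return [r for r, s in zip(self.region_order, rs) if s == 0]

    def index_of(self, regions: list[str]) -> np.ndarray:
        pos = {r: i for i, r in enumerate(self.region_order)}
        missing = [r for r in regions if r not in pos]
        if missing:
            raise KeyError(f"unknown regions: {missing}")
        return np.array([pos[r] for r in regions], dtype=int)


def weights_from_edges(region_map: RegionMap) -> SpatialWeights:
    """Binary symmetric adjacency matrix from a region map's edge list.

    Duplicate edges are collapsed to a single 1 with a warning; an edge
    naming an unknown region raises.
    """
    n = region_map.n
    pos = {r: i for i, r in enumerate(region_map.region_ids)}
    m = np.zeros((n, n))
    seen: set[frozenset[str]] = set()
    dupes = 0
    for a, b in region_map.edges:
        key = frozenset((a, b))
        if key in seen:
            dupes += 1
        seen.add(key)
        i, j = pos[a], pos[b]
        m[i, j] = m[j, i] = 1.0
    if dupes:
        warnings.warn(f"{dupes} duplicate edge(s) collapsed", stacklevel=2)
    return SpatialWeights(matrix=m, region_order=region_map.region_ids, standardized=False)


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Divide each nonzero row by its sum; island rows stay zero (warned)."""
    rs = w.matrix.sum(axis=1)
    out = w.matrix.copy()
    nz = rs > 0
    out[nz] = out[nz] / rs[nz, None]
    sw = SpatialWeights(matrix=out, region_order=w.region_order, standardized=True)
    if sw.islands:
        warnings.warn(f"islands kept as zero rows: {sw.islands}", stacklevel=2)
    return sw


def subset_weights(w: SpatialWeights, regions: list[str]) -> SpatialWeights:
    """Principal submatrix over ``regions`` (in the given order).

    If the input was row-standardized the subset is re-standardized, which
    for a binary base matrix equals standardizing the binary submatrix.
    New islands created by the cut are reported via the warning in
    :func:`row_standardize`.
    """
    if len(regions) == 0:
        raise ValueError("empty region subset")
    idx = w.index_of(list(regions))
    sub = w.matrix[np.ix_(idx, idx)].copy()
    out = SpatialWeights(matrix=sub, region_order=tuple(regions), standardized=False)
    if w.standardized:
        # recover binary support, then re-standardize over surviving neighbours
        out = SpatialWeights(
            matrix=(sub > 0).astype(float), region_order=tuple(regions), standardized=False
        )
        return row_standardize(out)
    return out


def spectrum(w: SpatialWeights) -> np.ndarray:
    """Real eigenvalues of the weight matrix, ascending.

    A row-standardized matrix derived from a symmetric binary one is
    similar to a symmetric matrix, so its spectrum is real; tiny imaginary
    parts from the general solver are checked and dropped.
    """
    m = w.matrix
    if np.allclose(m, m.T):
        return np.linalg.eigvalsh(m)
    ev = np.linalg.eigvals(m)
    if np.abs(ev.imag).max(initial=0.0) > 1e-8:
        raise ValueError("weight matrix has genuinely complex eigenvalues")
    return np.sort(ev.real)


def rho_interval(w: SpatialWeights) -> tuple[float, float]:
    """Admissible open interval for the spatial parameter: (1/w_min, 1/w_max).

    For a connected row-standardized matrix the upper bound is exactly 1.
    """
    ev = spectrum(w)
    lo, hi = ev.min(), ev.max()
    if hi <= 0:
        raise ValueError("largest eigenvalue must be positive")
    lower = 1.0 / lo if lo < 0 else -np.inf
    return (lower, 1.0 / hi)


def read_edges_csv(path) -> list[tuple[str, str]]:
    """Read a two-column edge list CSV (header required)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("edge list CSV needs two columns")
    return [tuple(row) for row in df.iloc[:, :2].itertuples(index=False)]


def write_weights_csv(w: SpatialWeights, path) -> None:
    """Write a dense weight matrix CSV with the region order as header/index."""
    pd.DataFrame(w.matrix, index=list(w.region_order), columns=list(w.region_order)).to_csv(path)


def read_weights_csv(path) -> SpatialWeights:
    df = pd.read_csv(path, index_col=0)
    m = df.to_numpy(dtype=float)
    rs = m[m.sum(axis=1) > 0].sum(axis=1)
    standardized = bool(len(rs)) and bool(np.allclose(rs, 1.0))
    return SpatialWeights(matrix=m, region_order=tuple(df.columns), standardized=standardized)
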
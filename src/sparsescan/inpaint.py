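"""Fill non-acquired pixels of sparse elemental maps for presentation.

Sparse scans leave most pixels unmeasured; for display the gaps are
filled by interpolation from the acquired pixels (including any spare
points placed outside the mask). Three interpolating methods:

``nearest``   value of the nearest acquired pixel (ties broken toward
              the smallest row-major index);
``idw``       inverse-distance-squared weighted mean of the k nearest
              acquired pixels (default k = 8);
``harmonic``  solution of the discrete Laplace equation on the
              non-acquired pixels with the acquired ones as Dirichlet
              boundary data (smooth, parameter-free; bounded by the
              min/max of the acquired values).

Counts are in-painted as rates (counts/dwell) and rescaled, so maps
from variable-dwell scans in-paint consistently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .engine import XRF_SENTINEL, ScanRecord

__all__ = ["SparseElementMap", "inpaint_map", "sparse_map_from_record"]


@dataclass
class SparseElementMap:
    """A per-element count grid with a sentinel where not acquired."""

    counts: np.ndarray
    acquired: np.ndarray
    element: str = ""
    dwell: np.ndarray | float = 1.0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, float)
        self.acquired = np.asarray(self.acquired, bool)
        if self.counts.shape != self.acquired.shape:
            raise ValueError("counts and acquired grids must share a shape")
        if np.any(self.counts[self.acquired] < 0):
            raise ValueError("acquired counts must be >= 0")

    def rates(self) -> np.ndarray:
        dw = np.broadcast_to(np.asarray(self.dwell, float), self.counts.shape)
        out = np.zeros_like(self.counts)
        np.divide(self.counts, dw, out=out, where=self.acquired & (dw > 0))
        return out


def sparse_map_from_record(record: ScanRecord, element: str) -> SparseElementMap:
    grid = record.xrf[element]
    acquired = grid != XRF_SENTINEL
    counts = np.where(acquired, grid, 0.0)
    dwell = np.where(acquired, record.dwell_long, 1.0)
    return SparseElementMap(counts=counts, acquired=acquired, element=element, dwell=dwell)


def _nearest(values: np.ndarray, acquired: np.ndarray) -> np.ndarray:
    rows, cols = acquired.shape
    pts = np.argwhere(acquired)
    # order acquired points by row-major index so distance ties resolve
    # to the smallest index
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    tree = cKDTree(pts)
    unk = np.argwhere(~acquired)
    out = values.copy()
    if unk.size:
        k = min(4, len(pts))
        d, idx = tree.query(unk, k=k)
        d = np.atleast_2d(d.reshape(len(unk), -1))
        idx = np.atleast_2d(idx.reshape(len(unk), -1))
        best = np.empty(len(unk), int)
        for n in range(len(unk)):
            tie = np.isclose(d[n], d[n, 0])
            best[n] = idx[n, tie].min()
        out[~acquired] = values[pts[best, 0], pts[best, 1]]
    return out


def _idw(values: np.ndarray, acquired: np.ndarray, k: int = 8) -> np.ndarray:
    pts = np.argwhere(acquired)
    tree = cKDTree(pts)
    unk = np.argwhere(~acquired)
    out = values.copy()
    if unk.size:
        kk = min(k, len(pts))
        d, idx = tree.query(unk, k=kk)
        d = d.reshape(len(unk), kk)
        idx = idx.reshape(len(unk), kk)
        w = 1.0 / np.maximum(d, 1e-12) ** 2
        v = values[pts[idx, 0], pts[idx, 1]]
        out[~acquired] = (w * v).sum(axis=1) / w.sum(axis=1)
    return out


def _harmonic(values: np.ndarray, acquired: np.ndarray) -> np.ndarray:
    """Dirichlet problem for the 5-point Laplacian on unknown pixels.

    Image-edge unknowns use only their tangential neighbours (the
    ghost-cell linear-extrapolation closure), corner unknowns the mean
    of their two in-grid neighbours; every equation is then a convex
    combination of neighbours, so the discrete maximum principle holds
    and linear fields are reproduced exactly away from corners. If
    that edge closure would disconnect part of the unknown set from
    the data, the affected system falls back to the truncated-stencil
    (Neumann) closure.
    """
    rows, cols = acquired.shape
    unknown = ~acquired
    n = int(unknown.sum())
    if n == 0:
        return values.copy()
    num = -np.ones((rows, cols), np.int64)
    num[unknown] = np.arange(n)

    # The tangential edge closure couples border unknowns only to other
    # border pixels, so it is well-posed only if the border ring holds
    # at least one acquired pixel; otherwise close the border with the
    # truncated (Neumann) stencil, which ties it to the interior.
    ring = np.zeros((rows, cols), bool)
    ring[0, :] = ring[-1, :] = ring[:, 0] = ring[:, -1] = True
    neumann_ring = not np.any(acquired & ring)

    def build(neumann: bool):
        rows_i, cols_j, data, b = [], [], [], np.zeros(n)
        for (i, j), eq in np.ndenumerate(num):
            if eq < 0:
                continue
            nbrs_all = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
            in_grid = [(a, bb) for a, bb in nbrs_all if 0 <= a < rows and 0 <= bb < cols]
            if neumann or neumann_ring or len(in_grid) == 4:
                nbrs = in_grid
            elif len(in_grid) == 3:
                # edge: keep only the two tangential neighbours
                if i in (0, rows - 1):
                    nbrs = [(a, bb) for a, bb in in_grid if a == i]
                else:
                    nbrs = [(a, bb) for a, bb in in_grid if bb == j]
            else:
                nbrs = in_grid  # corner: mean of the two in-grid neighbours
            deg = len(nbrs)
            rows_i.append(eq)
            cols_j.append(eq)
            data.append(float(deg))
            for a, bb in nbrs:
                if unknown[a, bb]:
                    rows_i.append(eq)
                    cols_j.append(num[a, bb])
                    data.append(-1.0)
                else:
                    b[eq] += values[a, bb]
            if deg == 0:
                raise FloatingPointError("isolated unknown pixel")
        A = sparse.csr_matrix((data, (rows_i, cols_j)), shape=(n, n))
        return A, b

    out = values.copy()
    import warnings

    try:
        A, b = build(neumann=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            x = spsolve(A.tocsc(), b)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("singular edge-closure system")
    except (FloatingPointError, RuntimeError):
        A, b = build(neumann=True)
        x = spsolve(A.tocsc(), b)
    out[unknown] = x
    return out


def inpaint_map(smap: SparseElementMap, method: str = "harmonic", **params) -> np.ndarray:
    """In-paint a sparse element map; acquired pixels are returned
    unchanged (all methods interpolate)."""
    if not np.any(smap.acquired):
        raise ValueError("cannot in-paint a map with no acquired pixels")
    rates = smap.rates()
    if method == "nearest":
        filled = _nearest(rates, smap.acquired)
    elif method == "idw":
        filled = _idw(rates, smap.acquired, k=int(params.get("k", 8)))
    elif method == "harmonic":
        filled = _harmonic(rates, smap.acquired)
    else:
        raise ValueError(f"unknown in-painting method {method!r}")
    # rescale rates back to counts at a single presentation dwell; where a
    # pixel was acquired at that dwell already, its counts pass through
    # bit-exactly (ratio is exactly 1.0)
    dw = np.broadcast_to(np.asarray(smap.dwell, float), rates.shape)
    ref_dwell = float(np.max(dw[smap.acquired]))
    out = filled * ref_dwell
    out[smap.acquired] = smap.counts[smap.acquired] * (ref_dwell / dw[smap.acquired])
    return out
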
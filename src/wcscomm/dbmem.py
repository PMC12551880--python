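"""Distance-based Moran's eigenvector maps (dbMEM / PCNM).

A dbMEM basis is obtained by principal coordinates analysis of a
truncated pairwise distance matrix: distances larger than a threshold t
(the longest edge of the minimum spanning tree, so that the neighbour
graph stays connected) are replaced by 4t, and the eigenvectors with
positive eigenvalues form orthogonal spatial (or temporal) predictors
ordered from broad to fine scale.  Moran's I of each axis, computed with
the truncation-graph connectivity weights, quantifies that scale.

For site-month designs the basis is computed on the unique locations (or
months) and broadcast to observations, since axis scores are properties
of a location, not of an observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from wcscomm.ordination import pco

__all__ = ["EigenBasis", "mst_truncation_threshold", "dbmem_axes", "axis_scale_report"]


@dataclass
class EigenBasis:
    """A dbMEM eigenvector basis.

    Attributes
    ----------
    axes : DataFrame, points x axes
        Orthonormal eigenvector scores (columns MEM1, MEM2, ...).
    eigenvalues : ndarray
        Positive eigenvalues, descending.
    morans_i : ndarray
        Moran's I per axis under the truncation-graph weights.
    threshold : float
        Truncation distance t.
    coords : ndarray
        The (unique) point coordinates the basis was computed on.
    """

    axes: pd.DataFrame
    eigenvalues: np.ndarray
    morans_i: np.ndarray
    threshold: float
    coords: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def broadcast(self, point_index: np.ndarray | list[int]) -> pd.DataFrame:
        """Expand axis scores to observations via unique-point indices."""
        idx = np.asarray(point_index, dtype=int)
        return self.axes.iloc[idx].reset_index(drop=True)


def _as_coords(points) -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("points must be a 1-D sequence or a 2-D coordinate array")
    return arr


def mst_truncation_threshold(points) -> float:
    """Longest edge of the minimum spanning tree of the distance graph.

    This is the smallest truncation distance at which the neighbour graph
    connects every point (site or time) to every other.
    """
    coords = _as_coords(points)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    d = squareform(pdist(coords))
    if d.max() == 0:
        raise ValueError("all points are identical; no spanning distance exists")
    mst = minimum_spanning_tree(d)
    return float(mst.data.max())


def dbmem_axes(points, threshold: float | None = None) -> EigenBasis:
    """dbMEM basis for spatial coordinates or a 1-D time axis.

    Distances greater than ``threshold`` (default: the longest MST edge)
    are replaced by four times the threshold before PCO; only axes with
    positive eigenvalues are retained.
    """
    coords = _as_coords(points)
    n = coords.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points to build a basis, got {n}")
    d = squareform(pdist(coords))
    t = mst_truncation_threshold(coords) if threshold is None else float(threshold)
    if t <= 0:
        raise ValueError(f"truncation threshold must be positive, got {t}")

    truncated = np.where(d <= t, d, 4.0 * t)
    np.fill_diagonal(truncated, 0.0)
    ordination = pco(truncated)

    eigval = ordination.eigenvalues
    tol = np.abs(eigval).max() * 1e-10
    keep = eigval > tol
    lambdas = eigval[keep]
    # orthonormal eigenvectors: undo the sqrt(lambda) scaling of PCO scores
    vectors = ordination.scores[:, : lambdas.size] / np.sqrt(lambdas)

    w = ((d <= t) & (d > 0)).astype(float)
    morans = np.array([_morans_i(vectors[:, k], w) for k in range(lambdas.size)])

    axes = pd.DataFrame(
        vectors, columns=[f"MEM{i + 1}" for i in range(lambdas.size)]
    )
    return EigenBasis(
        axes=axes, eigenvalues=lambdas, morans_i=morans, threshold=t, coords=coords
    )


def _morans_i(x: np.ndarray, w: np.ndarray) -> float:
    z = x - x.mean()
    s0 = w.sum()
    denom = float(z @ z)
    if s0 == 0 or denom == 0:
        return float("nan")
    return float(len(x) / s0 * (z @ w @ z) / denom)


def axis_scale_report(basis: EigenBasis, variable) -> pd.DataFrame:
    """Long-format table of axis scores against an original variable.

    One row per (axis, point): plotting score against the coordinate or
    month shows the spatial/temporal scale each axis captures (broad
    trends first, finer oscillation later).
    """
    var = np.asarray(variable, dtype=float).ravel()
    if var.size != basis.axes.shape[0]:
        raise ValueError("variable length must match the number of points")
    frames = []
    for name in basis.axes.columns:
        frames.append(
            pd.DataFrame(
                {
                    "axis": name,
                    "point": np.arange(var.size),
                    "variable": var,
                    "score": basis.axes[name].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
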
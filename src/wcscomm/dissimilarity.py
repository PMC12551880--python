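"""Response-matrix transforms and zero-adjusted Bray-Curtis dissimilarity.

Monthly detection-rate matrices are square-root transformed to damp the
influence of hyper-abundant species, then converted to a zero-adjusted
Bray-Curtis dissimilarity matrix.  The zero adjustment (Clarke's dummy
species) appends a constant-valued column to every sample before computing
Bray-Curtis, so a pair of empty samples has dissimilarity 0 instead of
being undefined:

    BC_adj(x, y) = sum_i |x_i - y_i| / (sum_i (x_i + y_i) + 2 d)

The default adjustment d = 0.03 represents the smallest possible unit in a
monthly rate matrix, one detection in a 31-day month.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

DEFAULT_ADJUSTMENT = 0.03


def sqrt_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root of a non-negative abundance/rate matrix.

    Parameters
    ----------
    matrix : DataFrame
        Observations x species, all values >= 0.

    Returns
    -------
    DataFrame of the same shape, index and columns.
    """
    values = np.asarray(matrix, dtype=float)
    if np.any(values < 0):
        bad = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value at row {matrix.index[bad[0]]!r}, "
            f"column {matrix.columns[bad[1]]!r}; rates must be non-negative"
        )
    return pd.DataFrame(np.sqrt(values), index=matrix.index, columns=matrix.columns)


def zero_adjusted_bray_curtis(
    matrix: pd.DataFrame, d: float = DEFAULT_ADJUSTMENT
) -> DistanceMatrix:
    """Zero-adjusted Bray-Curtis dissimilarity among the rows of ``matrix``.

    Parameters
    ----------
    matrix : DataFrame
        Observations x species, values >= 0.  At least two rows.
    d : float
        Dummy-species value appended to every row.  ``d = 0`` gives the
        classical Bray-Curtis coefficient, which is undefined for a pair
        of all-zero rows.

    Returns
    -------
    skbio DistanceMatrix labelled by the row index (as strings).
    """
    if d < 0:
        raise ValueError(f"adjustment d must be non-negative, got {d}")
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if np.any(values < 0):
        raise ValueError("Bray-Curtis requires non-negative values")

    if d == 0:
        zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
        if zero_rows.size >= 2:
            names = [str(matrix.index[i]) for i in zero_rows]
            raise ValueError(
                "Bray-Curtis undefined for all-zero row pairs with d=0: "
                + ", ".join(names)
            )
        augmented = values
    else:
        dummy = np.full((values.shape[0], 1), float(d))
        augmented = np.hstack([values, dummy])

    condensed = pdist(augmented, metric="braycurtis")
    full = squareform(condensed)
    labels = [str(i) for i in matrix.index]
    return DistanceMatrix(full, ids=labels)
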
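"""Principal coordinates analysis and distance-based redundancy analysis.

PCO is the eigendecomposition of the Gower-centred matrix of -D^2/2.  A
dbRDA is an ordinary least squares multivariate regression of the PCO
axis scores on (centred) predictors; R^2 is the explained share of the
total positive inertia, adjusted with Ezekiel's formula, and significance
is assessed by row permutation (Freedman-Lane residual permutation when
conditioning predictors are present).

Negative PCO eigenvalues, which arise because Bray-Curtis matrices are
not fully Euclidean-embeddable, are reported but excluded from the score
space; no Lingoes/Cailliez correction is applied and total inertia is the
sum of the positive eigenvalues only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as scipy_qr
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "PcoOrdination",
    "DbrdaFit",
    "pco",
    "broken_stick",
    "nontrivial_axes",
    "dbrda",
    "species_vectors",
]

# eigenvalues below this fraction of the largest are treated as zero
_EIG_RTOL = 1e-10


@dataclass
class PcoOrdination:
    """Result of a principal coordinates analysis.

    Attributes
    ----------
    eigenvalues : ndarray
        All eigenvalues of the Gower-centred matrix, descending; may
        include negatives.
    scores : ndarray, shape (n_obs, n_positive)
        Site scores on the positive-eigenvalue axes, scaled by sqrt(lambda)
        so inter-row Euclidean distances reproduce the input distances
        when those are Euclidean-embeddable.
    percent_variation : ndarray
        Percent of total positive inertia per positive axis.
    labels : list of str
        Observation ids, in row order of ``scores``.
    """

    eigenvalues: np.ndarray
    scores: np.ndarray
    percent_variation: np.ndarray
    labels: list[str]

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    @property
    def total_inertia(self) -> float:
        """Sum of positive eigenvalues."""
        return float(self.percent_variation_denominator)

    @property
    def percent_variation_denominator(self) -> float:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return float(pos.sum())

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PCO{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


@dataclass
class DbrdaFit:
    """A fitted distance-based redundancy analysis."""

    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: float | None
    coefficients: pd.DataFrame  # predictors x PCO axes
    fitted: np.ndarray  # n_obs x n_axes fitted scores
    n_obs: int
    n_predictors: int
    ordination: PcoOrdination = field(repr=False)


def _gower_center(distances: np.ndarray) -> np.ndarray:
    a = -0.5 * distances**2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pco(dissim: DistanceMatrix | np.ndarray, labels: Sequence[str] | None = None) -> PcoOrdination:
    """Principal coordinates analysis of a symmetric dissimilarity matrix."""
    if isinstance(dissim, DistanceMatrix):
        d = dissim.data
        ids = list(dissim.ids)
    else:
        d = np.asarray(dissim, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        ids = list(labels) if labels is not None else [str(i) for i in range(d.shape[0])]

    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    tol = max(abs(eigval[0]), abs(eigval[-1])) * _EIG_RTOL if eigval.size else 0.0
    positive = eigval > tol
    scores = eigvec[:, positive] * np.sqrt(eigval[positive])
    pos_sum = eigval[positive].sum()
    pct = 100.0 * eigval[positive] / pos_sum if pos_sum > 0 else np.zeros(positive.sum())
    return PcoOrdination(
        eigenvalues=eigval, scores=scores, percent_variation=pct, labels=ids
    )


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected proportions for ``p`` ordered components.

    b_i = (1/p) * sum_{k=i..p} 1/k, descending; the proportions sum to 1.
    """
    if p < 1:
        raise ValueError(f"need at least one axis, got p={p}")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def _centered_design(x: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, pd.DataFrame):
        names = [str(c) for c in x.columns]
        arr = np.asarray(x, dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{i}" for i in range(arr.shape[1])]
    return arr - arr.mean(axis=0, keepdims=True), names


def _check_full_rank(xc: np.ndarray, names: list[str]) -> None:
    if xc.size == 0:
        return
    _, r, piv = scipy_qr(xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = (diag[0] if diag.size else 0.0) * max(xc.shape) * np.finfo(float).eps
    dependent = [names[piv[i]] for i in range(len(diag)) if diag[i] <= thresh]
    if xc.shape[1] > len(diag):
        dependent += [names[j] for j in piv[len(diag):]]
    if dependent:
        raise np.linalg.LinAlgError(
            "singular design; linearly dependent columns: " + ", ".join(dependent)
        )


def _projector(xc: np.ndarray) -> np.ndarray:
    """Rank-revealing orthonormal basis Q of a centred design (n x rank)."""
    if xc.size == 0:
        return np.empty((xc.shape[0], 0))
    q, r, _ = scipy_qr(xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(xc.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return q[:, :rank]


def ezekiel_adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _explained(q: np.ndarray, y: np.ndarray) -> float:
    proj = q.T @ y
    return float(np.sum(proj**2))


def dbrda(
    response: DistanceMatrix | PcoOrdination,
    predictors: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    condition: pd.DataFrame | np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
    strict: bool = True,
) -> DbrdaFit:
    """Distance-based redundancy analysis.

    Regresses all positive PCO axes of ``response`` on the mean-centred
    ``predictors``.  With ``condition`` given, the fit and the permutation
    test are partial: the statistic is the inertia explained by
    ``predictors`` over and above the conditioning columns, and the
    permutation scheme is Freedman-Lane (residuals of the reduced model
    are permuted).

    ``strict=True`` raises on a rank-deficient design, naming the
    dependent columns.  With ``strict=False`` aliased columns simply do
    not contribute (the fit projects onto the column space) and the
    degrees of freedom / adjusted R^2 penalty use the design rank, the
    convention of constrained-ordination software.

    Returns a :class:`DbrdaFit`; ``p_value`` is None when ``n_perm`` is 0.
    """
    ordination = response if isinstance(response, PcoOrdination) else pco(response)
    y = ordination.scores
    n = y.shape[0]
    total = float(np.sum(y**2))

    xc, names = _centered_design(predictors)
    if xc.shape[0] != n:
        raise ValueError(f"predictors have {xc.shape[0]} rows, response has {n}")

    if condition is not None:
        zc, znames = _centered_design(condition)
        if strict:
            _check_full_rank(np.hstack([zc, xc]), znames + names)
    else:
        zc = None
        if strict:
            _check_full_rank(xc, names)

    # effective dimensionalities from rank-revealing projections
    if condition is not None:
        q_z_rank = _projector(zc).shape[1]
        q_full_rank = _projector(np.hstack([zc, xc])).shape[1]
        p_z = q_z_rank
        p_x = q_full_rank - q_z_rank
    else:
        p_z = 0
        p_x = _projector(xc).shape[1]
    if p_x == 0:
        raise ValueError("predictors add no dimensions beyond the conditioning set")

    p_full = p_x + p_z
    if n <= p_full + 1:
        raise ValueError(
            f"need n > p + 1 for the pseudo-F denominator (n={n}, p={p_full})"
        )

    if condition is None:
        q_full = _projector(xc)
        expl_full = _explained(q_full, y)
        expl_x = expl_full
        r2 = expl_full / total
        coef, *_ = np.linalg.lstsq(xc, y, rcond=None)
        fitted = q_full @ (q_full.T @ y)
    else:
        q_z = _projector(zc)
        q_full = _projector(np.hstack([zc, xc]))
        expl_z = _explained(q_z, y)
        expl_full = _explained(q_full, y)
        expl_x = expl_full - expl_z
        r2 = expl_x / total
        design = np.hstack([zc, xc])
        coef_all, *_ = np.linalg.lstsq(design, y, rcond=None)
        coef = coef_all[p_z:]
        fitted = q_full @ (q_full.T @ y)

    adj_r2 = ezekiel_adjusted_r2(expl_full / total, n, p_full) if condition is None else (
        ezekiel_adjusted_r2(expl_full / total, n, p_full)
        - ezekiel_adjusted_r2(expl_z / total, n, p_z)
    )
    resid_full = total - expl_full
    if resid_full <= total * 1e-12:
        pseudo_f = float("inf")
    else:
        pseudo_f = (expl_x / p_x) / (resid_full / (n - p_full - 1))

    p_value = None
    if n_perm:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        exceed = 0
        if condition is None:
            for _ in range(n_perm):
                y_perm = y[rng.permutation(n)]
                e_full = _explained(q_full, y_perm)
                f_perm = (e_full / p_x) / ((total - e_full) / (n - p_full - 1))
                if f_perm >= pseudo_f - 1e-12:
                    exceed += 1
        else:
            fitted_z = q_z @ (q_z.T @ y)
            resid_z = y - fitted_z
            for _ in range(n_perm):
                y_perm = fitted_z + resid_z[rng.permutation(n)]
                tot_perm = float(np.sum((y_perm - y_perm.mean(axis=0)) ** 2))
                e_z = _explained(q_z, y_perm)
                e_full = _explained(q_full, y_perm)
                f_perm = ((e_full - e_z) / p_x) / (
                    (tot_perm - e_full) / (n - p_full - 1)
                )
                if f_perm >= pseudo_f - 1e-12:
                    exceed += 1
        p_value = (exceed + 1) / (n_perm + 1)

    axis_names = [f"PCO{i + 1}" for i in range(y.shape[1])]
    coef_df = pd.DataFrame(coef, index=names, columns=axis_names)
    return DbrdaFit(
        r2=float(r2),
        adj_r2=float(adj_r2),
        pseudo_f=float(pseudo_f),
        p_value=p_value,
        coefficients=coef_df,
        fitted=fitted,
        n_obs=n,
        n_predictors=p_x,
        ordination=ordination,
    )


def nontrivial_axes(
    species_matrix: pd.DataFrame,
    dissim_fn: Callable[[pd.DataFrame], DistanceMatrix],
    n_boot: int = 999,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    max_axes: int | None = None,
) -> pd.DataFrame:
    """Flag non-trivial PCO axes under four criteria.

    For the ordination of ``dissim_fn(species_matrix)`` each positive axis
    is assessed by:

    ``broken_stick``
        observed percent variation exceeds the broken-stick expectation.
    ``bootstrap``
        the lower 2.5% bootstrap bound of the axis' percent variation
        (rows resampled with replacement) still exceeds the broken-stick
        expectation.
    ``permutation``
        observed percent variation exceeds the (1 - alpha) quantile of
        percent variation under independent within-column permutations of
        the species matrix.
    ``conditional``
        as ``permutation`` but with percent variation computed as a share
        of the variation remaining after the previous axes.

    Returns a DataFrame indexed by axis with the observed percent
    variation and one boolean column per criterion.
    """
    if n_boot < 99 or n_perm < 99:
        raise ValueError("use at least 99 bootstrap and permutation replicates")
    n_rows = species_matrix.shape[0]
    if n_rows < 5:
        raise ValueError(f"resampling refused with fewer than 5 rows (got {n_rows})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obs = pco(dissim_fn(species_matrix))
    n_axes = obs.n_axes if max_axes is None else min(max_axes, obs.n_axes)
    pct = obs.percent_variation[:n_axes]
    bstick = 100.0 * broken_stick(obs.n_axes)[:n_axes]

    def _cond_share(pcts: np.ndarray, k: int) -> float:
        remaining = 100.0 - pcts[:k].sum()
        return pcts[k] / remaining * 100.0 if remaining > 0 else 0.0

    values = species_matrix.to_numpy(dtype=float)

    # permutation null: shuffle each species column independently
    perm_pct = np.zeros((n_perm, n_axes))
    for r in range(n_perm):
        shuffled = np.column_stack(
            [values[rng.permutation(n_rows), j] for j in range(values.shape[1])]
        )
        frame = pd.DataFrame(shuffled, index=species_matrix.index,
                             columns=species_matrix.columns)
        null = pco(dissim_fn(frame))
        pv = np.zeros(n_axes)
        m = min(n_axes, null.n_axes)
        pv[:m] = null.percent_variation[:m]
        perm_pct[r] = pv
    perm_crit = pct > np.quantile(perm_pct, 1 - alpha, axis=0)

    cond_obs = np.array([_cond_share(obs.percent_variation, k) for k in range(n_axes)])
    cond_null = np.zeros((n_perm, n_axes))
    for r in range(n_perm):
        for k in range(n_axes):
            cond_null[r, k] = _cond_share(perm_pct[r], k)
    cond_crit = cond_obs > np.quantile(cond_null, 1 - alpha, axis=0)

    # bootstrap: resample rows with replacement
    boot_pct = np.zeros((n_boot, n_axes))
    for r in range(n_boot):
        idx = rng.integers(0, n_rows, size=n_rows)
        frame = species_matrix.iloc[idx].reset_index(drop=True)
        boot = pco(dissim_fn(frame))
        pv = np.zeros(n_axes)
        m = min(n_axes, boot.n_axes)
        pv[:m] = boot.percent_variation[:m]
        boot_pct[r] = pv
    boot_lower = np.quantile(boot_pct, 0.025, axis=0)
    boot_crit = boot_lower > bstick

    return pd.DataFrame(
        {
            "percent_variation": pct,
            "broken_stick_expected": bstick,
            "broken_stick": pct > bstick,
            "bootstrap": boot_crit,
            "permutation": perm_crit,
            "conditional": cond_crit,
        },
        index=[f"PCO{i + 1}" for i in range(n_axes)],
    )


def species_vectors(
    species_matrix: pd.DataFrame, scores: pd.DataFrame | np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of each species with each retained axis.

    Species whose column is constant have no defined correlation and are
    omitted from the result.
    """
    s = np.asarray(scores, dtype=float)
    if isinstance(scores, pd.DataFrame):
        axis_names = [str(c) for c in scores.columns]
    else:
        axis_names = [f"PCO{i + 1}" for i in range(s.shape[1])]
    if species_matrix.shape[0] != s.shape[0]:
        raise ValueError("species matrix and scores must have matching rows")
    out = {}
    for sp in species_matrix.columns:
        col = species_matrix[sp].to_numpy(dtype=float)
        if np.std(col) == 0:
            continue
        out[sp] = [float(np.corrcoef(col, s[:, k])[0, 1]) for k in range(s.shape[1])]
    return pd.DataFrame(out, index=axis_names).T
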
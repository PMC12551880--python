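"""Predictive multivariate regression of principal coordinates (MRPC).

Retained PCO axes of the community dissimilarity matrix are regressed by
OLS on mean-centred predictors.  Spatial and temporal structure enters
through the raw UTM coordinates and the month index rather than through
eigenvector bases, because an eigenvector basis is data-specific: adding
a new, unbuilt site would change the basis and invalidate the fitted
coefficients, while raw coordinates extend to new sites directly.

Validation follows a drop-one-site scheme: all months of one structure
are removed, the dissimilarity -> PCO -> OLS pipeline is re-run on the
remaining observations, the dropped site-months are predicted, and five
Mantel correlations compare observed, fitted and predicted configurations:

    M1  observed distances (all obs)      vs full-model fitted distances
    M2  observed distances (training obs) vs drop-model fitted distances
    M3  observed distances (dropped obs)  vs predicted-score distances
    M4  full-model fitted distances of the dropped obs vs predicted
    M5  observed distances (all obs)      vs drop-model fitted + predicted

Mantel correlations are invariant to rotation or reflection of a score
set, so no Procrustes alignment is needed for M1-M5; alignment is only
used for plotting overlays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from wcscomm.dissimilarity import DEFAULT_ADJUSTMENT, sqrt_transform, zero_adjusted_bray_curtis
from wcscomm.ordination import PcoOrdination, _centered_design, _check_full_rank, pco

__all__ = [
    "MrpcModel",
    "mantel",
    "fit_mrpc",
    "predict_sites",
    "drop_one_site_cv",
    "residual_diagnostics",
    "assemblage_summary",
    "procrustes_overlay",
]


@dataclass
class MrpcModel:
    """OLS regression of retained PCO axes on centred predictors."""

    axes: list[str]
    coefficients: pd.DataFrame  # predictors x axes
    training_means: pd.Series
    training_ranges: pd.DataFrame  # predictors x (min, max)
    per_axis_r2: pd.Series
    training_scores: pd.DataFrame  # observed scores on retained axes
    fitted_scores: pd.DataFrame

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients.index)


def _as_distance(d) -> np.ndarray:
    if isinstance(d, DistanceMatrix):
        return d.data
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    return arr


def mantel(
    d1,
    d2,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """Mantel correlation between two distance matrices.

    Pearson correlation of the lower triangles; significance by joint
    row/column permutation of the second matrix with
    p = (exceedances + 1) / (n_perm + 1).  Returns ``(r, p)``; p is None
    when ``n_perm`` is 0.
    """
    a = _as_distance(d1)
    b = _as_distance(d2)
    if a.shape != b.shape:
        raise ValueError(f"distance matrices differ in size: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError(f"Mantel needs at least 3 observations, got {n}")
    tri = np.tril_indices(n, k=-1)
    x = a[tri]
    y = b[tri]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("a distance matrix is constant; Mantel r undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if not n_perm:
        return r, None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xc = x - x.mean()
    denom_x = np.sqrt(float(xc @ xc))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = b[np.ix_(perm, perm)][tri]
        ypc = yp - yp.mean()
        r_perm = float(xc @ ypc) / (denom_x * np.sqrt(float(ypc @ ypc)))
        if r_perm >= r - 1e-12:
            exceed += 1
    return r, (exceed + 1) / (n_perm + 1)


def fit_mrpc(
    ordination: PcoOrdination,
    retained_axes: int | list[str],
    predictors: pd.DataFrame,
) -> MrpcModel:
    """Fit per-axis OLS of retained PCO scores on centred predictors.

    PCO scores are column-centred by construction, so centring the
    predictors absorbs the intercept: a zero-predictor model fits every
    score at the (zero) response mean.
    """
    if isinstance(retained_axes, int):
        axes = [f"PCO{i + 1}" for i in range(retained_axes)]
    else:
        axes = list(retained_axes)
    scores = ordination.scores_frame()
    missing = [a for a in axes if a not in scores.columns]
    if missing:
        raise ValueError(f"ordination lacks axes {missing}")
    y = scores[axes].to_numpy()
    n = y.shape[0]
    if predictors.shape[0] != n:
        raise ValueError("predictor rows must match ordination observations")
    xc, names = _centered_design(predictors)
    if n <= xc.shape[1] + 1:
        raise ValueError(
            f"need n > p + 1 observations (n={n}, p={xc.shape[1]})"
        )
    _check_full_rank(xc, names)
    coef, *_ = np.linalg.lstsq(xc, y, rcond=None)
    fitted = xc @ coef
    sst = np.sum(y**2, axis=0)
    sse = np.sum((y - fitted) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, 0.0)
    means = pd.Series(
        np.asarray(predictors, dtype=float).mean(axis=0), index=names, name="mean"
    )
    ranges = pd.DataFrame(
        {
            "min": np.asarray(predictors, dtype=float).min(axis=0),
            "max": np.asarray(predictors, dtype=float).max(axis=0),
        },
        index=names,
    )
    return MrpcModel(
        axes=axes,
        coefficients=pd.DataFrame(coef, index=names, columns=axes),
        training_means=means,
        training_ranges=ranges,
        per_axis_r2=pd.Series(r2, index=axes, name="R2"),
        training_scores=scores[axes],
        fitted_scores=pd.DataFrame(fitted, index=scores.index, columns=axes),
    )


def predict_sites(model: MrpcModel, new_rows: pd.DataFrame) -> pd.DataFrame:
    """Predict retained-axis scores for new predictor rows.

    Rows are centred with the training means.  Predictors outside the
    training range trigger a warning (regression predictions should not
    be extrapolated) but are still computed.
    """
    missing = [p for p in model.predictors if p not in new_rows.columns]
    if missing:
        raise KeyError(f"new rows lack model predictors: {missing}")
    x = new_rows[model.predictors].to_numpy(dtype=float)
    lo = model.training_ranges["min"].to_numpy()
    hi = model.training_ranges["max"].to_numpy()
    outside = (x < lo) | (x > hi)
    if outside.any():
        cols = [model.predictors[j] for j in sorted(set(np.where(outside)[1]))]
        warnings.warn(
            f"predictors outside the training range: {cols}; "
            "extrapolated predictions are unreliable",
            UserWarning,
            stacklevel=2,
        )
    xc = x - model.training_means.to_numpy()
    scores = xc @ model.coefficients.to_numpy()
    return pd.DataFrame(scores, index=new_rows.index, columns=model.axes)


def _score_distance(scores: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(scores, dtype=float)))


def drop_one_site_cv(
    rates: pd.DataFrame,
    predictors: pd.DataFrame,
    n_axes: int,
    d: float = DEFAULT_ADJUSTMENT,
    n_perm: int = 0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Drop-one-site cross-validation with the five Mantel correlations.

    Parameters
    ----------
    rates : DataFrame
        (site_id, month)-indexed detection-rate matrix (untransformed).
    predictors : DataFrame
        Same row index; the numeric predictors of the MRPC model
        (raw coordinates, month index, screened covariates).
    n_axes : int
        Number of PCO axes retained, held fixed across drop models so
        score spaces stay comparable.
    n_perm : int
        Mantel permutations per correlation (0 skips p-values).

    Returns a DataFrame with one row per site: M1-M5 (and p-values when
    permuted) or a ``skipped`` reason.
    """
    sites = rates.index.get_level_values(0)
    unique_sites = list(pd.unique(sites))
    if len(unique_sites) < 3:
        raise ValueError(f"need at least 3 sites, got {len(unique_sites)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    transformed = sqrt_transform(rates)
    d_obs = zero_adjusted_bray_curtis(transformed, d=d).data
    ord_full = pco(d_obs, labels=[str(i) for i in range(len(rates))])
    n_axes = min(n_axes, ord_full.n_axes)
    full_model = fit_mrpc(ord_full, n_axes, predictors)
    full_fitted = full_model.fitted_scores.to_numpy()
    m1, m1_p = mantel(d_obs, _score_distance(full_fitted), n_perm=n_perm, seed=rng)

    rows = []
    for site in unique_sites:
        mask_drop = np.asarray(sites == site)
        n_drop = int(mask_drop.sum())
        if n_drop < 3:
            rows.append(
                {"site_id": site, "skipped": f"only {n_drop} months monitored"}
            )
            continue
        train = transformed[~mask_drop]
        d_train = zero_adjusted_bray_curtis(train, d=d).data
        ord_train = pco(d_train, labels=[str(i) for i in range(len(train))])
        k = min(n_axes, ord_train.n_axes)
        # removing a site can alias site-level covariates in the smaller
        # training design; drop such columns for this fold only
        from wcscomm.predictors import drop_aliased

        kept_cols, _ = drop_aliased(predictors[~mask_drop])
        model = fit_mrpc(ord_train, k, predictors.loc[~mask_drop, kept_cols])
        with warnings.catch_warnings():
            # a dropped site routinely sits at the edge of the training range
            warnings.simplefilter("ignore", UserWarning)
            predicted = predict_sites(model, predictors[mask_drop]).to_numpy()

        def _safe_mantel(a, b):
            try:
                return mantel(a, b, n_perm=n_perm, seed=rng)
            except ValueError:
                return float("nan"), float("nan")

        d_obs_drop = d_obs[np.ix_(mask_drop, mask_drop)]
        m2, m2_p = _safe_mantel(
            d_train, _score_distance(model.fitted_scores.to_numpy())
        )
        m3, m3_p = _safe_mantel(d_obs_drop, _score_distance(predicted))
        m4, m4_p = _safe_mantel(
            _score_distance(full_fitted[mask_drop][:, :k]),
            _score_distance(predicted),
        )
        combined = np.zeros((len(rates), k))
        combined[~mask_drop] = model.fitted_scores.to_numpy()
        combined[mask_drop] = predicted
        m5, m5_p = _safe_mantel(d_obs, _score_distance(combined))
        row = {
            "site_id": site,
            "skipped": "",
            "M1": m1,
            "M2": m2,
            "M3": m3,
            "M4": m4,
            "M5": m5,
        }
        if n_perm:
            row.update(
                {"M1_p": m1_p, "M2_p": m2_p, "M3_p": m3_p, "M4_p": m4_p, "M5_p": m5_p}
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_id")


def residual_diagnostics(
    residuals: pd.DataFrame,
    site_coords: pd.DataFrame,
    n_perm: int = 199,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Permutation-assumption diagnostics for the MRPC residuals.

    ``residuals`` is (site_id, month)-indexed with one column per
    retained axis; ``site_coords`` maps site_id -> (utm_x, utm_y).

    Returns per-axis residual autocorrelation (per site, averaged across
    sites, to lag min(10, floor(months/2))), a Mantel correlogram of
    residual distance against Sturges geographic distance classes with
    Holm-adjusted p-values, and fitted-free residual summaries.
    """
    from statsmodels.stats.multitest import multipletests

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = residuals.index.get_level_values(0)
    months_per_site = residuals.groupby(level=0).size()
    max_months = int(months_per_site.max())
    if max_months < 2:
        acf_table = None
    else:
        max_lag = min(10, max_months // 2)
        acf_rows = []
        for axis in residuals.columns:
            per_lag = {lag: [] for lag in range(1, max_lag + 1)}
            for site, grp in residuals[axis].groupby(level=0):
                series = grp.sort_index(level=1).to_numpy()
                z = series - series.mean()
                denom = float(z @ z)
                if denom == 0 or len(z) < 2:
                    continue
                for lag in range(1, min(max_lag, len(z) - 1) + 1):
                    per_lag[lag].append(float(z[lag:] @ z[:-lag]) / denom)
            for lag, vals in per_lag.items():
                if vals:
                    acf_rows.append(
                        {"axis": axis, "lag": lag, "acf": float(np.mean(vals))}
                    )
        acf_table = pd.DataFrame(acf_rows)

    coords = site_coords.loc[sites, ["utm_x", "utm_y"]].to_numpy(dtype=float)
    geo = _score_distance(coords)
    res_dist = _score_distance(residuals.to_numpy())
    n = geo.shape[0]
    tri = np.tril_indices(n, k=-1)
    pairs = geo[tri]
    n_classes = int(np.ceil(np.log2(pairs.size) + 1))  # Sturges
    edges = np.linspace(pairs.min(), pairs.max(), n_classes + 1)
    rows = []
    for c in range(n_classes):
        lo, hi = edges[c], edges[c + 1]
        inside = (pairs >= lo) & (pairs <= hi if c == n_classes - 1 else pairs < hi)
        if inside.sum() < 2 or inside.all():
            continue
        indicator = np.zeros_like(geo)
        mask_mat = np.zeros_like(geo, dtype=bool)
        mask_mat[tri] = inside
        indicator[mask_mat | mask_mat.T] = 1.0
        r, p = mantel(res_dist, indicator, n_perm=n_perm, seed=rng)
        rows.append({"class": c, "d_lo": lo, "d_hi": hi, "n_pairs": int(inside.sum()),
                     "mantel_r": r, "p_value": p})
    correlogram = pd.DataFrame(rows)
    if len(correlogram):
        correlogram["p_holm"] = multipletests(
            correlogram["p_value"], method="holm"
        )[1]
    return {"acf": acf_table, "correlogram": correlogram}


def assemblage_summary(
    predicted_scores: pd.DataFrame,
    training_scores: pd.DataFrame,
    species_matrix: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """Expected species profile at predicted positions in ordination space.

    Relative distance between site scores proxies similarity of species
    assemblages, so the profile at a predicted point is the
    inverse-distance-weighted mean of the transformed species rates of
    its k nearest training observations (exact match -> that
    observation's profile).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_train = training_scores.shape[0]
    if k > n_train:
        warnings.warn(
            f"k={k} exceeds {n_train} training observations; using k={n_train}",
            UserWarning,
            stacklevel=2,
        )
        k = n_train
    t = training_scores.to_numpy(dtype=float)
    sp = species_matrix.to_numpy(dtype=float)
    out = []
    for _, row in predicted_scores.iterrows():
        dist = np.sqrt(((t - row.to_numpy(dtype=float)) ** 2).sum(axis=1))
        nearest = np.argsort(dist, kind="stable")[:k]
        dn = dist[nearest]
        if np.any(dn == 0):
            weights = (dn == 0).astype(float)
        else:
            weights = 1.0 / dn
        weights = weights / weights.sum()
        out.append(weights @ sp[nearest])
    return pd.DataFrame(
        out, index=predicted_scores.index, columns=species_matrix.columns
    )


def procrustes_overlay(
    reference_scores: np.ndarray, target_scores: np.ndarray
) -> np.ndarray:
    """Orthogonal Procrustes rotation for plotting drop-model scores.

    Returns the rotation matrix mapping ``target_scores`` (fitted on the
    shared training observations) onto ``reference_scores``; apply it to
    predicted scores before overlaying them on the original ordination.
    """
    r, _ = orthogonal_procrustes(np.asarray(target_scores), np.asarray(reference_scores))
    return r
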
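"""Predictor assembly, screening and selection.

Covers the screening steps applied to crossing-structure predictors:
the openness ratio, log(x + 1) transforms for skewed covariates, dummy
coding of categoricals (substrate with water as the reference level,
catwalk as a single indicator), variance inflation factors, forward
selection by corrected AIC against a community dissimilarity response,
and PRESS-vs-SSE comparison of competing predictor sets.

The AICc used for selection is a distance-based analogue for ranking
only: AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1), where RSS is the
residual inertia of the Gower-centred response after regressing the PCO
axes on the current columns and k counts the predictor columns plus one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from wcscomm.ordination import PcoOrdination, _centered_design, _check_full_rank, _projector, pco

__all__ = [
    "compute_openness",
    "apply_skew_transforms",
    "encode_categoricals",
    "vif",
    "forward_select",
    "press_compare",
    "SelectionResult",
    "SKEWED_PREDICTORS",
]

# covariates the screening log(x+1)-transforms by default
SKEWED_PREDICTORS = [
    "openness",
    "fencing",
    "human_activity",
    "livestock_activity",
    "domestic_activity",
    "building_prop",
]


def compute_openness(height: float, width: float, length: float) -> float:
    """Openness ratio of a crossing structure: (height x width) / length (m)."""
    for name, v in (("height", height), ("width", width), ("length", length)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return height * width / length


def apply_skew_transforms(table: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """log(x + 1) transform the named columns; all others untouched."""
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise KeyError(f"column {col!r} not in table")
        vals = out[col].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError(f"column {col!r} has negative values; log1p undefined")
        out[col] = np.log1p(vals)
    return out


def encode_categoricals(
    table: pd.DataFrame,
    substrate_col: str = "substrate",
    catwalk_col: str = "catwalk",
    substrate_reference: str = "water",
    substrate_levels: tuple[str, ...] = ("concrete", "dirt"),
) -> pd.DataFrame:
    """Dummy-code substrate (reference level dropped) and catwalk.

    Substrate levels other than the reference become 0/1 indicator
    columns ``substrate_<level>``; catwalk becomes a single 0/1 column.
    Indicator columns are created for every level in ``substrate_levels``
    plus any extra observed level, so designs stay comparable across
    subsets of sites.
    """
    out = table.copy()
    if substrate_col in out.columns:
        observed = {str(l) for l in pd.unique(out[substrate_col])}
        levels = sorted((observed | set(substrate_levels)) - {substrate_reference})
        for level in levels:
            out[f"substrate_{level}"] = (
                out[substrate_col].astype(str) == level
            ).astype(float)
        out = out.drop(columns=[substrate_col])
    if catwalk_col in out.columns and out[catwalk_col].dtype == object:
        out[catwalk_col] = (
            out[catwalk_col].astype(str).str.lower().isin(["1", "true", "yes"])
        ).astype(float)
    return out


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1 / (1 - R^2_aux).

    R^2_aux comes from regressing the column on all other columns plus an
    intercept.  Exactly collinear designs raise, naming the columns.
    """
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValueError(f"need more rows than columns (n={n}, p={p})")
    names = [str(c) for c in design.columns]
    constant = [names[j] for j in range(p) if np.std(x[:, j]) == 0]
    if constant:
        raise ValueError("constant columns have no VIF: " + ", ".join(constant))
    xc = x - x.mean(axis=0, keepdims=True)
    _check_full_rank(xc, names)

    out = {}
    for j in range(p):
        yj = xc[:, j]
        others = np.delete(xc, j, axis=1)
        if others.shape[1] == 0:
            out[names[j]] = 1.0
            continue
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        r2 = 1.0 - float(resid @ resid) / float(yj @ yj)
        out[names[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def drop_aliased(design: pd.DataFrame, tol: float = 1e-9) -> tuple[list[str], list[str]]:
    """Split columns into (kept, dropped) so the kept set is full rank.

    Columns are scanned in order; a column is dropped when, after
    centring and scaling, it lies in the span of the columns already
    kept (relative residual norm below ``tol``).
    """
    kept: list[str] = []
    dropped: list[str] = []
    basis = np.empty((design.shape[0], 0))
    for col in design.columns:
        v = design[col].to_numpy(dtype=float)
        v = v - v.mean()
        norm = np.linalg.norm(v)
        if norm == 0:
            dropped.append(str(col))
            continue
        v = v / norm
        resid = v - basis @ (basis.T @ v)
        if np.linalg.norm(resid) < tol:
            dropped.append(str(col))
        else:
            kept.append(str(col))
            basis = np.hstack([basis, (resid / np.linalg.norm(resid))[:, None]])
    return kept, dropped


@dataclass
class SelectionResult:
    """Outcome of AICc forward selection."""

    selected: list[str]
    base: list[str]
    trace: pd.DataFrame = field(repr=False)  # step, candidate, aicc, accepted

    @property
    def columns(self) -> list[str]:
        return self.base + self.selected


def _response_scores(dissim: DistanceMatrix | PcoOrdination) -> np.ndarray:
    ordination = dissim if isinstance(dissim, PcoOrdination) else pco(dissim)
    return ordination.scores


def _rss(y: np.ndarray, xc: np.ndarray) -> float:
    total = float(np.sum(y**2))
    if xc.shape[1] == 0:
        return total
    q = _projector(xc)
    return total - float(np.sum((q.T @ y) ** 2))


def _aicc(y: np.ndarray, xc: np.ndarray) -> float:
    n = y.shape[0]
    k = xc.shape[1] + 1
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n}, k={k} leaves no residual df")
    rss = _rss(y, xc)
    if rss <= 0:
        return -np.inf
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def forward_select(
    dissim: DistanceMatrix | PcoOrdination,
    predictors: pd.DataFrame,
    candidates: list[str],
    base: list[str] | None = None,
) -> SelectionResult:
    """Greedy forward selection of predictor columns by AICc.

    ``base`` columns are locked into every model (used to condition the
    structural/environmental/anthropogenic selections on the spatial and
    temporal axes).  At each step the candidate that most lowers AICc is
    accepted; selection stops when no candidate lowers it.  Ties break by
    candidate order.
    """
    base = list(base or [])
    y = _response_scores(dissim)
    n = y.shape[0]
    if predictors.shape[0] != n:
        raise ValueError("predictor rows must match response observations")

    def design(cols: list[str]) -> np.ndarray:
        if not cols:
            return np.empty((n, 0))
        xc, _ = _centered_design(predictors[cols])
        return xc

    current = list(base)
    remaining = [c for c in candidates if c not in base]
    best_aicc = _aicc(y, design(current))
    rows = [{"step": 0, "candidate": "<base>", "aicc": best_aicc, "accepted": True}]
    step = 0
    while remaining:
        step += 1
        scores = []
        for cand in remaining:
            try:
                a = _aicc(y, design(current + [cand]))
            except (ValueError, np.linalg.LinAlgError):
                a = np.inf
            scores.append(a)
        j = int(np.argmin(scores))
        rows.append(
            {
                "step": step,
                "candidate": remaining[j],
                "aicc": scores[j],
                "accepted": scores[j] < best_aicc,
            }
        )
        if scores[j] < best_aicc:
            best_aicc = scores[j]
            current.append(remaining.pop(j))
        else:
            break
    return SelectionResult(
        selected=[c for c in current if c not in base],
        base=base,
        trace=pd.DataFrame(rows),
    )


def _press_sse(y: np.ndarray, xc: np.ndarray) -> tuple[float, float]:
    """(SSE, PRESS) for OLS of the PCO scores on a centred design.

    The model includes an implicit intercept (centring); leverages are
    h_ii = 1/n + diag(Xc (Xc'Xc)^-1 Xc').  PRESS uses the closed form
    e_i / (1 - h_ii) per axis.
    """
    n = y.shape[0]
    q = _projector(xc) if xc.shape[1] else np.empty((n, 0))
    h = 1.0 / n + np.sum(q**2, axis=1)
    if np.any(h >= 1.0 - 1e-12):
        bad = np.flatnonzero(h >= 1.0 - 1e-12)
        raise ValueError(f"leverage 1 at observations {bad.tolist()}; PRESS undefined")
    fitted = q @ (q.T @ y) if q.shape[1] else np.zeros_like(y)
    resid = y - fitted
    sse = float(np.sum(resid**2))
    press = float(np.sum((resid / (1.0 - h)[:, None]) ** 2))
    return sse, press


def press_compare(
    dissim: DistanceMatrix | PcoOrdination,
    predictors: pd.DataFrame,
    model_a: list[str],
    model_b: list[str],
    names: tuple[str, str] = ("A", "B"),
) -> dict:
    """Compare two predictor sets by the SSE-PRESS gap.

    A smaller |PRESS - SSE| indicates a model whose fit degrades less
    under leave-one-out deletion, i.e. less overfitting (the criterion
    used to drop one of a collinear fencing/traffic pair).
    """
    y = _response_scores(dissim)
    out = {}
    for name, cols in zip(names, (model_a, model_b)):
        xc, colnames = _centered_design(predictors[cols])
        _check_full_rank(xc, colnames)
        sse, press = _press_sse(y, xc)
        out[name] = {"SSE": sse, "PRESS": press, "gap": press - sse}
    preferred = min(names, key=lambda k: abs(out[k]["gap"]))
    out["preferred"] = preferred
    return out
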
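"""End-to-end orchestration: photos -> matrices -> models -> validation.

A run is driven by a :class:`RunConfig` (loadable from YAML), executes
the stages in order — event grouping, response matrices, dissimilarity,
dbMEM bases with AICc forward selection, predictor screening, variation
partitioning, the predictive MRPC model with drop-one-site validation —
and writes every artefact plus a JSON manifest to a run directory.  A
single seed fans out to per-stage child seeds so stages are
independently re-runnable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wcscomm import __version__
from wcscomm.dissimilarity import DEFAULT_ADJUSTMENT, sqrt_transform, zero_adjusted_bray_curtis
from wcscomm.dbmem import dbmem_axes
from wcscomm.events import build_response_matrices, group_independent_events
from wcscomm.ordination import nontrivial_axes, pco
from wcscomm.predictors import (
    SKEWED_PREDICTORS,
    apply_skew_transforms,
    drop_aliased,
    encode_categoricals,
    forward_select,
    vif,
)
from wcscomm.predictive import drop_one_site_cv, fit_mrpc, residual_diagnostics
from wcscomm.synthetic import MONTHLY_COVARIATES, SITE_COVARIATES
from wcscomm.varpart import partition

__all__ = ["RunConfig", "build_design", "run_pipeline", "make_report"]

PREDICTOR_SETS = {
    "structural": ["openness", "catwalk", "substrate_concrete", "substrate_dirt"],
    "environmental": ["natural_prop", "water_prop", "woody_prop", "precipitation"],
    "anthropogenic": [
        "speed_limit",
        "building_prop",
        "traffic",
        "human_activity",
        "domestic_activity",
        "livestock_activity",
    ],
}


@dataclass
class RunConfig:
    """Settings of one analysis run."""

    photos: str = ""
    site_covariates: str = ""
    monthly_covariates: str = ""
    out_dir: str = "run"
    category: str = "total"  # total | successful | failed
    gap_minutes: float = 30.0
    adjustment: float = DEFAULT_ADJUSTMENT
    skew_columns: list[str] = field(default_factory=lambda: list(SKEWED_PREDICTORS))
    exclude_period_labels: list[str] = field(default_factory=lambda: ["construction"])
    n_perm: int = 199
    n_boot: int = 199
    alpha: float = 0.05
    min_axes: int = 2
    cv_n_perm: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in ("total", "successful", "failed"):
            raise ValueError(f"unknown response category {self.category!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def child_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence([self.seed, stage]).generate_state(1)[0] % (2**31))


def build_design(
    sites: pd.DataFrame,
    monthly: pd.DataFrame,
    observations: pd.MultiIndex,
) -> pd.DataFrame:
    """Observation-level predictor table from site and monthly covariates.

    Joins the site covariates (including UTM coordinates and the
    dummy-coded categoricals) and monthly covariates onto the
    (site_id, month) observation index and adds ``month_index`` (months
    since the first observed month) as the raw temporal predictor.
    """
    site_part = encode_categoricals(sites)
    monthly_part = monthly.copy()
    monthly_part.index = pd.PeriodIndex(monthly_part.index, freq="M")
    obs = pd.DataFrame(index=observations)
    obs = obs.join(site_part, on=observations.names[0])
    obs = obs.join(monthly_part, on=observations.names[1])
    months = pd.PeriodIndex(observations.get_level_values(1), freq="M")
    first = months.min()
    obs["month_index"] = [(m - first).n for m in months]
    if obs.isna().any().any():
        bad = obs.columns[obs.isna().any()].tolist()
        raise ValueError(f"incomplete covariates after assembly: {bad}")
    return obs


def _select_mem_axes(dissim_ord, basis, obs_point_index, prefix: str):
    """Broadcast a dbMEM basis to observations and forward-select axes.

    Only axes with Moran's I above its null expectation -1/(n-1) are
    candidates (positive spatial/temporal autocorrelation), so the
    selected axes cannot saturate the between-location space and
    location-level covariates stay identifiable alongside them.
    """
    n_points = basis.coords.shape[0]
    keep = np.where(basis.morans_i > -1.0 / (n_points - 1))[0]
    if keep.size == 0:
        keep = np.array([0])
    broadcast = basis.broadcast(obs_point_index)
    broadcast.columns = [f"{prefix}{i + 1}" for i in range(broadcast.shape[1])]
    broadcast = broadcast.iloc[:, keep]
    sel = forward_select(dissim_ord, broadcast, list(broadcast.columns))
    cols = sel.selected if sel.selected else list(broadcast.columns[:1])
    return broadcast[cols].copy(), sel


def partition_workflow(
    rates: pd.DataFrame,
    sites: pd.DataFrame,
    monthly: pd.DataFrame,
    adjustment: float = DEFAULT_ADJUSTMENT,
    n_perm: int = 0,
    seed: int | None = None,
):
    """Dissimilarity -> dbMEM selection -> per-set screening -> partition.

    The screening mirrors the full pipeline: spatial and temporal dbMEM
    axes are forward-selected by AICc, then each measured predictor set
    (structural, environmental, anthropogenic) is forward-selected with
    the spatial and temporal axes locked in as a base, and the five
    resulting sets are partitioned.  Returns the
    :class:`~wcscomm.varpart.PartitionResult`.
    """
    ordination = pco(zero_adjusted_bray_curtis(sqrt_transform(rates), d=adjustment))
    design = build_design(sites, monthly, rates.index)
    site_codes, site_pos = np.unique(
        rates.index.get_level_values(0), return_inverse=True
    )
    coords = sites.loc[site_codes, ["utm_x", "utm_y"]].to_numpy()
    month_periods = pd.PeriodIndex(rates.index.get_level_values(1), freq="M")
    month_vals, month_pos = np.unique(month_periods.astype(int), return_inverse=True)
    spatial_basis = dbmem_axes(coords)
    temporal_basis = dbmem_axes(month_vals.astype(float) - month_vals.min())
    smem, _ = _select_mem_axes(ordination, spatial_basis, site_pos, "sMEM")
    tmem, _ = _select_mem_axes(ordination, temporal_basis, month_pos, "tMEM")
    smem.index = rates.index
    tmem.index = rates.index
    preds = pd.concat([smem, tmem, design], axis=1)
    base = list(smem.columns) + list(tmem.columns)
    sets = {"spatial": list(smem.columns), "temporal": list(tmem.columns)}
    for set_name, cols in PREDICTOR_SETS.items():
        cands = [c for c in cols if c in preds.columns and preds[c].std() > 0]
        sel = forward_select(ordination, preds[base + cands], cands, base=base)
        sets[set_name] = sel.selected if sel.selected else cands[:1]
    return partition(ordination, preds, sets, n_perm=n_perm, seed=seed)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write artefacts to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path, label in (
        (config.photos, "photos"),
        (config.site_covariates, "site covariates"),
        (config.monthly_covariates, "monthly covariates"),
    ):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{label} file not found: {path!r}")

    photos = pd.read_csv(config.photos)
    sites = pd.read_csv(config.site_covariates, index_col="site_id")
    monthly = pd.read_csv(config.monthly_covariates, index_col="month")

    # events and response matrices
    events = group_independent_events(photos, gap_minutes=config.gap_minutes)
    months = pd.PeriodIndex(pd.DatetimeIndex(events["start"]), freq="M")
    calendar = pd.DataFrame(
        [(s, m) for s in sites.index for m in pd.period_range(months.min(), months.max())],
        columns=["site_id", "month"],
    )
    matrices = build_response_matrices(
        events, calendar, exclude_period_labels=config.exclude_period_labels
    )
    events.to_csv(out / "events.csv", index=False)
    for cat, rm in matrices.items():
        rm.flat().to_csv(out / f"matrix_{cat}.csv")

    response = matrices[config.category]
    rates = response.data
    transformed = sqrt_transform(rates)
    dissim = zero_adjusted_bray_curtis(transformed, d=config.adjustment)
    pd.DataFrame(dissim.data, index=response.observation_ids,
                 columns=response.observation_ids).to_csv(out / "dissimilarity.csv")
    ordination = pco(dissim)

    # dbMEM bases on unique sites and months
    site_codes, site_pos = np.unique(
        rates.index.get_level_values(0), return_inverse=True
    )
    coords = sites.loc[site_codes, ["utm_x", "utm_y"]].to_numpy()
    month_periods = pd.PeriodIndex(rates.index.get_level_values(1), freq="M")
    month_vals, month_pos = np.unique(month_periods.astype(int), return_inverse=True)
    spatial_basis = dbmem_axes(coords)
    temporal_basis = dbmem_axes(month_vals.astype(float) - month_vals.min())
    spatial_axes, spatial_sel = _select_mem_axes(ordination, spatial_basis, site_pos, "sMEM")
    temporal_axes, temporal_sel = _select_mem_axes(
        ordination, temporal_basis, month_pos, "tMEM"
    )
    spatial_sel.trace.to_csv(out / "selection_spatial.csv", index=False)
    temporal_sel.trace.to_csv(out / "selection_temporal.csv", index=False)

    # predictor screening
    design = build_design(sites, monthly, rates.index)
    design = apply_skew_transforms(
        design, [c for c in config.skew_columns if c in design.columns]
    )
    spatial_axes.index = rates.index
    temporal_axes.index = rates.index
    base = pd.concat([spatial_axes, temporal_axes], axis=1)
    screened_sets: dict[str, list[str]] = {}
    selection_rows = []
    for set_name, cols in PREDICTOR_SETS.items():
        cols = [c for c in cols if c in design.columns and design[c].std() > 0]
        table = pd.concat([base, design[cols]], axis=1)
        sel = forward_select(ordination, table, cols, base=list(base.columns))
        screened_sets[set_name] = sel.selected if sel.selected else cols[:1]
        for _, r in sel.trace.iterrows():
            selection_rows.append({"set": set_name, **r.to_dict()})
    pd.DataFrame(selection_rows).to_csv(out / "selection_sets.csv", index=False)

    all_cols = [c for cols in screened_sets.values() for c in cols]
    vif_kept, _ = drop_aliased(pd.concat([base, design[all_cols]], axis=1))
    vif_table = vif(pd.concat([base, design], axis=1)[vif_kept])
    vif_table.to_csv(out / "vif.csv")

    # variation partitioning over the five sets
    predictor_table = pd.concat([base, design], axis=1)
    sets = {
        "spatial": list(spatial_axes.columns),
        "temporal": list(temporal_axes.columns),
        **screened_sets,
    }
    part = partition(
        dissim, predictor_table, sets, n_perm=config.n_perm,
        seed=config.child_seed(1),
    )
    part.to_frame().to_csv(out / "partition.csv", index=False)
    if part.set_tests is not None:
        part.set_tests.to_csv(out / "set_tests.csv", index=False)

    # predictive model on raw coordinates + month + screened covariates
    axis_flags = nontrivial_axes(
        transformed,
        lambda m: zero_adjusted_bray_curtis(m, d=config.adjustment),
        n_boot=config.n_boot,
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=config.child_seed(2),
        max_axes=min(8, ordination.n_axes),
    )
    axis_flags.to_csv(out / "axis_criteria.csv")
    n_axes = max(int(axis_flags["permutation"].sum()), config.min_axes)

    mrpc_cols = ["utm_x", "utm_y", "month_index"] + all_cols
    # aliased covariates (possible when few sites) cannot enter the OLS fit
    mrpc_cols, mrpc_dropped = drop_aliased(design[mrpc_cols])
    mrpc_design = design[mrpc_cols]
    model = fit_mrpc(ordination, n_axes, mrpc_design)
    model.coefficients.to_csv(out / "mrpc_coefficients.csv")
    model.per_axis_r2.to_csv(out / "mrpc_axis_r2.csv")
    with open(out / "model.json", "w") as fh:
        json.dump(
            {
                "axes": model.axes,
                "coefficients": model.coefficients.to_dict(),
                "training_means": model.training_means.to_dict(),
                "training_ranges": model.training_ranges.to_dict(),
                "per_axis_r2": model.per_axis_r2.to_dict(),
            },
            fh,
            indent=2,
        )

    cv = drop_one_site_cv(
        rates,
        mrpc_design,
        n_axes=n_axes,
        d=config.adjustment,
        n_perm=config.cv_n_perm,
        seed=config.child_seed(3),
    )
    cv.to_csv(out / "validation.csv")

    residuals = model.training_scores - model.fitted_scores
    residuals.index = rates.index
    diag = residual_diagnostics(
        residuals, sites, n_perm=config.n_perm, seed=config.child_seed(4)
    )
    if diag["acf"] is not None:
        diag["acf"].to_csv(out / "residual_acf.csv", index=False)
    diag["correlogram"].to_csv(out / "residual_correlogram.csv", index=False)

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "n_observations": int(len(rates)),
        "n_species": int(rates.shape[1]),
        "n_sites": int(len(site_codes)),
        "retained_axes": int(n_axes),
        "mrpc_predictors": mrpc_cols,
        "mrpc_dropped_aliased": mrpc_dropped,
        "selected": {
            "spatial": list(spatial_axes.columns),
            "temporal": list(temporal_axes.columns),
            **screened_sets,
        },
        "partition_total_explained": part.total_explained(),
        "partition_residual": part.residual,
        "mean_M3": float(cv["M3"].mean()) if "M3" in cv else None,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def make_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed (or partial) run."""
    run_dir = Path(run_dir)
    lines = [f"Run report: {run_dir}", "=" * 40]
    manifest_path = run_dir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"package version: {manifest['version']}")
        lines.append(f"observations: {manifest['n_observations']}  "
                     f"species: {manifest['n_species']}  sites: {manifest['n_sites']}")
        lines.append(f"retained PCO axes: {manifest['retained_axes']}")
        lines.append("selected predictors:")
        for k, v in manifest["selected"].items():
            lines.append(f"  {k}: {', '.join(v)}")
    else:
        lines.append("MISSING: manifest.json (incomplete run)")

    part_path = run_dir / "partition.csv"
    if part_path.exists():
        part = pd.read_csv(part_path)
        lines.append("")
        lines.append("variation partitioning (exclusive fractions):")
        for _, r in part.iterrows():
            lines.append(f"  {r['subset']:<40s} {r['fraction']: .4f}")
        total = part["fraction"].sum()
        lines.append(f"  fractions + residual sum: {total:.6f}")
    else:
        lines.append("MISSING: partition.csv")

    val_path = run_dir / "validation.csv"
    if val_path.exists():
        cv = pd.read_csv(val_path)
        lines.append("")
        lines.append("drop-one-site validation (Mantel correlations):")
        for _, r in cv.iterrows():
            if isinstance(r.get("skipped"), str) and r["skipped"]:
                lines.append(f"  {r['site_id']}: skipped ({r['skipped']})")
            else:
                lines.append(
                    f"  {r['site_id']}: M1={r['M1']:.3f} M2={r['M2']:.3f} "
                    f"M3={r['M3']:.3f} M4={r['M4']:.3f} M5={r['M5']:.3f}"
                )
    else:
        lines.append("MISSING: validation.csv")
    return "\n".join(lines)
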
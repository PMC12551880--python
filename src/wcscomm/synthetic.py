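"""Synthetic camera-trap data with known ground truth.

Emulates the monitoring design of the South Texas crossing-structure
study: 18 structures followed for roughly a year of months, a
medium-large mammal pool of ~20 species, site covariates drawn to match
the published predictor means and SDs, and monthly covariates
(precipitation, human/domestic/livestock activity).  Species counts per
site-month follow a log-linear rate model

    log rate[s, m, j] = a_j
        + sum_g  beta_g * (L[j, .] . z_g(s, m)) / sqrt(|g|)
        + beta_spat * G_j(s) + beta_temp * H_j(m)
        + u_s + v_m

with species loadings L on z-scored covariates of each predictor set g
(structural, environmental, anthropogenic), species-specific spatially
and temporally autocorrelated fields G, H (exponential covariance), and
shared site/month random intercepts u, v.  Counts are negative binomial
(Poisson in the zero-overdispersion limit).  Monthly counts are expanded
into photo records whose independent-event structure is recovered
exactly by the event-grouping rules (events > 30 min apart, photos of an
event < 30 min apart).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from wcscomm.events import CATEGORIES

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_site_covariates",
    "generate_monthly_covariates",
    "generate_counts",
    "generate_rate_matrix",
    "generate_photo_records",
    "month_calendar",
]

# published covariate moments (mean, SD); activity covariates are monthly
DEFAULT_COVARIATE_TARGETS: dict[str, tuple[float, float]] = {
    "openness": (0.338, 0.026),
    "fencing": (3371.544, 216.587),
    "natural_prop": (0.786, 0.171),
    "water_prop": (0.024, 0.003),
    "woody_prop": (0.171, 0.074),
    "precipitation": (48.955, 50.398),
    "speed_limit": (98.389, 6.873),
    "building_prop": (0.002, 0.007),
    "traffic": (3398.988, 2819.024),
    "human_activity": (6.467, 10.417),
    "domestic_activity": (6.818, 20.080),
    "livestock_activity": (1.305, 8.352),
}

SITE_COVARIATES = [
    "openness",
    "fencing",
    "natural_prop",
    "water_prop",
    "woody_prop",
    "speed_limit",
    "building_prop",
    "traffic",
]
MONTHLY_COVARIATES = [
    "precipitation",
    "human_activity",
    "domestic_activity",
    "livestock_activity",
]
_PROPORTIONS = {"natural_prop", "water_prop", "woody_prop", "building_prop"}
_NONNEGATIVE = {
    "precipitation",
    "human_activity",
    "domestic_activity",
    "livestock_activity",
    "traffic",
    "fencing",
    "openness",
    "speed_limit",
}

# covariate membership of the three measured predictor sets
SET_COVARIATES = {
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
class SimulationConfig:
    """Study-design and effect parameters of the generator.

    Effect sizes are log-rate-scale SD contributions per predictor set;
    ``overdispersion`` is the negative-binomial theta in
    Var = mu + theta mu^2 (0 = Poisson); ``spatial_range`` (m) and
    ``temporal_range`` (months) set the exponential-covariance ranges of
    the autocorrelated fields.
    """

    n_sites: int = 18
    n_months: int = 14
    n_species: int = 20
    covariate_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_TARGETS)
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "spatial": 0.3,
            "temporal": 0.3,
            "structural": 0.3,
            "environmental": 0.3,
            "anthropogenic": 0.3,
        }
    )
    overdispersion: float = 0.3
    spatial_range: float = 10000.0
    temporal_range: float = 3.0
    site_re_sd: float = 0.25
    month_re_sd: float = 0.25
    catwalk_freq: float = 0.4
    substrate_freqs: dict[str, float] = field(
        default_factory=lambda: {"water": 0.3, "concrete": 0.4, "dirt": 0.3}
    )
    bounding_box: tuple[tuple[float, float], tuple[float, float]] = (
        (600000.0, 660000.0),
        (2870000.0, 2930000.0),
    )
    species_intercept_mean: float = float(np.log(3.0))
    species_intercept_sd: float = 0.8
    species_intercepts: list[float] | None = None
    interaction_freqs: dict[str, float] = field(
        default_factory=lambda: {"A": 0.3, "B": 0.2, "C": 0.2, "D": 0.25, "E": 0.05}
    )
    start_month: str = "2018-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites < 4:
            raise ValueError(f"n_sites must be >= 4, got {self.n_sites}")
        if self.n_species < 2:
            raise ValueError(f"n_species must be >= 2, got {self.n_species}")
        if self.n_months < 1:
            raise ValueError(f"n_months must be >= 1, got {self.n_months}")
        for name, v in self.effect_sizes.items():
            if v < 0:
                raise ValueError(f"effect size {name!r} must be >= 0, got {v}")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        for name, (_, sd) in self.covariate_targets.items():
            if sd < 0:
                raise ValueError(f"SD target for {name!r} must be >= 0, got {sd}")
        freq_sum = sum(self.interaction_freqs.get(c, 0.0) for c in CATEGORIES)
        if not np.isclose(freq_sum, 1.0):
            raise ValueError("interaction code frequencies must sum to 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground-truth structure behind a generated count table."""

    species_loadings: pd.DataFrame  # species x covariate
    site_random_effects: pd.Series
    month_random_effects: pd.Series
    spatial_fields: pd.DataFrame  # site x species
    temporal_fields: pd.DataFrame  # month x species
    log_rates: pd.DataFrame  # (site, month) x species


def _site_ids(n: int) -> list[str]:
    return [f"WCS{i + 1:02d}" for i in range(n)]


def _species_ids(n: int) -> list[str]:
    return [f"sp{j + 1:02d}" for j in range(n)]


def month_calendar(config: SimulationConfig, sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full (site, month) monitoring calendar for the configured design."""
    months = pd.period_range(config.start_month, periods=config.n_months, freq="M")
    ids = list(sites.index) if sites is not None else _site_ids(config.n_sites)
    return pd.DataFrame(
        [(s, m) for s in ids for m in months], columns=["site_id", "month"]
    )


def generate_site_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw one covariate row per crossing structure.

    Numeric covariates are normal draws at the published mean/SD targets
    (proportions clipped to [0, 1], physical quantities to >= 0);
    substrate and catwalk are categorical draws at the configured
    frequencies; UTM coordinates are uniform in the bounding box.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    (x0, x1), (y0, y1) = config.bounding_box
    out = pd.DataFrame(index=pd.Index(_site_ids(n), name="site_id"))
    out["utm_x"] = rng.uniform(x0, x1, size=n)
    out["utm_y"] = rng.uniform(y0, y1, size=n)
    for name in SITE_COVARIATES:
        mean, sd = config.covariate_targets[name]
        draws = rng.normal(mean, sd, size=n)
        if name in _PROPORTIONS:
            draws = np.clip(draws, 0.0, 1.0)
        elif name in _NONNEGATIVE:
            draws = np.clip(draws, 0.0, None)
        out[name] = draws
    out["catwalk"] = (rng.uniform(size=n) < config.catwalk_freq).astype(int)
    levels = list(config.substrate_freqs)
    probs = np.array([config.substrate_freqs[l] for l in levels], dtype=float)
    out["substrate"] = rng.choice(levels, size=n, p=probs / probs.sum())
    return out


def generate_monthly_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Draw monthly covariates (precipitation and activity counts)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    months = pd.period_range(config.start_month, periods=config.n_months, freq="M")
    out = pd.DataFrame(index=pd.Index(months, name="month"))
    for name in MONTHLY_COVARIATES:
        mean, sd = config.covariate_targets[name]
        draws = np.clip(rng.normal(mean, sd, size=len(months)), 0.0, None)
        out[name] = draws
    return out


def _exp_gp(rng: np.random.Generator, dist: np.ndarray, rangep: float, size: int) -> np.ndarray:
    """Draw ``size`` unit-variance GP realisations with exp(-d/range) covariance."""
    if rangep <= 0:
        return rng.standard_normal((dist.shape[0], size))
    cov = np.exp(-dist / rangep)
    cov[np.diag_indices_from(cov)] += 1e-9
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((dist.shape[0], size))


def _zscore_design(
    sites: pd.DataFrame, monthly: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Site-month design of z-scored covariates used to build the signal."""
    months = list(monthly.index)
    idx = pd.MultiIndex.from_product(
        [list(sites.index), months], names=["site_id", "month"]
    )
    z = pd.DataFrame(index=idx)
    for name in SITE_COVARIATES:
        mean, sd = config.covariate_targets[name]
        vals = (sites[name] - mean) / sd if sd > 0 else sites[name] * 0.0
        z[name] = np.repeat(vals.to_numpy(), len(months))
    for name in MONTHLY_COVARIATES:
        mean, sd = config.covariate_targets[name]
        vals = (monthly[name] - mean) / sd if sd > 0 else monthly[name] * 0.0
        z[name] = np.tile(vals.to_numpy(), len(sites))
    p_cat = config.catwalk_freq
    denom = np.sqrt(p_cat * (1 - p_cat)) if 0 < p_cat < 1 else 1.0
    z["catwalk"] = np.repeat(
        ((sites["catwalk"] - p_cat) / denom).to_numpy(), len(months)
    )
    for level in ("concrete", "dirt"):
        p = config.substrate_freqs.get(level, 0.0)
        denom = np.sqrt(p * (1 - p)) if 0 < p < 1 else 1.0
        ind = (sites["substrate"].astype(str) == level).astype(float)
        z[f"substrate_{level}"] = np.repeat(((ind - p) / denom).to_numpy(), len(months))
    return z


def _log_rates(
    config: SimulationConfig,
    sites: pd.DataFrame,
    monthly: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    config.validate()
    species = _species_ids(config.n_species)
    z = _zscore_design(sites, monthly, config)
    covs = [c for cols in SET_COVARIATES.values() for c in cols]
    loadings = pd.DataFrame(
        rng.standard_normal((config.n_species, len(covs))), index=species, columns=covs
    )

    if config.species_intercepts is not None:
        intercepts = np.asarray(config.species_intercepts, dtype=float)
        if intercepts.size != config.n_species:
            raise ValueError("species_intercepts length must equal n_species")
    else:
        intercepts = rng.normal(
            config.species_intercept_mean, config.species_intercept_sd, config.n_species
        )

    coords = sites[["utm_x", "utm_y"]].to_numpy()
    site_dist = np.sqrt(
        ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    )
    months_idx = np.arange(config.n_months, dtype=float)
    month_dist = np.abs(months_idx[:, None] - months_idx[None, :])

    g_spat = _exp_gp(rng, site_dist, config.spatial_range, config.n_species)
    h_temp = _exp_gp(rng, month_dist, config.temporal_range, config.n_species)
    u_site = config.site_re_sd * _exp_gp(rng, site_dist, config.spatial_range, 1)[:, 0]
    v_month = config.month_re_sd * _exp_gp(rng, month_dist, config.temporal_range, 1)[:, 0]

    eta = np.tile(intercepts, (len(z), 1))
    for g, cols in SET_COVARIATES.items():
        beta = config.effect_sizes[g]
        if beta == 0:
            continue
        eta += beta * (z[cols].to_numpy() @ loadings[cols].to_numpy().T) / np.sqrt(len(cols))
    site_pos = np.repeat(np.arange(config.n_sites), config.n_months)
    month_pos = np.tile(np.arange(config.n_months), config.n_sites)
    eta += config.effect_sizes["spatial"] * g_spat[site_pos]
    eta += config.effect_sizes["temporal"] * h_temp[month_pos]
    eta += u_site[site_pos][:, None] + v_month[month_pos][:, None]

    log_rates = pd.DataFrame(eta, index=z.index, columns=species)
    truth = SyntheticTruth(
        species_loadings=loadings,
        site_random_effects=pd.Series(u_site, index=sites.index, name="site_re"),
        month_random_effects=pd.Series(
            v_month, index=monthly.index, name="month_re"
        ),
        spatial_fields=pd.DataFrame(g_spat, index=sites.index, columns=species),
        temporal_fields=pd.DataFrame(h_temp, index=monthly.index, columns=species),
        log_rates=log_rates,
    )
    return log_rates, truth


def generate_counts(
    config: SimulationConfig,
    sites: pd.DataFrame,
    monthly: pd.DataFrame,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Monthly event counts per (site, month) and species, plus the truth.

    Counts are negative binomial around the log-linear monthly mean
    exp(eta); ``overdispersion`` 0 gives the Poisson limit.
    """
    if len(monthly) != config.n_months or len(sites) != config.n_sites:
        raise ValueError("site/month tables do not match the configured design")
    rng = np.random.default_rng(config.seed + 2)
    log_rates, truth = _log_rates(config, sites, monthly, rng)
    mu = np.exp(log_rates.to_numpy())
    theta = config.overdispersion
    if theta == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / theta, scale=theta * mu)
        counts = rng.poisson(lam)
    table = pd.DataFrame(counts, index=log_rates.index, columns=log_rates.columns)
    return table, truth


def generate_rate_matrix(
    config: SimulationConfig,
    sites: pd.DataFrame,
    monthly: pd.DataFrame,
    noise_sd_fraction: float = 0.1,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Continuous detection-rate matrix with controlled relative noise.

    The signal is the monthly mean rate exp(eta); independent Gaussian
    noise with SD = ``noise_sd_fraction`` x SD(signal) is added per
    species column and the result clipped at zero.  Used for assessing
    predictive validity under a known signal-to-noise ratio, bypassing
    count sampling.
    """
    rng = np.random.default_rng(config.seed + 2)
    log_rates, truth = _log_rates(config, sites, monthly, rng)
    signal = np.exp(log_rates.to_numpy())
    sd = signal.std(axis=0, ddof=0)
    noise = rng.standard_normal(signal.shape) * (noise_sd_fraction * sd)
    rates = np.clip(signal + noise, 0.0, None)
    return pd.DataFrame(rates, index=log_rates.index, columns=log_rates.columns), truth


def generate_photo_records(
    counts: pd.DataFrame,
    config: SimulationConfig,
    construction_months: list | None = None,
) -> pd.DataFrame:
    """Expand monthly event counts into timestamped photo records.

    Each event occupies its own time slot within the month so that
    consecutive events of a species at a site are separated by more than
    30 minutes, while the 1-5 photos of one event span less than 30
    minutes.  Interaction codes are drawn per individual at the
    configured A-E frequencies and attached to the first photo of the
    event; photos in ``construction_months`` carry the period label
    ``"construction"`` and no codes (interactions not assessed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    construction = {pd.Period(m, freq="M") for m in (construction_months or [])}
    codes = list(CATEGORIES)
    probs = np.array([config.interaction_freqs[c] for c in codes], dtype=float)
    probs = probs / probs.sum()

    rows = []
    for (site, month), row in counts.iterrows():
        month = pd.Period(month, freq="M")
        month_start = month.to_timestamp()
        total_minutes = month.days_in_month * 24 * 60
        in_construction = month in construction
        for species, n_events in row.items():
            n_events = int(n_events)
            if n_events <= 0:
                continue
            slot = total_minutes / n_events
            if slot < 61:
                raise ValueError(
                    f"{n_events} events for {species} at {site} {month} cannot be "
                    "separated by >30 min within the month"
                )
            for i in range(n_events):
                start = i * slot + rng.uniform(0, slot - 60)
                n_photos = int(rng.integers(1, 6))
                offsets = np.sort(rng.uniform(0, 29, size=n_photos - 1))
                photo_minutes = np.concatenate([[0.0], offsets]) + start
                n_indiv = 1 + int(rng.poisson(0.2))
                event_codes = rng.choice(codes, size=n_indiv, p=probs)
                for k, minute in enumerate(photo_minutes):
                    rows.append(
                        {
                            "site_id": site,
                            "camera_id": f"{site}-C{1 + int(rng.integers(0, 2))}",
                            "timestamp": month_start + pd.Timedelta(minutes=float(minute)),
                            "species": species,
                            "n_individuals": n_indiv,
                            "interaction_codes": (
                                None
                                if in_construction
                                else (";".join(event_codes) if k == 0 else None)
                            ),
                            "period_label": "construction" if in_construction else "",
                        }
                    )
    photos = pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "camera_id",
            "timestamp",
            "species",
            "n_individuals",
            "interaction_codes",
            "period_label",
        ],
    )
    return photos.sort_values(["site_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )
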
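"""Synthetic generator: determinism, moments, count model, photo round-trip."""

import numpy as np
import pandas as pd
import pytest

from wcscomm.events import group_independent_events
from wcscomm.synthetic import (
    SimulationConfig,
    generate_counts,
    generate_monthly_covariates,
    generate_photo_records,
    generate_rate_matrix,
    generate_site_covariates,
)


class TestSiteCovariates:
    def test_same_seed_bit_identical(self, small_config):
        a = generate_site_covariates(small_config)
        b = generate_site_covariates(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_moments_converge_to_targets(self):
        cfg = SimulationConfig(n_sites=10000, seed=1)
        sites = generate_site_covariates(cfg)
        # unclipped covariates: standard-error bounds at n = 10000
        assert abs(sites["openness"].mean() - 0.338) < 0.01
        assert abs(sites["fencing"].mean() - 3371.544) < 3 * 216.587 / 100
        assert abs(sites["speed_limit"].std() - 6.873) < 0.3

    def test_zero_sd_target_gives_constant_column(self):
        cfg = SimulationConfig(seed=2)
        cfg.covariate_targets["speed_limit"] = (98.389, 0.0)
        sites = generate_site_covariates(cfg)
        assert (sites["speed_limit"] == 98.389).all()

    def test_proportions_clipped_to_unit_interval(self):
        cfg = SimulationConfig(n_sites=500, seed=3)
        sites = generate_site_covariates(cfg)
        for col in ("natural_prop", "water_prop", "woody_prop", "building_prop"):
            assert sites[col].between(0, 1).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_sites"):
            generate_site_covariates(SimulationConfig(n_sites=3))
        cfg = SimulationConfig()
        cfg.covariate_targets["openness"] = (0.3, -1.0)
        with pytest.raises(ValueError, match="SD target"):
            generate_site_covariates(cfg)
        cfg = SimulationConfig()
        cfg.effect_sizes["structural"] = -0.1
        with pytest.raises(ValueError, match="effect size"):
            generate_site_covariates(cfg)


class TestCounts:
    def test_null_model_is_poisson(self):
        cfg = SimulationConfig(
            n_sites=30,
            n_months=12,
            n_species=8,
            seed=4,
            effect_sizes={k: 0.0 for k in
                          ("spatial", "temporal", "structural", "environmental", "anthropogenic")},
            overdispersion=0.0,
            site_re_sd=0.0,
            month_re_sd=0.0,
        )
        sites = generate_site_covariates(cfg)
        monthly = generate_monthly_covariates(cfg)
        counts, _ = generate_counts(cfg, sites, monthly)
        ratios = counts.var(axis=0, ddof=1) / counts.mean(axis=0)
        # iid Poisson per species: variance/mean ratio near 1
        assert abs(float(ratios.mean()) - 1.0) < 0.15

    def test_overdispersion_inflates_variance(self, small_dataset):
        cfg = small_dataset["config"].with_(overdispersion=2.0, seed=9)
        counts, _ = generate_counts(cfg, small_dataset["sites"], small_dataset["monthly"])
        poisson_cfg = cfg.with_(overdispersion=0.0)
        base, _ = generate_counts(poisson_cfg, small_dataset["sites"], small_dataset["monthly"])
        assert counts.to_numpy().var() > base.to_numpy().var()

    def test_silent_species_column_retained_as_zeros(self, small_dataset):
        cfg = small_dataset["config"].with_(
            species_intercepts=[-np.inf] + [1.0] * (small_dataset["config"].n_species - 1)
        )
        counts, _ = generate_counts(cfg, small_dataset["sites"], small_dataset["monthly"])
        assert counts.shape[1] == cfg.n_species
        assert counts.iloc[:, 0].sum() == 0

    def test_truth_dimensions(self, small_dataset):
        truth = small_dataset["truth"]
        cfg = small_dataset["config"]
        assert truth.species_loadings.shape[0] == cfg.n_species
        assert len(truth.site_random_effects) == cfg.n_sites
        assert len(truth.month_random_effects) == cfg.n_months
        assert np.isfinite(truth.species_loadings.to_numpy()).all()

    def test_rate_matrix_noise_fraction(self, small_dataset):
        cfg = small_dataset["config"]
        clean, _ = generate_rate_matrix(
            cfg, small_dataset["sites"], small_dataset["monthly"], noise_sd_fraction=0.0
        )
        noisy, _ = generate_rate_matrix(
            cfg, small_dataset["sites"], small_dataset["monthly"], noise_sd_fraction=0.1
        )
        assert (clean.to_numpy() >= 0).all()
        resid = noisy.to_numpy() - clean.to_numpy()
        assert 0 < np.abs(resid).mean() < clean.to_numpy().std()


class TestPhotoRecords:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_event_counts_recovered_exactly(self, seed):
        cfg = SimulationConfig(n_sites=5, n_months=3, n_species=4, seed=seed)
        sites = generate_site_covariates(cfg)
        monthly = generate_monthly_covariates(cfg)
        counts, _ = generate_counts(cfg, sites, monthly)
        photos = generate_photo_records(counts, cfg)
        events = group_independent_events(photos)
        months = pd.PeriodIndex(pd.DatetimeIndex(events["start"]), freq="M")
        recovered = (
            events.assign(month=months)
            .groupby(["site_id", "month", "species"])
            .size()
        )
        for (site, month, sp), n in recovered.items():
            assert counts.loc[(site, month), sp] == n
        assert int(recovered.sum()) == int(counts.to_numpy().sum())

    def test_between_event_gaps_exceed_30_minutes(self):
        cfg = SimulationConfig(n_sites=4, n_months=2, n_species=3, seed=5)
        sites = generate_site_covariates(cfg)
        monthly = generate_monthly_covariates(cfg)
        counts, _ = generate_counts(cfg, sites, monthly)
        photos = generate_photo_records(counts, cfg)
        events = group_independent_events(photos)
        for (_, _), grp in events.groupby(["site_id", "species"]):
            grp = grp.sort_values("start")
            gaps = (
                grp["start"].iloc[1:].to_numpy() - grp["end"].iloc[:-1].to_numpy()
            ) / np.timedelta64(1, "m")
            assert (gaps > 30).all()

    def test_zero_counts_give_empty_record_set(self):
        cfg = SimulationConfig(n_sites=4, n_months=2, n_species=2, seed=6)
        idx = pd.MultiIndex.from_product(
            [["WCS01"], pd.period_range("2018-01", periods=1, freq="M")],
            names=["site_id", "month"],
        )
        counts = pd.DataFrame(0, index=idx, columns=["sp01", "sp02"])
        photos = generate_photo_records(counts, cfg)
        assert photos.empty

    def test_construction_months_lack_codes(self):
        cfg = SimulationConfig(n_sites=4, n_months=2, n_species=3, seed=7)
        sites = generate_site_covariates(cfg)
        monthly = generate_monthly_covariates(cfg)
        counts, _ = generate_counts(cfg, sites, monthly)
        photos = generate_photo_records(
            counts, cfg, construction_months=[cfg.start_month]
        )
        jan = photos[photos["period_label"] == "construction"]
        assert len(jan) > 0
        assert jan["interaction_codes"].isna().all()
        rest = photos[photos["period_label"] != "construction"]
        assert (rest["timestamp"].dt.to_period("M") != cfg.start_month).all() or rest.empty
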
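"""MRPC fitting, prediction, Mantel validation and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from wcscomm.dissimilarity import zero_adjusted_bray_curtis
from wcscomm.ordination import dbrda, pco
from wcscomm.predictive import (
    assemblage_summary,
    drop_one_site_cv,
    fit_mrpc,
    mantel,
    predict_sites,
    procrustes_overlay,
    residual_diagnostics,
)

from conftest import random_rate_matrix


def _ordination(seed=0, n=20, n_species=6):
    rng = np.random.default_rng(seed)
    m = random_rate_matrix(rng, n, n_species)
    return rng, pco(zero_adjusted_bray_curtis(m))


class TestMantel:
    def test_identity_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        d = squareform(pdist(rng.normal(size=(8, 2))))
        r, _ = mantel(d, d, n_perm=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        r, _ = mantel(d, 2 * d + 0.1 * (1 - np.eye(8)), n_perm=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_distribution(self):
        rng = np.random.default_rng(1)
        rs, rejections = [], 0
        for _ in range(100):
            d1 = squareform(pdist(rng.normal(size=(10, 2))))
            d2 = squareform(pdist(rng.normal(size=(10, 2))))
            r, p = mantel(d1, d2, n_perm=99, seed=rng)
            rs.append(r)
            rejections += p <= 0.05
        assert abs(float(np.mean(rs))) < 0.05
        assert rejections <= 12  # ~ alpha with binomial slack

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(2)
        d1 = squareform(pdist(rng.normal(size=(9, 3))))
        d2 = squareform(pdist(rng.normal(size=(9, 3))))
        r, _ = mantel(d1, d2, n_perm=0)
        ref_r, _, _ = skbio_mantel(
            DistanceMatrix(d1), DistanceMatrix(d2), permutations=0
        )
        assert r == pytest.approx(float(ref_r), abs=1e-12)

    def test_too_small_rejected(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="at least 3"):
            mantel(d, d, n_perm=0)


class TestFitPredict:
    def test_exact_interpolation_when_scores_linear(self):
        rng, ordn = _ordination(3)
        x = pd.DataFrame(rng.normal(size=(20, 2)), columns=["u", "v"])
        # overwrite scores with an exact linear map of the predictors
        xc = x - x.mean()
        ordn.scores[:, :2] = xc.to_numpy() @ np.array([[1.0, -0.5], [0.3, 2.0]])
        model = fit_mrpc(ordn, 2, x)
        assert np.allclose(
            model.fitted_scores.to_numpy(), ordn.scores[:, :2], atol=1e-8
        )
        assert model.per_axis_r2.to_numpy() == pytest.approx([1.0, 1.0], abs=1e-10)

    def test_zero_predictor_model_fits_centered_means(self):
        _, ordn = _ordination(4)
        model = fit_mrpc(ordn, 2, pd.DataFrame(index=range(20)))
        assert np.allclose(model.fitted_scores.to_numpy(), 0.0)

    def test_coefficient_recovery_within_two_se(self):
        rng = np.random.default_rng(5)
        n = 200
        x = pd.DataFrame(rng.normal(size=(n, 2)), columns=["u", "v"])
        b_true = np.array([[1.2], [-0.7]])
        noise = rng.normal(scale=0.3, size=(n, 1))
        points = (x - x.mean()).to_numpy() @ b_true + noise
        d = squareform(pdist(points))
        model = fit_mrpc(pco(d), 1, x)
        # score axis is defined up to sign
        est = model.coefficients.to_numpy()
        sign = np.sign(est[0, 0] * b_true[0, 0])
        se = 0.3 / np.sqrt(n)
        assert np.allclose(sign * est, b_true, atol=3 * se + 0.05)

    def test_predictions_reproduce_fitted_and_center(self):
        rng, ordn = _ordination(6)
        x = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = fit_mrpc(ordn, 2, x)
        pred = predict_sites(model, x.iloc[[4]])
        assert np.allclose(pred.to_numpy(), model.fitted_scores.iloc[[4]].to_numpy())
        at_mean = predict_sites(model, pd.DataFrame([x.mean()]))
        assert np.allclose(at_mean.to_numpy(), 0.0, atol=1e-12)

    def test_out_of_range_prediction_warns_but_returns(self):
        rng, ordn = _ordination(7)
        x = pd.DataFrame(rng.uniform(0, 1, size=(20, 1)), columns=["openness"])
        model = fit_mrpc(ordn, 1, x)
        with pytest.warns(UserWarning, match="openness"):
            out = predict_sites(model, pd.DataFrame({"openness": [5.0]}))
        assert np.isfinite(out.to_numpy()).all()

    def test_matches_dbrda_fitted_scores(self):
        rng, ordn = _ordination(8)
        x = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = fit_mrpc(ordn, ordn.n_axes, x)
        fit = dbrda(ordn, x, n_perm=0)
        assert np.allclose(model.fitted_scores.to_numpy(), fit.fitted, atol=1e-10)


class TestDropOneSiteCV:
    def _twin_dataset(self):
        # community structure driven by the predictors themselves, so the
        # drop model can genuinely recover the twin's months
        rng = np.random.default_rng(0)
        months = pd.period_range("2020-01", periods=6, freq="M")
        sites = ["T1", "T2", "A", "B", "C"]
        x_site = {s: rng.normal(size=2) for s in sites}
        x_site["T2"] = x_site["T1"]  # bit-identical twin covariates
        loadings = rng.normal(size=(3, 4))  # (p1, p2, month) x species
        rows, pred_rows = [], []
        for s in sites:
            for t in range(6):
                x = np.array([x_site[s][0], x_site[s][1], 0.4 * t])
                eta = 1.0 + x @ loadings + rng.normal(scale=0.02, size=4)
                rows.append(np.clip(eta, 0.05, None))
                pred_rows.append([x_site[s][0], x_site[s][1], t])
        idx = pd.MultiIndex.from_product([sites, months], names=["site_id", "month"])
        rates = pd.DataFrame(rows, index=idx, columns=[f"sp{j}" for j in range(4)])
        preds = pd.DataFrame(
            pred_rows, index=idx, columns=["p1", "p2", "month_index"]
        )
        return rates, preds

    def test_twin_site_is_well_predicted(self):
        rates, preds = self._twin_dataset()
        cv = drop_one_site_cv(rates, preds, n_axes=3)
        assert cv.loc["T2", "M3"] >= 0.9

    def test_m1_constant_across_sites(self):
        rates, preds = self._twin_dataset()
        cv = drop_one_site_cv(rates, preds, n_axes=3)
        assert cv["M1"].nunique() == 1
        assert cv[["M1", "M2", "M3", "M4", "M5"]].stack().between(-1, 1).all()

    def test_two_sites_refused(self):
        rates, preds = self._twin_dataset()
        keep = rates.index.get_level_values(0).isin(["T1", "A"])
        with pytest.raises(ValueError, match="3 sites"):
            drop_one_site_cv(rates[keep], preds[keep], n_axes=2)

    def test_short_site_recorded_as_skipped(self):
        rates, preds = self._twin_dataset()
        mask = ~(
            (rates.index.get_level_values(0) == "C")
            & (rates.index.get_level_values(1) > pd.Period("2020-02", freq="M"))
        )
        cv = drop_one_site_cv(rates[mask], preds[mask], n_axes=2)
        assert "months" in cv.loc["C", "skipped"]


class TestDiagnostics:
    def _residual_frame(self, series_by_site):
        months = pd.period_range("2020-01", periods=len(next(iter(series_by_site.values()))))
        idx = pd.MultiIndex.from_tuples(
            [(s, m) for s in series_by_site for m in months], names=["site_id", "month"]
        )
        vals = np.concatenate([series_by_site[s] for s in series_by_site])
        return pd.DataFrame({"PCO1": vals}, index=idx)

    def _coords(self, sites):
        rng = np.random.default_rng(42)
        return pd.DataFrame(
            rng.uniform(0, 1000, size=(len(sites), 2)),
            index=sites,
            columns=["utm_x", "utm_y"],
        )

    def test_iid_residuals_have_small_acf(self):
        rng = np.random.default_rng(1)
        series = {f"S{i}": rng.normal(size=24) for i in range(6)}
        diag = residual_diagnostics(
            self._residual_frame(series), self._coords(list(series)), n_perm=99
        )
        acf = diag["acf"]["acf"].to_numpy()
        assert (np.abs(acf) < 2 / np.sqrt(24 * 6)).mean() >= 0.7

    def test_planted_ar1_visible_at_lag_one(self):
        rng = np.random.default_rng(2)
        series = {}
        for i in range(6):
            e = rng.normal(size=40)
            x = np.zeros(40)
            for t in range(1, 40):
                x[t] = 0.8 * x[t - 1] + e[t]
            series[f"S{i}"] = x
        diag = residual_diagnostics(
            self._residual_frame(series), self._coords(list(series)), n_perm=99
        )
        lag1 = diag["acf"].query("lag == 1")["acf"].iloc[0]
        assert lag1 > 0.5

    def test_correlogram_uses_sturges_classes(self):
        rng = np.random.default_rng(3)
        series = {f"S{i}": rng.normal(size=6) for i in range(5)}
        frame = self._residual_frame(series)
        diag = residual_diagnostics(frame, self._coords(list(series)), n_perm=99)
        n = len(frame)
        sturges = int(np.ceil(np.log2(n * (n - 1) / 2) + 1))
        assert len(diag["correlogram"]) <= sturges
        assert "p_holm" in diag["correlogram"].columns


class TestAssemblageSummary:
    def test_coincident_point_returns_that_profile(self):
        train = pd.DataFrame({"PCO1": [0.0, 1.0, 2.0], "PCO2": [0.0, 1.0, 0.0]})
        species = pd.DataFrame(
            {"fox": [1.0, 2.0, 3.0], "coyote": [0.5, 0.1, 0.9]}
        )
        pred = pd.DataFrame({"PCO1": [1.0], "PCO2": [1.0]})
        out = assemblage_summary(pred, train, species, k=1)
        assert out.iloc[0].tolist() == [2.0, 0.1]

    def test_equidistant_neighbours_average(self):
        train = pd.DataFrame({"PCO1": [-1.0, 1.0], "PCO2": [0.0, 0.0]})
        species = pd.DataFrame({"fox": [1.0, 3.0]})
        pred = pd.DataFrame({"PCO1": [0.0], "PCO2": [0.0]})
        out = assemblage_summary(pred, train, species, k=2)
        assert out.iloc[0, 0] == pytest.approx(2.0, abs=1e-12)

    def test_profile_bounded_by_neighbourhood(self):
        rng = np.random.default_rng(4)
        train = pd.DataFrame(rng.normal(size=(12, 2)), columns=["PCO1", "PCO2"])
        species = pd.DataFrame(rng.uniform(size=(12, 3)), columns=list("abc"))
        pred = pd.DataFrame(rng.normal(size=(4, 2)), columns=["PCO1", "PCO2"])
        out = assemblage_summary(pred, train, species, k=5)
        assert (out.to_numpy() >= species.to_numpy().min(axis=0) - 1e-12).all()
        assert (out.to_numpy() <= species.to_numpy().max(axis=0) + 1e-12).all()

    def test_excess_k_clipped_with_warning(self):
        train = pd.DataFrame({"PCO1": [0.0, 1.0]})
        species = pd.DataFrame({"fox": [1.0, 2.0]})
        with pytest.warns(UserWarning, match="k="):
            assemblage_summary(pd.DataFrame({"PCO1": [0.5]}), train, species, k=10)


class TestProcrustesOverlay:
    def test_recovers_a_rotation(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(10, 2))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        target = ref @ rot.T
        r = procrustes_overlay(ref, target)
        assert np.allclose(target @ r, ref, atol=1e-10)
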
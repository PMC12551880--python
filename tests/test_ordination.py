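"""PCO, broken stick, dbRDA and axis-retention criteria."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from wcscomm.dissimilarity import zero_adjusted_bray_curtis
from wcscomm.ordination import (
    broken_stick,
    dbrda,
    ezekiel_adjusted_r2,
    nontrivial_axes,
    pco,
    species_vectors,
)

from conftest import random_rate_matrix


class TestPco:
    def test_two_points(self):
        # hand double-centering: one axis, lambda = d^2/2, scores +-d/2
        o = pco(np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert o.eigenvalues[0] == pytest.approx(4.5, abs=1e-12)
        assert sorted(o.scores.ravel()) == pytest.approx([-1.5, 1.5], abs=1e-12)

    def test_three_equidistant_points(self):
        # Gower matrix is 0.5 I - J/6: eigenvalues (1/2, 1/2, 0)
        d = np.ones((3, 3)) - np.eye(3)
        o = pco(d)
        assert o.eigenvalues == pytest.approx([0.5, 0.5, 0.0], abs=1e-12)

    def test_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(15, 2))
        d = squareform(pdist(points))
        o = pco(d)
        recon = squareform(pdist(o.scores))
        assert np.allclose(recon, d, atol=1e-8)

    def test_rejects_asymmetric_input(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pco(d)

    def test_matches_reference_implementation(self):
        # independent oracle: scikit-bio's PCoA on the same matrix
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(8)
        m = random_rate_matrix(rng, 9, 5)
        dm = zero_adjusted_bray_curtis(m, d=0.03)
        ours = pco(dm)
        ref = pcoa(dm, number_of_dimensions=ours.n_axes)
        pos = ours.eigenvalues[: ours.n_axes]
        assert np.allclose(pos, ref.eigvals.to_numpy()[: ours.n_axes], atol=1e-10)
        for k in range(ours.n_axes):
            ref_axis = ref.samples.iloc[:, k].to_numpy()
            assert np.allclose(np.abs(ours.scores[:, k]), np.abs(ref_axis), atol=1e-8)


class TestBrokenStick:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (1, [1.0]),
            (2, [0.75, 0.25]),
            (4, [0.5208333333333333, 0.2708333333333333, 0.14583333333333331, 0.0625]),
        ],
    )
    def test_closed_form(self, p, expected):
        assert broken_stick(p) == pytest.approx(expected, abs=1e-12)

    def test_sums_to_one_and_rejects_empty(self):
        assert broken_stick(17).sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            broken_stick(0)


class TestDbrda:
    def test_ezekiel_formula(self):
        assert ezekiel_adjusted_r2(0.5, 10, 3) == pytest.approx(0.25, abs=1e-12)

    def test_saturated_design_gives_r2_one(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(12, 2))
        d = squareform(pdist(points))
        fit = dbrda(d, pd.DataFrame(points, columns=["x", "y"]), n_perm=0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)

    def test_equals_rda_on_coordinates(self):
        # when D is Euclidean, dbRDA R^2 equals the multivariate OLS R^2
        # on the raw coordinates (computed independently here)
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(14, 3))
        d = squareform(pdist(coords))
        x = pd.DataFrame(rng.normal(size=(14, 2)), columns=["a", "b"])
        fit = dbrda(d, x, n_perm=0)
        yc = coords - coords.mean(axis=0)
        xc = np.asarray(x) - np.asarray(x).mean(axis=0)
        beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        r2_direct = np.sum((xc @ beta) ** 2) / np.sum(yc**2)
        assert fit.r2 == pytest.approx(r2_direct, abs=1e-10)

    def test_null_adjusted_r2_centers_on_zero(self):
        rng = np.random.default_rng(10)
        vals = []
        for _ in range(200):
            m = random_rate_matrix(rng, 40, 8)
            dm = zero_adjusted_bray_curtis(m)
            x = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
            vals.append(dbrda(dm, x, n_perm=0).adj_r2)
        assert abs(float(np.mean(vals))) < 0.02

    def test_adjusted_never_exceeds_raw(self):
        rng = np.random.default_rng(2)
        m = random_rate_matrix(rng, 25, 6)
        dm = zero_adjusted_bray_curtis(m)
        x = pd.DataFrame(rng.normal(size=(25, 4)))
        fit = dbrda(dm, x, n_perm=0)
        assert fit.adj_r2 < fit.r2

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(1)
        m = random_rate_matrix(rng, 12, 4)
        dm = zero_adjusted_bray_curtis(m)
        x = pd.DataFrame({"a": rng.normal(size=12)})
        x["copy_of_a"] = x["a"]
        with pytest.raises(np.linalg.LinAlgError, match="copy_of_a|a"):
            dbrda(dm, x, n_perm=0)

    def test_permutation_p_detects_real_structure(self):
        rng = np.random.default_rng(7)
        gradient = np.linspace(0, 1, 30)
        m = pd.DataFrame(
            np.outer(gradient, np.arange(1, 6)) + rng.normal(scale=0.05, size=(30, 5))
        ).clip(lower=0)
        dm = zero_adjusted_bray_curtis(m)
        fit = dbrda(dm, pd.DataFrame({"g": gradient}), n_perm=199, seed=1)
        assert fit.p_value == pytest.approx(1 / 200, abs=1e-12)


class TestNontrivialAxes:
    def _dissim(self, m):
        return zero_adjusted_bray_curtis(m, d=0.03)

    def test_dominant_gradient_flagged_noise_axis_not(self):
        rng = np.random.default_rng(0)
        gradient = np.linspace(0.1, 2.0, 24)
        m = pd.DataFrame(
            np.outer(gradient, [1, 2, 0.5, 1.5]) + rng.normal(scale=0.02, size=(24, 4))
        ).clip(lower=0)
        flags = nontrivial_axes(m, self._dissim, n_boot=99, n_perm=99, seed=1)
        assert bool(flags["permutation"].iloc[0])
        assert not bool(flags["permutation"].iloc[1])

    def test_pure_noise_rarely_flagged(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            m = pd.DataFrame(rng.lognormal(0, 0.3, size=(16, 6)))
            flags = nontrivial_axes(m, self._dissim, n_boot=99, n_perm=99, seed=seed)
            hits += int(flags["permutation"].iloc[0])
        assert hits <= 1  # >= 90% of runs flag nothing

    def test_broken_stick_column_is_deterministic(self):
        rng = np.random.default_rng(5)
        m = random_rate_matrix(rng, 12, 5)
        flags = nontrivial_axes(m, self._dissim, n_boot=99, n_perm=99, seed=0)
        expected = flags["percent_variation"] > flags["broken_stick_expected"]
        assert (flags["broken_stick"] == expected).all()

    def test_refuses_tiny_designs(self):
        m = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError, match="5 rows"):
            nontrivial_axes(m, self._dissim, n_boot=99, n_perm=99)


class TestSpeciesVectors:
    def test_correlations_and_constant_columns(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {"PCO1": rng.normal(size=10), "PCO2": rng.normal(size=10)}
        )
        species = pd.DataFrame(
            {
                "tracks_axis1": scores["PCO1"],
                "constant": np.ones(10),
                "noise": rng.normal(size=10),
            }
        )
        out = species_vectors(species, scores)
        assert out.loc["tracks_axis1", "PCO1"] == pytest.approx(1.0, abs=1e-12)
        assert "constant" not in out.index
        flipped = species_vectors(species, scores.assign(PCO1=-scores["PCO1"]))
        assert flipped.loc["tracks_axis1", "PCO1"] == pytest.approx(-1.0, abs=1e-12)
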
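"""Bioclim arithmetic, downscaling, PCA spaces, and SWD extraction."""

import numpy as np
import pandas as pd
import pytest

from alpshift import env as envmod
from alpshift import synthetic as syn
from alpshift.grids import Grid


def climate_from_series(tmean12, prec12, year=2000, half_range=3.0):
    """A 2x2-cell MonthlyClimate whose every cell follows the given series."""
    t = np.asarray(tmean12, dtype=float)[:, None, None] * np.ones((1, 2, 2))
    p = np.asarray(prec12, dtype=float)[:, None, None] * np.ones((1, 2, 2))
    return syn.MonthlyClimate(
        year=year, tmin=t - half_range, tmean=t, tmax=t + half_range, prec=p
    )


def bioclim_oracle(tmean, tmin, tmax, prec):
    """Direct arithmetic bioclim reference for a single 12-month series."""
    tmean, tmin, tmax, prec = map(np.asarray, (tmean, tmin, tmax, prec))
    q = lambda a: np.array([a[i] + a[(i + 1) % 12] + a[(i + 2) % 12] for i in range(12)])
    q_t, q_p = q(tmean) / 3.0, q(prec)
    out = {
        "bio1": tmean.mean(),
        "bio2": (tmax - tmin).mean(),
        "bio4": 100 * tmean.std(ddof=1),
        "bio5": tmax.max(),
        "bio6": tmin.min(),
        "bio7": tmax.max() - tmin.min(),
        "bio10": q_t[np.argmax(q_t)],
        "bio11": q_t[np.argmin(q_t)],
        "bio12": prec.sum(),
        "bio13": prec.max(),
        "bio14": prec.min(),
        "bio15": 100 * prec.std(ddof=1) / (prec.mean() + 1),
        "bio16": q_p[np.argmax(q_p)],
        "bio17": q_p[np.argmin(q_p)],
    }
    out["bio3"] = 100 * out["bio2"] / out["bio7"]
    return out


class TestBioclim:
    def test_constant_temperature_and_precip(self):
        mc = climate_from_series([10.0] * 12, [50.0] * 12)
        bio = envmod.compute_bioclim(mc)
        assert bio.layers["bio1"][0, 0] == pytest.approx(10.0)
        assert bio.layers["bio4"][0, 0] == pytest.approx(0.0)
        assert bio.layers["bio12"][0, 0] == pytest.approx(600.0)

    def test_alpine_series_against_hand_oracle(self):
        tmean = np.array([-5, -3, 0, 4, 9, 13, 15, 14, 10, 5, 0, -4], dtype=float)
        prec = np.array([60, 55, 70, 90, 120, 140, 150, 130, 100, 80, 70, 65], float)
        mc = climate_from_series(tmean, prec)
        bio = envmod.compute_bioclim(mc)
        oracle = bioclim_oracle(tmean, tmean - 3, tmean + 3, prec)
        for name, val in oracle.items():
            assert bio.layers[name][1, 1] == pytest.approx(val, abs=1e-9), name

    def test_random_series_oracle_equivalence(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            tmean = rng.normal(5, 8, 12)
            prec = rng.uniform(0, 200, 12)
            mc = climate_from_series(tmean, prec)
            bio = envmod.compute_bioclim(mc)
            for name, val in bioclim_oracle(tmean, tmean - 3, tmean + 3, prec).items():
                assert bio.layers[name][0, 0] == pytest.approx(val, abs=1e-9), name

    def test_default_set_excludes_hybrid_quarters(self):
        assert {"bio8", "bio9", "bio18", "bio19"}.isdisjoint(envmod.DEFAULT_BIOCLIM)

    def test_missing_month_rejected(self):
        mc = climate_from_series([1.0] * 12, [10.0] * 12)
        mc.tmean = mc.tmean[:11]
        with pytest.raises(ValueError):
            envmod.compute_bioclim(mc)


class TestGWR:
    def test_global_linear_model_recovered_exactly(self):
        rng = np.random.default_rng(0)
        cdem = Grid(rng.uniform(400, 3000, (12, 12)), cell_size=400.0)
        ctemp = cdem.like(20.0 - 0.0065 * cdem.values)
        fdem = Grid(rng.uniform(400, 3000, (24, 24)), cell_size=200.0)
        out = envmod.gwr_downscale(ctemp, cdem, fdem)
        np.testing.assert_allclose(out.values, 20.0 - 0.0065 * fdem.values, atol=1e-6)

    def test_constant_field_stays_constant(self):
        rng = np.random.default_rng(1)
        cdem = Grid(rng.uniform(400, 3000, (10, 10)), cell_size=300.0)
        fdem = Grid(rng.uniform(400, 3000, (20, 20)), cell_size=150.0)
        out = envmod.gwr_downscale(cdem.like(np.full((10, 10), 7.5)), cdem, fdem)
        np.testing.assert_allclose(out.values, 7.5, atol=1e-8)

    def test_matches_per_cell_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(2)
        cdem = Grid(rng.uniform(400, 3000, (8, 8)), cell_size=500.0)
        ctemp = cdem.like(rng.normal(size=(8, 8)) + 10 - 0.005 * cdem.values)
        fdem = Grid(rng.uniform(400, 3000, (10, 10)), cell_size=400.0)
        bw = 2 * cdem.cell_size
        out = envmod.gwr_downscale(ctemp, cdem, fdem, bandwidth=bw, cutoff_factor=1e9)

        cx, cy = np.meshgrid(cdem.x_coords(), cdem.y_coords())
        e, t = cdem.values.ravel(), ctemp.values.ravel()
        for i in [0, 4, 9]:
            for j in [0, 5, 9]:
                fx = fdem.origin[0] + (j + 0.5) * fdem.cell_size
                fy = fdem.origin[1] + (i + 0.5) * fdem.cell_size
                d2 = (cx.ravel() - fx) ** 2 + (cy.ravel() - fy) ** 2
                w = np.exp(-d2 / (2 * bw**2))
                X = np.column_stack([np.ones_like(e), e])
                beta = np.linalg.solve((X.T * w) @ X, (X.T * w) @ t)
                pred = beta[0] + beta[1] * fdem.values[i, j]
                assert out.values[i, j] == pytest.approx(pred, abs=1e-8)

    def test_large_bandwidth_reduces_to_global_ols(self):
        rng = np.random.default_rng(3)
        cdem = Grid(rng.uniform(400, 3000, (10, 10)), cell_size=300.0)
        ctemp = cdem.like(rng.normal(size=(10, 10)) + 15 - 0.004 * cdem.values)
        fdem = Grid(rng.uniform(400, 3000, (10, 10)), cell_size=300.0)
        out = envmod.gwr_downscale(ctemp, cdem, fdem, bandwidth=1e9, cutoff_factor=1e9)
        e, t = cdem.values.ravel(), ctemp.values.ravel()
        X = np.column_stack([np.ones_like(e), e])
        beta = np.linalg.lstsq(X, t, rcond=None)[0]
        np.testing.assert_allclose(
            out.values, beta[0] + beta[1] * fdem.values, atol=1e-6
        )


class TestBilinear:
    def test_constant_and_coincident_centres(self):
        coarse = Grid(np.full((5, 5), 3.3), cell_size=200.0)
        fine = Grid(np.zeros((10, 10)), cell_size=100.0)
        np.testing.assert_allclose(
            envmod.bilinear_downscale(coarse, fine).values, 3.3
        )
        rng = np.random.default_rng(4)
        coarse = Grid(rng.normal(size=(5, 5)), cell_size=200.0)
        same = Grid(np.zeros((5, 5)), cell_size=200.0)
        np.testing.assert_allclose(
            envmod.bilinear_downscale(coarse, same).values, coarse.values, atol=1e-12
        )

    def test_midpoint_of_four_corners(self):
        coarse = Grid(np.array([[0.0, 0.0], [10.0, 10.0]]), cell_size=100.0)
        # a 1-cell fine grid whose centre is the coarse 4-centre midpoint
        fine = Grid(np.zeros((2, 2)), cell_size=50.0, origin=(50.0, 50.0))
        out = envmod.bilinear_downscale(coarse, fine)
        mid = out.values.mean()
        assert mid == pytest.approx(5.0)


class TestPCA:
    def test_single_axis_of_variation(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=100)
        X = np.column_stack([t, 2 * t, -t])
        space = envmod.fit_env_pca(X)
        assert space.eigenvalues[0] / space.eigenvalues.sum() == pytest.approx(1.0)

    def test_loadings_orthonormal_and_variance_conserved(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
        space = envmod.fit_env_pca(X)
        gram = space.loadings.T @ space.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        assert space.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)
        assert np.all(np.diff(space.eigenvalues) <= 1e-12)

    def test_eigenvalues_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3))
        X = rng.normal(size=(200, 3)) @ A
        space = envmod.fit_env_pca(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ev = np.sort(np.linalg.eigvalsh(np.cov(Z.T)))[::-1]
        np.testing.assert_allclose(space.eigenvalues, ev, atol=1e-8)

    def test_projection_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 4))
        space = envmod.fit_env_pca(X)
        scores = envmod.project_pca(space, X, n_components=4)
        Z = scores @ space.loadings.T
        np.testing.assert_allclose(Z, (X - space.means) / space.sds, atol=1e-8)
        np.testing.assert_allclose(
            envmod.project_pca(space, space.means[None, :]), 0.0, atol=1e-10
        )

    def test_zero_variance_variable_dropped(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([rng.normal(size=30), np.full(30, 2.0), rng.normal(size=30)])
        with pytest.warns(UserWarning, match="zero-variance"):
            space = envmod.fit_env_pca(X, ["a", "b", "c"])
        assert space.columns == ["a", "c"]


class TestSWD:
    @pytest.fixture()
    def two_year_world(self, small_dem):
        clim = syn.make_climate_series(
            small_dem, [2000, 2010], warming_rate=0.1, noise_sd=0.0,
            prec_noise_frac=0.0, seed=1,
        )
        bioclim = {mc.year: envmod.compute_bioclim(mc) for mc in clim}
        mats = [
            b.stack(list(envmod.DEFAULT_BIOCLIM)).reshape(len(envmod.DEFAULT_BIOCLIM), -1).T
            for b in bioclim.values()
        ]
        pca = envmod.fit_env_pca(np.vstack(mats), list(envmod.DEFAULT_BIOCLIM))
        return clim, bioclim, pca

    def test_year_matched_extraction(self, small_dem, two_year_world):
        _, bioclim, pca = two_year_world
        x, y = small_dem.cell_center(5, 5)
        records = pd.DataFrame(
            {
                "species": ["a", "a"],
                "date": ["2000-07-01", "2010-07-01"],
                "x": [x, x],
                "y": [y, y],
                "elevation": [small_dem.values[5, 5]] * 2,
            }
        )
        swd = envmod.extract_swd(records, bioclim, pca, small_dem)
        assert len(swd) == 2
        # same place, different years under warming: different PC1 scores
        pc1 = swd.sort_values("year")["pc1"].to_numpy()
        assert pc1[0] != pytest.approx(pc1[1], abs=1e-9)

    def test_outside_grid_dropped(self, small_dem, two_year_world):
        _, bioclim, pca = two_year_world
        records = pd.DataFrame(
            {
                "species": ["a"],
                "date": ["2000-07-01"],
                "x": [-1e6],
                "y": [0.0],
                "elevation": [100.0],
            }
        )
        swd = envmod.extract_swd(records, bioclim, pca, small_dem)
        assert len(swd) == 0

    def test_background_counts_and_uniqueness(self, small_dem):
        bg = envmod.sample_background([2000, 2001, 2002], 50, small_dem, seed=3)
        assert len(bg) == 150
        for _, g in bg.groupby("year"):
            assert not g.duplicated(["x", "y"]).any()
        again = envmod.sample_background([2000, 2001, 2002], 50, small_dem, seed=3)
        pd.testing.assert_frame_equal(bg, again)

    def test_background_elevation_distribution_matches_dem(self):
        from scipy.stats import ks_2samp

        dem = syn.make_dem(64, 64, 100.0, seed=21)
        bg = envmod.sample_background([2000, 2001, 2002], 3000, dem, seed=4)
        ks = ks_2samp(bg["elevation"], dem.values.ravel()).statistic
        assert ks < 0.05
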
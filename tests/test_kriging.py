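"""Variogram estimation and ordinary kriging against a dense
linear-solve oracle, plus grid assembly and raster round-trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nrloss import (
    OrdinaryKriging,
    Raster,
    SimulationConfig,
    VariogramModel,
    build_grid,
    county_average,
    fit_variogram,
    generate_county_survey,
    read_ascii_grid,
    write_ascii_grid,
)
from nrloss.kriging import empirical_variogram, kriging_weights, ordinary_kriging
from nrloss.synthetic import _exponential_grf


class TestCountyAverage:
    def test_mean_and_sample_sd(self):
        raw = pd.DataFrame({"county_id": ["a", "a"], "x": [0, 0], "y": [0, 0],
                            "n_rate": [180.0, 220.0]})
        rec = county_average(raw)
        assert rec["mean_n_rate"].iloc[0] == 200.0
        assert rec["sd_n_rate"].iloc[0] == pytest.approx(np.std([180, 220], ddof=1))
        assert rec["n_farmers"].iloc[0] == 2

    def test_single_farmer_county_has_missing_sd(self):
        raw = pd.DataFrame({"county_id": ["a"], "x": [1.0], "y": [2.0],
                            "n_rate": [150.0]})
        rec = county_average(raw)
        assert rec["mean_n_rate"].iloc[0] == 150.0
        assert np.isnan(rec["sd_n_rate"].iloc[0])

    def test_full_scale_county_count(self):
        cfg = SimulationConfig(seed=1)
        assert len(generate_county_survey(cfg)) == 1050

    def test_nonpositive_rates_rejected(self):
        raw = pd.DataFrame({"county_id": ["a"], "x": [0], "y": [0], "n_rate": [-5.0]})
        with pytest.raises(ValueError):
            county_average(raw)


class TestVariogram:
    def test_semivariance_nondecreasing_and_zero_at_origin(self):
        for family in ("spherical", "exponential", "gaussian"):
            vg = VariogramModel(family, nugget=1.0, psill=4.0, range=10.0)
            h = np.linspace(0.0, 50.0, 200)
            g = vg(h)
            assert g[0] == 0.0
            assert np.all(np.diff(g[1:]) >= -1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel("exponential", -1.0, 1.0, 5.0)
        with pytest.raises(ValueError):
            VariogramModel("cubic", 0.0, 1.0, 5.0)

    def test_iid_field_fits_essentially_flat(self, rng):
        pts = rng.uniform(0, 100, size=(150, 2))
        vals = rng.normal(200, 30, size=150)
        rec = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "mean_n_rate": vals})
        vg = fit_variogram(rec)
        emp = empirical_variogram(pts, vals)
        # the model reaches most of its sill already at the first lag
        assert vg(np.array([emp["lag"].iloc[0]]))[0] >= 0.6 * vg.sill

    def test_exponential_range_recovered_within_factor_two(self):
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 100, size=(200, 2))
        true_range = 15.0
        z = _exponential_grf(rng, pts, true_range)
        rec = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1],
                            "mean_n_rate": 200.0 + 30.0 * z})
        vg = fit_variogram(rec, family="exponential")
        assert true_range / 2 <= vg.range <= true_range * 2

    def test_constant_rates_degenerate_with_warning(self):
        rec = pd.DataFrame({"x": np.arange(6.0), "y": np.zeros(6),
                            "mean_n_rate": np.full(6, 200.0)})
        with pytest.warns(UserWarning, match="constant"):
            vg = fit_variogram(rec)
        assert vg.sill == 0.0

    def test_too_few_or_coincident_counties_error(self):
        rec = pd.DataFrame({"x": [0.0] * 6, "y": [0.0] * 6,
                            "mean_n_rate": np.arange(6.0) + 100})
        with pytest.raises(ValueError, match="coincident"):
            fit_variogram(rec)
        with pytest.raises(ValueError, match="at least 5"):
            fit_variogram(rec.iloc[:3])


class TestOrdinaryKriging:
    VG = VariogramModel("exponential", nugget=0.0, psill=400.0, range=20.0)

    def _records(self, rng, n=5):
        return pd.DataFrame({
            "x": rng.uniform(0, 50, n),
            "y": rng.uniform(0, 50, n),
            "mean_n_rate": rng.uniform(150, 250, n),
        })

    def test_weights_sum_to_one(self, rng):
        rec = self._records(rng, 12)
        pts = rec[["x", "y"]].to_numpy()
        for target in rng.uniform(0, 50, size=(10, 2)):
            w, _ = kriging_weights(pts, target, self.VG)
            assert w.sum() == pytest.approx(1.0, abs=1e-8)

    def test_zero_nugget_is_exact_at_data(self, rng):
        rec = self._records(rng)
        preds = ordinary_kriging(rec, self.VG, rec[["x", "y"]].to_numpy())
        np.testing.assert_allclose(preds, rec["mean_n_rate"], atol=1e-8)

    def test_single_county_constant_surface(self):
        rec = pd.DataFrame({"x": [10.0], "y": [10.0], "mean_n_rate": [222.0]})
        preds = ordinary_kriging(rec, self.VG, np.array([[0.0, 0.0], [40.0, 40.0]]))
        assert np.allclose(preds, 222.0)

    def test_matches_dense_oracle_on_five_points(self, rng):
        """Neighborhood implementation vs. an independently assembled
        full kriging system solved densely in this test."""
        rec = self._records(rng, 5)
        pts = rec[["x", "y"]].to_numpy()
        vals = rec["mean_n_rate"].to_numpy()
        targets = rng.uniform(0, 50, size=(7, 2))
        preds = ordinary_kriging(rec, self.VG, targets, n_max=16)

        for t, target in enumerate(targets):
            n = len(pts)
            A = np.ones((n + 1, n + 1))
            for i in range(n):
                for j in range(n):
                    A[i, j] = self.VG(np.array([np.hypot(*(pts[i] - pts[j]))]))[0]
            A[n, n] = 0.0
            b = np.ones(n + 1)
            for i in range(n):
                b[i] = self.VG(np.array([np.hypot(*(pts[i] - target))]))[0]
            w = np.linalg.solve(A, b)[:n]
            assert preds[t] == pytest.approx(w @ vals, abs=1e-8)

    def test_duplicate_locations_error_or_jitter(self, rng):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.5], [3.0, 2.0]])
        y = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="duplicate"):
            OrdinaryKriging(variogram=self.VG).fit(X, y)
        ok = OrdinaryKriging(variogram=self.VG, on_duplicates="jitter").fit(X, y)
        assert np.isfinite(ok.predict(np.array([[0.5, 0.5]]))).all()


class TestBuildGrid:
    def test_constant_survey_gives_constant_rates(self, grid_stack):
        rec = pd.DataFrame({"county_id": [f"c{i}" for i in range(8)],
                            "x": np.linspace(1, 19, 8),
                            "y": np.linspace(2, 18, 8),
                            "mean_n_rate": np.full(8, 200.0)})
        vg = VariogramModel("exponential", 0.0, 100.0, 10.0)
        cells = build_grid(grid_stack, rec, vg)
        assert np.allclose(cells["n_rate"], 200.0, atol=1e-6)

    def test_cells_cover_mask_with_covariates_and_regions(self, grid_stack, survey):
        cells = build_grid(grid_stack, survey)
        assert len(cells) == int(grid_stack["mask"].data.sum())
        assert set(cells["region"]).issubset(
            {"North China", "North China Plain", "South China", "Southwest China"})
        assert (cells["n_rate"] >= 0).all()
        # covariates are read at cell centers
        r0 = cells.iloc[0]
        assert grid_stack["pH"].data[int(r0["row"]), int(r0["col"])] == r0["pH"]

    def test_kriging_beats_mean_fill_on_smooth_field(self):
        rng = np.random.default_rng(5)
        n_data, n_targ = 100, 80
        pts = rng.uniform(0, 100, size=(n_data + n_targ, 2))
        z = _exponential_grf(rng, pts, corr_range=25.0)
        field = 200.0 + 30.0 * z
        rec = pd.DataFrame({"x": pts[:n_data, 0], "y": pts[:n_data, 1],
                            "mean_n_rate": field[:n_data]})
        vg = fit_variogram(rec)
        preds = ordinary_kriging(rec, vg, pts[n_data:])
        rmse_krige = np.sqrt(np.mean((preds - field[n_data:]) ** 2))
        rmse_mean = np.sqrt(np.mean((field[:n_data].mean() - field[n_data:]) ** 2))
        assert rmse_krige < rmse_mean

    def test_misaligned_rasters_error(self, grid_stack, survey):
        import copy

        broken = copy.deepcopy(grid_stack)
        bad = broken.layers["pH"]
        broken.layers["pH"] = Raster(bad.data, xll=5.0, yll=0.0, cellsize=bad.cellsize)
        with pytest.raises(ValueError, match="pH"):
            build_grid(broken, survey)

    def test_empty_mask_warns_empty_frame(self, survey):
        stack_cfg = SimulationConfig(nx=6, ny=6, n_counties=5, seed=2)
        from nrloss import generate_grid

        stack = generate_grid(stack_cfg)
        stack.layers["mask"] = stack["mask"].copy_with(np.zeros((6, 6)))
        with pytest.warns(UserWarning, match="no active cells"):
            cells = build_grid(stack, survey)
        assert cells.empty


def test_raster_round_trip_bit_exact(tmp_path, grid_stack):
    layer = grid_stack["rainfall"]
    data = layer.data.copy()
    data[0, 0] = np.nan
    r = Raster(data, xll=3.25, yll=-7.5, cellsize=0.5, crs="EPSG:32650")
    path = write_ascii_grid(r, tmp_path / "layer.asc")
    back = read_ascii_grid(path)
    np.testing.assert_array_equal(back.data, r.data)
    assert (back.xll, back.yll, back.cellsize, back.crs) == (3.25, -7.5, 0.5, "EPSG:32650")
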
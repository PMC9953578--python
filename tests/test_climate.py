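import dataclasses

import numpy as np
import pytest
import xarray as xr

from resurvey import climate as clim
from resurvey import synth
from resurvey.cli import run_climate_pipeline


def field2d(values, x, y, name="t"):
    return xr.DataArray(
        np.asarray(values, dtype=float), dims=("y", "x"),
        coords={"y": np.asarray(y, float), "x": np.asarray(x, float)},
        name=name,
    )


def grid(nx=8, ny=8, spacing=1.0):
    return np.arange(nx) * spacing, np.arange(ny) * spacing


class TestRegrid:
    @pytest.mark.parametrize("method", ["patch_like", "bilinear"])
    def test_constant_field_preserved(self, method):
        x, y = grid()
        f = field2d(np.full((8, 8), 5.0), x, y)
        tx = np.linspace(0.3, 6.7, 13)
        out = clim.regrid(f, tx, tx, method=method)
        np.testing.assert_allclose(out.values, 5.0, atol=1e-12)

    @pytest.mark.parametrize("method", ["patch_like", "bilinear"])
    def test_linear_field_exact(self, method):
        x, y = grid()
        xx, yy = np.meshgrid(x, y)
        f = field2d(2 * xx + 3 * yy, x, y)
        tx = np.linspace(0.0, 7.0, 15)
        out = clim.regrid(f, tx, tx, method=method)
        txx, tyy = np.meshgrid(tx, tx)
        np.testing.assert_allclose(out.values, 2 * txx + 3 * tyy, atol=1e-9)

    def test_patch_beats_bilinear_on_quadratic(self):
        x, y = grid(10, 10)
        xx, yy = np.meshgrid(x, y)
        f = field2d(0.5 * xx**2 - 0.3 * yy**2 + 0.2 * xx * yy, x, y)
        tx = np.linspace(1.0, 8.0, 71)  # 10x refinement, interior
        txx, tyy = np.meshgrid(tx, tx)
        truth = 0.5 * txx**2 - 0.3 * tyy**2 + 0.2 * txx * tyy
        err_patch = np.abs(
            clim.regrid(f, tx, tx, method="patch_like").values - truth
        ).max()
        err_bilin = np.abs(
            clim.regrid(f, tx, tx, method="bilinear").values - truth
        ).max()
        assert err_patch < err_bilin

    def test_outside_domain_warns(self, caplog):
        x, y = grid(4, 4)
        f = field2d(np.zeros((4, 4)), x, y)
        with caplog.at_level("WARNING"):
            clim.regrid(f, np.array([-1.0, 5.0]), np.array([1.0]))
        assert "outside the source domain" in caplog.text

    def test_irregular_grid_rejected(self):
        f = field2d(np.zeros((3, 3)), [0, 1, 3], [0, 1, 2])
        with pytest.raises(ValueError, match="not regular"):
            clim.regrid(f, np.array([0.5]), np.array([0.5]))

    def test_unknown_method_rejected(self):
        x, y = grid(3, 3)
        f = field2d(np.zeros((3, 3)), x, y)
        with pytest.raises(ValueError):
            clim.regrid(f, x, y, method="nearest")


def monthly(values, years, x, y):
    return clim.monthly_grid(values, years, x, y)


def make_stack(nx=4, ny=4, years=range(2000, 2012), fill=0.0):
    years = list(years)
    vals = np.full((len(years), 12, ny, nx), fill)
    x, y = np.arange(nx) * 10.0, np.arange(ny) * 10.0
    return vals, years, x, y


class TestBias:
    def test_identity_relation(self):
        vals, years, x, y = make_stack()
        rng = np.random.default_rng(0)
        vals = vals + rng.normal(size=vals.shape)
        stack = monthly(vals, years, x, y)
        model = clim.fit_bias(stack, stack, years)
        np.testing.assert_allclose(model.slope.values, 1.0, atol=1e-10)
        np.testing.assert_allclose(model.intercept.values, 0.0, atol=1e-10)

    def test_exact_affine_relation(self):
        vals, years, x, y = make_stack()
        rng = np.random.default_rng(1)
        vals = vals + rng.normal(size=vals.shape)
        coarse = monthly(vals, years, x, y)
        fine = monthly(2 * vals + 1, years, x, y)
        model = clim.fit_bias(coarse, fine, years)
        np.testing.assert_allclose(model.slope.values, 2.0, atol=1e-10)
        np.testing.assert_allclose(model.intercept.values, 1.0, atol=1e-10)

    def test_too_few_years_rejected(self):
        vals, years, x, y = make_stack(years=range(2000, 2005))
        stack = monthly(vals, years, x, y)
        with pytest.raises(ValueError, match="overlap years"):
            clim.fit_bias(stack, stack, years)

    def test_zero_variance_falls_back_to_intercept(self, caplog):
        vals, years, x, y = make_stack(fill=3.0)
        coarse = monthly(vals, years, x, y)
        fine = monthly(vals + 4.0, years, x, y)
        with caplog.at_level("WARNING"):
            model = clim.fit_bias(coarse, fine, years)
        assert "zero predictor variance" in caplog.text
        np.testing.assert_allclose(model.slope.values, 0.0)
        np.testing.assert_allclose(model.intercept.values, 7.0)

    def test_noisy_slope_recovery_within_2se(self):
        rng = np.random.default_rng(5)
        n_years = 30
        years = list(range(1961, 1961 + n_years))
        vals, _, x, y = make_stack(years=years)
        coarse_anom = rng.normal(size=(n_years, 12, 1, 1)) * np.ones_like(vals)
        coarse = monthly(coarse_anom, years, x, y)
        noise = rng.normal(0, 0.1, size=vals.shape)
        fine = monthly(1.3 * coarse_anom + 0.5 + noise, years, x, y)
        model = clim.fit_bias(coarse, fine, years)
        # per-cell-month SE of the slope
        xc = coarse_anom - coarse_anom.mean(axis=0, keepdims=True)
        sxx = (xc**2).sum(axis=0)
        resid = (
            fine.values - model.slope.values * coarse.values
            - model.intercept.values
        )
        se = np.sqrt((resid**2).sum(axis=0) / (n_years - 2) / sxx)
        within = np.abs(model.slope.values - 1.3) <= 2 * se
        assert within.mean() >= 0.93

    def test_apply_identity_and_affine(self):
        vals, years, x, y = make_stack(fill=3.0)
        coarse = monthly(vals, years, x, y)
        ident = clim.BiasModel(
            slope=xr.ones_like(coarse.isel(year=0, drop=True)),
            intercept=xr.zeros_like(coarse.isel(year=0, drop=True)),
            overlap_years=tuple(years),
        )
        out = clim.apply_bias(coarse, ident)
        np.testing.assert_allclose(out.values, coarse.values)
        affine = clim.BiasModel(
            slope=2 * xr.ones_like(ident.slope),
            intercept=xr.ones_like(ident.slope),
            overlap_years=tuple(years),
        )
        out = clim.apply_bias(coarse, affine)
        np.testing.assert_allclose(out.values, 7.0)

    def test_splice_continuity(self):
        # corrected pre-splice series agrees with the fine data on the
        # overlap up to the regression residuals (zero here by construction)
        rng = np.random.default_rng(2)
        years = list(range(1941, 1991))
        vals = rng.normal(size=(len(years), 12, 4, 4))
        x, y = np.arange(4.0), np.arange(4.0)
        coarse = monthly(vals, years, x, y)
        fine = monthly(1.2 * vals - 0.7, years, x, y)
        model = clim.fit_bias(coarse, fine, range(1961, 1991))
        fused = clim.apply_bias(coarse, fine=fine, model=model,
                                splice_year=1961)
        corrected = model.slope * coarse + model.intercept
        np.testing.assert_allclose(
            fused.sel(year=slice(1941, 1960)).values,
            corrected.sel(year=slice(1941, 1960)).transpose(
                "year", "month", "y", "x").values,
            atol=1e-10,
        )
        np.testing.assert_allclose(
            fused.sel(year=slice(1961, 1990)).values,
            fine.sel(year=slice(1961, 1990)).values, atol=1e-10,
        )


class TestTemperatureIndex:
    def test_constant_series_every_index(self):
        vals, years, x, y = make_stack(fill=4.0)
        stack = monthly(vals, years, x, y)
        for name in clim.INDEX_MONTHS:
            out = clim.temperature_index(stack, name, [2005, 2006])
            np.testing.assert_allclose(out.values, 4.0)

    def test_spring_uses_exactly_march_to_june(self):
        vals, years, x, y = make_stack()
        vals = vals.copy()
        # value = month index; spring mean must be (3+4+5+6)/4
        for m in range(12):
            vals[:, m] = m + 1
        stack = monthly(vals, years, x, y)
        out = clim.temperature_index(stack, "spring", [2004])
        np.testing.assert_allclose(out.values, 4.5)
        assert clim.INDEX_MONTHS["spring"] == (3, 4, 5, 6)

    def test_winter_crosses_year_boundary(self):
        years = [2000, 2001]
        vals = np.zeros((2, 12, 1, 1))
        vals[0, 9:] = 10.0  # Oct-Dec 2000
        vals[1, :3] = 20.0  # Jan-Mar 2001
        stack = monthly(vals, years, [0.0], [0.0])
        out = clim.temperature_index(stack, "winter_half", [2001])
        np.testing.assert_allclose(out.values, 15.0)

    def test_incomplete_period_rejected(self):
        vals, years, x, y = make_stack()
        stack = monthly(vals, years, x, y)
        with pytest.raises(ValueError, match="missing"):
            clim.temperature_index(stack, "annual", [1990])

    def test_annual_is_mix_of_half_years(self):
        # on a year-constant series: annual = (summer + winter)/2 exactly
        rng = np.random.default_rng(3)
        month_vals = rng.normal(size=12)
        vals, years, x, y = make_stack()
        vals = vals + month_vals[None, :, None, None]
        stack = monthly(vals, years, x, y)
        annual = clim.temperature_index(stack, "annual", [2005])
        summer = clim.temperature_index(stack, "summer_half", [2005])
        winter = clim.temperature_index(stack, "winter_half", [2005])
        np.testing.assert_allclose(
            annual.values, (summer.values + winter.values) / 2, atol=1e-12
        )


class TestDownscale:
    def setup_fields(self):
        x, y = grid(6, 6, spacing=100.0)
        xx, yy = np.meshgrid(x, y)
        src_elev = field2d(1000.0 + 2.0 * yy, x, y, "elev")
        tx = np.linspace(0, 500, 21)
        txx, tyy = np.meshgrid(tx, tx)
        dem = field2d(1000.0 + 2.0 * tyy + 30 * np.sin(txx / 77), tx, tx, "elev")
        return src_elev, dem

    def test_pure_lapse_field_exact(self):
        src_elev, dem = self.setup_fields()
        gamma = -6.68
        f = (gamma * src_elev / 1000.0 + 3.0).rename("t")
        out = clim.downscale(f, src_elev, dem, gradient=gamma)
        np.testing.assert_allclose(
            out.values, gamma * dem.values / 1000.0 + 3.0, atol=1e-9
        )

    def test_elevation_difference_gives_gradient(self):
        src_elev, dem = self.setup_fields()
        gamma = -6.68
        f = (gamma * src_elev / 1000.0).rename("t")
        out = clim.downscale(f, src_elev, dem, gradient=gamma)
        hi = out.values[dem.values > 1900]
        lo = out.values[dem.values < 1100]
        # 1000 m of elevation -> -6.68 K by construction
        assert hi.mean() - lo.mean() == pytest.approx(
            gamma * (dem.values[dem.values > 1900].mean()
                     - dem.values[dem.values < 1100].mean()) / 1000.0,
            abs=1e-9,
        )

    def test_uniform_warming_shifts_exactly(self):
        src_elev, dem = self.setup_fields()
        rng = np.random.default_rng(0)
        f = field2d(
            rng.normal(size=src_elev.shape), src_elev["x"], src_elev["y"]
        )
        a = clim.downscale(f, src_elev, dem)
        b = clim.downscale(f + 1.76, src_elev, dem)
        np.testing.assert_allclose(b.values - a.values, 1.76, atol=1e-9)

    def test_positive_gradient_rejected(self):
        src_elev, dem = self.setup_fields()
        with pytest.raises(ValueError, match="negative"):
            clim.downscale(src_elev, src_elev, dem, gradient=1.0)


class TestScalars:
    def test_equivalent_shift_per_kelvin(self):
        assert clim.equivalent_shift(1.0, -6.68) == pytest.approx(149.70, abs=0.01)

    def test_equivalent_shift_observed_warming(self):
        assert clim.equivalent_shift(1.76, -6.68) == pytest.approx(263.47, abs=0.01)

    def test_zero_delta(self):
        assert clim.equivalent_shift(0.0) == 0.0

    def test_zero_gradient_rejected(self):
        with pytest.raises(ValueError):
            clim.equivalent_shift(1.0, 0.0)

    def test_glacier_change_printed_areas(self):
        assert clim.glacier_change(26.8, 8.4) == pytest.approx(68.657, abs=1e-3)

    def test_glacier_change_trivial(self):
        assert clim.glacier_change(10, 10) == 0.0
        assert clim.glacier_change(10, 5) == 50.0
        assert clim.glacier_change(10, 12) == pytest.approx(-20.0)

    def test_zone_means(self):
        x = np.arange(3) * 1.0
        dem = field2d([[1000, 1500, 2000]] * 3, x, x, "elev")
        f = field2d([[1.0, 2.0, 3.0]] * 3, x, x)
        zm = clim.zone_means(f, dem, [(900, 1100), (900, 2100)])
        assert zm["900-1100"] == pytest.approx(1.0)
        assert zm["900-2100"] == pytest.approx(2.0)
        with pytest.raises(ValueError, match="empty"):
            clim.zone_means(f, dem, [(5000, 6000)])

    def test_zone_mean_of_lapse_field_closed_form(self):
        x = np.arange(5) * 1.0
        elev = np.linspace(1900, 2000, 25).reshape(5, 5)
        dem = field2d(elev, x, x, "elev")
        gamma = -6.68
        f = field2d(gamma * elev / 1000.0 + 2.0, x, x)
        zm = clim.zone_means(f, dem, [(1900, 2000)])
        assert zm.iloc[0] == pytest.approx(gamma * elev.mean() / 1000.0 + 2.0)


class TestFullPipeline:
    def test_warming_recovery_zero_noise(self):
        scen = synth.ScenarioConfig(fine_shape=(16, 16))
        data = synth.gen_climate(scen, seed=11)
        summary = run_climate_pipeline(data, scen)
        assert summary["warming"] == pytest.approx(1.76, abs=0.05)

    def test_warming_recovery_with_noise(self):
        scen = synth.ScenarioConfig(fine_shape=(16, 16), spatial_noise_sd=0.5)
        data = synth.gen_climate(scen, seed=12)
        summary = run_climate_pipeline(data, scen)
        assert summary["warming"] == pytest.approx(1.76, abs=0.2)

    def test_roundtrip_to_coarse_on_smooth_field(self):
        # downscaling then block-averaging back reproduces the coarse field
        scen = synth.ScenarioConfig(fine_shape=(16, 16), coarse_factor=4)
        data = synth.gen_climate(scen, seed=13)
        fine = data["fine"]
        f = fine.isel(year=0, month=5)
        coarse_x = data["coarse"]["x"].values
        coarse_y = data["coarse"]["y"].values
        back = clim.regrid(f, coarse_x, coarse_y, method="patch_like")
        agg = f.values.reshape(4, 4, 4, 4).mean(axis=(1, 3))
        # interior cells within interpolation tolerance of the block means
        assert np.abs(back.values[1:-1, 1:-1] - agg[1:-1, 1:-1]).max() < 0.35
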
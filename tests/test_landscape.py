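"""Synthetic-landscape generator: determinism, geometry and the bioclim
identities the downstream analysis relies on."""

import numpy as np
import pytest
from scipy import stats

from ensdm.grids import Grid
from ensdm.landscape import (
    SpeciesTruth,
    derive_topo_vars,
    make_climate_surfaces,
    make_dem,
    make_future,
    make_protected_areas,
    make_scenarios,
    sample_occurrences,
)


class TestMakeDem:
    def test_zero_relief_is_flat_land(self):
        dem = make_dem((16, 16), relief_params={"amplitude": 0, "base": 12.0}, seed=0)
        assert dem.mask.all()
        assert np.all(dem.values == 12.0)

    def test_same_seed_identical(self):
        a = make_dem((32, 32), seed=5)
        b = make_dem((32, 32), seed=5)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, make_dem((32, 32), seed=6).values)

    def test_land_fraction_within_bounds(self):
        dem = make_dem((64, 64), relief_params={"land_fraction": 0.45}, seed=1)
        frac = dem.n_land / dem.values.size
        # quantile thresholding plus the forced sea margin
        assert 0.30 < frac < 0.50

    def test_sea_margin_and_degenerate_shape(self):
        dem = make_dem((16, 16), seed=2)
        assert not dem.mask[0, :].any() and not dem.mask[:, -1].any()
        with pytest.raises(ValueError, match="8x8"):
            make_dem((4, 12), seed=0)


class TestTopoVars:
    def test_flat_dem_slope_zero(self):
        dem = Grid(np.full((10, 10), 5.0))
        topo = derive_topo_vars(dem)
        assert np.allclose(topo["slope"].values, 0.0)
        assert np.allclose(topo["westerly_aspect"].values, 0.0)

    def test_inclined_plane_constant_slope(self):
        g = 0.3  # gradient in z per map unit, increasing eastward
        x = np.arange(12) * 1.0
        dem = Grid(np.tile(g * x, (12, 1)), cell_size=1.0)
        topo = derive_topo_vars(dem)
        expected = np.degrees(np.arctan(g))
        inner = topo["slope"].values[1:-1, 1:-1]
        assert np.allclose(inner, expected, atol=1e-9)
        # downslope is due west on an east-rising plane
        assert np.allclose(topo["westerly_aspect"].values[1:-1, 1:-1], 1.0)

    def test_single_cell_island_distance_zero(self):
        vals = np.full((9, 9), np.nan)
        vals[4, 4] = 10.0
        topo = derive_topo_vars(Grid(vals))
        assert topo["dist_coast"].values[4, 4] == 0.0

    def test_all_sea_rejected(self):
        with pytest.raises(ValueError, match="no land"):
            derive_topo_vars(Grid(np.full((9, 9), np.nan)))

    def test_solar_index_flat_is_one(self):
        dem = Grid(np.zeros((10, 10)))
        topo = derive_topo_vars(dem, latitude=-51.7)
        assert np.allclose(topo["solar_index"].values, 1.0)

    def test_twi_higher_in_valleys(self, small_dem):
        topo = derive_topo_vars(small_dem)
        twi = topo["twi"].land_values()
        elev = small_dem.land_values()
        r = stats.pearsonr(twi, elev).statistic
        assert r < 0  # wetness accumulates downslope


class TestClimateSurfaces:
    def test_constant_when_no_gradients(self):
        dem = make_dem((16, 16), relief_params={"amplitude": 0}, seed=0)
        env = make_climate_surfaces(dem, lapse_rate=0, ew_gradient=0, noise=0,
                                    seasonal_ew=0, precip_ew_gradient=0,
                                    precip_noise=0, seed=0)
        for name in ("BIO1", "BIO5", "BIO12"):
            vals = env[name].land_values()
            assert np.allclose(vals, vals[0])

    def test_bioclim_identities(self, small_env):
        b = {n: small_env[n].land_values() for n in small_env.names if n.startswith("BIO")}
        np.testing.assert_allclose(b["BIO7"], b["BIO5"] - b["BIO6"], rtol=1e-12)
        assert np.all(b["BIO10"] >= b["BIO11"])
        assert np.all(b["BIO16"] >= b["BIO17"])
        for n in ("BIO12", "BIO13", "BIO14", "BIO16", "BIO17", "BIO18", "BIO19"):
            assert np.all(b[n] >= 0)

    def test_configured_island_means(self, small_dem):
        env = make_climate_surfaces(small_dem, mean_temp=6.6, mean_precip=559.0, seed=3)
        assert env["BIO1"].land_values().mean() == pytest.approx(6.6, abs=1e-9)
        assert env["BIO12"].land_values().mean() == pytest.approx(559.0, rel=1e-9)

    def test_temperature_decreases_with_elevation(self, small_dem):
        env = make_climate_surfaces(small_dem, noise=0, seed=0)
        elev = small_dem.land_values()
        t = env["BIO1"].land_values()
        assert stats.pearsonr(elev, t).statistic < -0.5

    def test_excluded_layers_flagged(self, small_env):
        assert {"BIO2", "BIO3", "BIO8", "BIO9", "BIO15"} <= set(small_env.excluded)
        assert "BIO2" not in small_env.selectable_names()
        assert "BIO2" in small_env.names  # emitted for completeness


class TestMakeFuture:
    def test_zero_warming_identity(self, small_env):
        fut = make_future(small_env, warming=0.0, rcm_jitter_sd=0.0)
        for name in small_env.names:
            np.testing.assert_array_equal(fut[name].values, small_env[name].values)

    def test_warming_shift_exact(self, small_env):
        fut = make_future(small_env, warming=1.8, rcm_jitter_sd=0.0)
        diff = fut["BIO1"].land_values() - small_env["BIO1"].land_values()
        np.testing.assert_allclose(diff, 1.8, rtol=0, atol=1e-12)
        assert fut["BIO1"].land_values().mean() - small_env["BIO1"].land_values().mean() == pytest.approx(1.8)

    def test_point_mass_translation_and_invariants(self, small_env):
        fut = make_future(small_env, warming=1.2, rcm_jitter_sd=0.5, seed=9)
        d10 = np.unique(np.round(fut["BIO10"].land_values() - small_env["BIO10"].land_values(), 9))
        d1 = np.unique(np.round(fut["BIO1"].land_values() - small_env["BIO1"].land_values(), 9))
        assert d10.size == 1 and d1.size == 1 and d10[0] == d1[0]
        # precipitation, diurnal range and seasonality untouched
        for name in ("BIO12", "BIO16", "BIO7", "BIO4", "BIO2"):
            np.testing.assert_array_equal(fut[name].values, small_env[name].values)

    def test_negative_jitter_sd_rejected(self, small_env):
        with pytest.raises(ValueError, match="non-negative"):
            make_future(small_env, warming=1.0, rcm_jitter_sd=-0.1)


class TestScenarios:
    def test_scenario_grid_complete(self, small_env):
        ss = make_scenarios(small_env, rcm_jitter_sd=0.34, seed=4)
        assert len(ss.stacks) == 15  # 3 periods x 5 RCMs
        keys = {(s.period, s.rcm) for s in ss.stacks}
        assert len(keys) == 15
        # precipitation identical across periods within an RCM
        r = ss.rcm_names[0]
        p1 = ss.get("2020", r)["BIO12"].values
        p2 = ss.get("2080", r)["BIO12"].values
        np.testing.assert_array_equal(p1, p2)

    def test_warming_monotone_within_rcm(self, small_env):
        ss = make_scenarios(small_env, rcm_jitter_sd=0.34, seed=4)
        for r in ss.rcm_names:
            w = [ss.warming_per_period[(p, r)] for p in ("2020", "2050", "2080")]
            assert w[0] < w[1] < w[2]


class TestSampleOccurrences:
    def test_zero_base_rate_no_presences(self, small_env):
        truth = SpeciesTruth("ghost", {"BIO10": ("gaussian", 10.0, 1.0)}, base_rate=0.0)
        occ = sample_occurrences(truth, small_env, n_target=10, seed=0, enforce_min=None)
        assert len(occ) == 0

    def test_uniform_env_points_uniform(self, flat_land_grid):
        from ensdm.grids import EnvStack

        env = EnvStack(layers={"flat": flat_land_grid})
        truth = SpeciesTruth("any", {}, base_rate=0.5)
        occ = sample_occurrences(truth, env, n_target=2000, seed=1, enforce_min=None)
        counts, _, _ = np.histogram2d(
            occ.records["y"], occ.records["x"], bins=4, range=[[0, 20], [0, 20]]
        )
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        p = stats.chi2.sf(chi2, df=counts.size - 1)
        assert p > 0.01

    def test_cold_niche_directional(self, small_env):
        mean_b10 = small_env["BIO10"].land_values().mean()
        truth = SpeciesTruth("cold", {"BIO10": ("gaussian", mean_b10 - 1.5, 0.5)})
        occ = sample_occurrences(truth, small_env, n_target=50, seed=2, enforce_min=None)
        row, col = small_env.template.cell_index(occ.records["x"], occ.records["y"])
        sampled = small_env["BIO10"].values[row, col]
        assert sampled.mean() < mean_b10

    def test_unreachable_target_errors_with_count(self, small_env):
        truth = SpeciesTruth("rare", {"BIO10": ("gaussian", -50.0, 0.1)})
        with pytest.raises(RuntimeError, match="achieved only"):
            sample_occurrences(truth, small_env, n_target=30, seed=0, max_attempts=2000)

    def test_determinism(self, small_env):
        truth = SpeciesTruth("sp", {"BIO10": ("gaussian", 9.0, 1.0)})
        a = sample_occurrences(truth, small_env, n_target=20, seed=5, enforce_min=None)
        b = sample_occurrences(truth, small_env, n_target=20, seed=5, enforce_min=None)
        assert a.records.equals(b.records)


class TestProtectedAreas:
    def test_full_coverage(self, small_env):
        pa = make_protected_areas(small_env, coverage_fraction=1.0, seed=0)
        land = small_env.template.mask
        assert (pa["NNR"].values[land] == 1.0).all()

    def test_coverage_count(self, small_env):
        pa = make_protected_areas(small_env, coverage_fraction=0.1, seed=3)
        n_land = small_env.template.n_land
        got = np.nansum(pa["IPA"].values)
        assert abs(got - 0.1 * n_land) <= max(3, 0.02 * n_land)

    def test_disjoint_networks(self, small_env):
        pa = make_protected_areas(small_env, coverage_fraction=0.15, seed=3, disjoint=True)
        both = (np.nan_to_num(pa["NNR"].values) > 0) & (np.nan_to_num(pa["IPA"].values) > 0)
        assert not both.any()

    def test_bad_coverage_rejected(self, small_env):
        with pytest.raises(ValueError, match="coverage"):
            make_protected_areas(small_env, coverage_fraction=0.0, seed=0)
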
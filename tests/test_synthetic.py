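"""Synthetic-ocean generator invariants and virtual-species sampling."""

from __future__ import annotations

import numpy as np
import pytest

from aquasdm import GridSpec, NicheSpec, SyntheticOceanConfig, make_ocean, sample_virtual_presences
from aquasdm.grids import VARIABLES
from aquasdm.synthetic import MONTHS, dome_region, surface_cycle

from .conftest import SMALL_GRID


class TestNiche:
    def test_plateau_is_one(self):
        niche = NicheSpec()
        sbt = np.array([5.0, 10.0, 18.0])
        assert np.allclose(niche.suitability(sbt), 1.0)

    def test_tails_fall_off(self):
        niche = NicheSpec()
        s = niche.suitability(np.array([2.0, 4.0, 19.0, 22.0]))
        assert s[0] < s[1] < 1.0
        assert s[3] < s[2] < 1.0
        assert s[0] < 0.1 and s[3] < 0.05

    def test_continuous_at_edges(self):
        niche = NicheSpec()
        eps = 1e-9
        assert niche.suitability(np.array([5.0 - eps]))[0] == pytest.approx(1.0, abs=1e-6)
        assert niche.suitability(np.array([18.0 + eps]))[0] == pytest.approx(1.0, abs=1e-6)

    def test_salinity_modulation(self):
        niche = NicheSpec()
        base = niche.suitability(np.array([10.0]))
        with_sal = niche.suitability(np.array([10.0]), np.array([33.0]))
        far_sal = niche.suitability(np.array([10.0]), np.array([15.0]))
        assert with_sal[0] == pytest.approx(base[0], abs=1e-9)
        assert far_sal[0] < 0.05

    def test_nan_maps_to_zero(self):
        assert NicheSpec().suitability(np.array([np.nan]))[0] == 0.0


class TestSurfaceCycle:
    def test_center_extremes(self):
        cfg = SyntheticOceanConfig()
        assert surface_cycle(cfg, 8.0) == pytest.approx(cfg.surface_summer_max)
        assert surface_cycle(cfg, 2.0) == pytest.approx(cfg.surface_winter_min)

    def test_south_warmer_than_north(self):
        cfg = SyntheticOceanConfig()
        for m in (2.0, 8.0):
            assert surface_cycle(cfg, m, lat=32.0) > surface_cycle(cfg, m, lat=40.0)


class TestOcean:
    @pytest.fixture(scope="class")
    def ocean(self, default_ocean):
        return default_ocean

    def test_determinism(self):
        cfg = SyntheticOceanConfig(grid=SMALL_GRID, seed=3)
        a = make_ocean(cfg)
        b = make_ocean(cfg)
        assert np.array_equal(a.bathymetry, b.bathymetry, equal_nan=True)
        for m in MONTHS:
            assert np.array_equal(a.temperature[m], b.temperature[m], equal_nan=True)

    def test_seed_changes_fields(self):
        a = make_ocean(SyntheticOceanConfig(grid=SMALL_GRID, seed=1))
        b = make_ocean(SyntheticOceanConfig(grid=SMALL_GRID, seed=2))
        assert not np.array_equal(a.bathymetry, b.bathymetry, equal_nan=True)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_ocean(SyntheticOceanConfig(grid=GridSpec(120.0, 120.5, 31.0, 31.5, 15.0)))

    def test_land_ocean_consistency(self, ocean):
        assert np.isnan(ocean.bathymetry[~ocean.ocean_mask]).all()
        assert np.isfinite(ocean.bathymetry[ocean.ocean_mask]).all()
        assert 0.3 < ocean.ocean_mask.mean() < 0.95

    def test_profiles_masked_below_seafloor(self, ocean):
        levels = np.asarray(ocean.config.depth_levels)
        t = ocean.temperature[7]
        for k, z in enumerate(levels):
            below = ocean.ocean_mask & (ocean.bathymetry < z)
            assert np.isnan(t[k][below]).all()
        assert np.isfinite(t[0][ocean.ocean_mask]).all()

    def test_dome_cold_in_summer(self, ocean):
        """Dome bottom water stays below 10 degC at 50 m in July-August."""
        levels = np.asarray(ocean.config.depth_levels)
        k50 = int(np.flatnonzero(levels == 50.0)[0])
        core = dome_region(ocean, depth_at_least=55.0)
        assert core.sum() > 10
        for m in (7, 8):
            vals = ocean.temperature[m][k50][core]
            vals = vals[np.isfinite(vals)]
            assert (vals < 10.0).all()

    def test_dome_absent_in_winter(self, ocean):
        """After the November overturn the dome signature vanishes: in
        December bottom and surface temperature agree within a few degC."""
        levels = np.asarray(ocean.config.depth_levels)
        k50 = int(np.flatnonzero(levels == 50.0)[0])
        core = dome_region(ocean, depth_at_least=55.0)
        t = ocean.temperature[12]
        diff = t[0][core] - t[k50][core]
        diff = diff[np.isfinite(diff)]
        assert np.abs(diff).max() < 5.0

    def test_summer_stratification_exceeds_winter(self, ocean):
        levels = np.asarray(ocean.config.depth_levels)
        k50 = int(np.flatnonzero(levels == 50.0)[0])
        core = dome_region(ocean, depth_at_least=55.0)

        def strat(month):
            t = ocean.temperature[month]
            d = t[0][core] - t[k50][core]
            return np.nanmean(d)

        assert strat(8) > strat(2) + 5.0

    def test_surface_seasonal_cycle(self, ocean):
        sst_aug = np.nanmean(ocean.temperature[8][0])
        sst_feb = np.nanmean(ocean.temperature[2][0])
        assert sst_aug - sst_feb > 8.0

    def test_stacks_cover_months_and_layers(self, ocean):
        labels = ocean.layer_labels
        assert set(ocean.stacks) == {(m, lab) for m in MONTHS for lab in labels}
        surf = ocean.stacks[(7, labels[0])]
        deep = ocean.stacks[(7, labels[-1])]
        # deep layer has data only where the sea is deep enough
        assert deep.mask.sum() < surf.mask.sum()
        # SST in every stack equals the surface-layer temperature
        assert np.array_equal(
            deep.variables["SST"][deep.mask], surf.variables["SBT"][deep.mask]
        )

    def test_training_climatology_contract(self, ocean):
        stack = ocean.training_stack
        assert set(stack.variables) == set(VARIABLES)
        assert np.array_equal(stack.mask, ocean.ocean_mask)
        # bottom colder than surface on average over the deep basin
        deep = ocean.ocean_mask & (np.nan_to_num(ocean.bathymetry) > 50)
        assert np.nanmean(stack.variables["SBT"][deep]) < np.nanmean(stack.variables["SST"][deep])


class TestSampling:
    def test_presences_land_on_suitable_cells(self, default_ocean):
        occ = sample_virtual_presences(default_ocean, NicheSpec(), 200, seed=1)
        assert len(occ) == 200
        assert (occ.records["true_suitability"] > 0).all()
        row, col, inside = default_ocean.grid.index_of(occ.lons, occ.lats)
        assert inside.all()
        assert default_ocean.ocean_mask[row, col].all()

    def test_sampling_is_weighted_by_suitability(self, default_ocean):
        occ = sample_virtual_presences(default_ocean, NicheSpec(), 500, seed=2)
        assert occ.records["true_suitability"].mean() > 0.7

    def test_determinism_and_seed_sensitivity(self, default_ocean):
        a = sample_virtual_presences(default_ocean, NicheSpec(), 50, seed=3)
        b = sample_virtual_presences(default_ocean, NicheSpec(), 50, seed=3)
        c = sample_virtual_presences(default_ocean, NicheSpec(), 50, seed=4)
        assert np.array_equal(a.lons, b.lons)
        assert not np.array_equal(a.lons, c.lons)

    def test_min_n(self, default_ocean):
        with pytest.raises(ValueError):
            sample_virtual_presences(default_ocean, NicheSpec(), 5)

    def test_impossible_niche_raises(self, default_ocean):
        # plateau far beyond any ocean temperature, with tails so sharp
        # they underflow to exactly zero
        dead = NicheSpec(optimum_low=60.0, optimum_high=70.0, falloff_scale=0.01)
        with np.errstate(over="ignore"), pytest.raises(ValueError, match="zero everywhere"):
            sample_virtual_presences(default_ocean, dead, 50)
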
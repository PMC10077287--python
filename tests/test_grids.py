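"""Grid, depth-layer, stack and VIF behaviour."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aquasdm import (
    STANDARD_DEPTH_LEVELS,
    STANDARD_LAYERS,
    DepthLayer,
    GridSpec,
    PredictorStack,
    crop,
    extract_at_points,
    layer_mean,
    vif,
)
from aquasdm.grids import VARIABLES, AlignmentError

from .conftest import SMALL_GRID, random_stack


class TestGridSpec:
    def test_shape_and_centers(self):
        g = GridSpec(120.0, 130.0, 31.0, 41.0, 15.0)
        assert g.shape == (40, 40)
        assert g.cell_deg == pytest.approx(0.25)
        assert g.lon_centers[0] == pytest.approx(120.125)
        assert g.lat_centers[-1] == pytest.approx(40.875)

    def test_index_of_roundtrip(self):
        g = SMALL_GRID
        rng = np.random.default_rng(3)
        lons = rng.uniform(g.lon_min, g.lon_max - 1e-9, 50)
        lats = rng.uniform(g.lat_min, g.lat_max - 1e-9, 50)
        row, col, inside = g.index_of(lons, lats)
        assert inside.all()
        assert np.allclose(g.lon_centers[col], lons, atol=g.cell_deg / 2 + 1e-9)
        assert np.allclose(g.lat_centers[row], lats, atol=g.cell_deg / 2 + 1e-9)

    def test_outside_points_flagged(self):
        row, col, inside = SMALL_GRID.index_of([119.0, 121.0], [35.0, 35.0])
        assert list(inside) == [False, True]

    def test_bad_extent_raises(self):
        with pytest.raises(ValueError):
            GridSpec(120.0, 119.0, 31.0, 41.0, 15.0)
        with pytest.raises(ValueError):
            GridSpec(120.0, 130.0, 31.0, 41.0, -5.0)
        with pytest.raises(ValueError, match="integer number of cells"):
            GridSpec(120.0, 130.1, 31.0, 41.0, 15.0)


class TestLayers:
    def test_standard_layers_are_15m_bands(self):
        assert [l.label for l in STANDARD_LAYERS] == ["0-15 m", "15-30 m", "30-45 m", "45-60 m"]
        for layer in STANDARD_LAYERS:
            assert layer.bottom - layer.top == pytest.approx(15.0)

    def test_bad_layer(self):
        with pytest.raises(ValueError):
            DepthLayer("x", 20.0, 10.0)

    def test_layer_mean_closed_interval(self):
        levels = np.asarray(STANDARD_DEPTH_LEVELS)
        prof = np.tile(levels[:, None, None], (1, 2, 2)).astype(float)
        got = layer_mean(prof, levels, STANDARD_LAYERS[1])  # 15-30 m: levels 15,20,25,30
        assert np.allclose(got, np.mean([15, 20, 25, 30]))

    def test_layer_mean_all_missing_is_nan(self):
        levels = np.asarray(STANDARD_DEPTH_LEVELS)
        prof = np.full((levels.size, 2, 2), np.nan)
        prof[0] = 5.0  # only the surface level present
        got = layer_mean(prof, levels, STANDARD_LAYERS[3])
        assert np.isnan(got).all()

    def test_layer_mean_no_levels_raises(self):
        with pytest.raises(ValueError, match="no standard levels"):
            layer_mean(np.zeros((2, 2, 2)), [0.0, 5.0], DepthLayer("deep", 50.0, 60.0))


class TestPredictorStack:
    def test_mask_unification(self):
        g = SMALL_GRID
        v = {name: np.ones(g.shape) * 10.0 for name in VARIABLES}
        v["SBT"][0, 0] = np.nan
        stack = PredictorStack(spec=g, variables=v)
        for name in VARIABLES:
            assert np.isnan(stack.variables[name][0, 0])
        assert not stack.mask[0, 0]

    def test_range_check(self):
        g = SMALL_GRID
        v = {name: np.ones(g.shape) * 10.0 for name in VARIABLES}
        v["SST"][2, 2] = 99.0
        with pytest.raises(ValueError, match="SST outside"):
            PredictorStack(spec=g, variables=v)

    def test_to_frame_indexes_valid_cells(self):
        stack = random_stack(7)
        frame = stack.to_frame()
        assert len(frame) == int(stack.mask.sum())
        k = frame.index[0]
        i, j = divmod(k, stack.spec.nlon)
        assert frame.iloc[0]["SBT"] == stack.variables["SBT"][i, j]


class TestCrop:
    def test_aligned_crop(self):
        stack = random_stack(1)
        region = GridSpec(121.0, 123.0, 34.0, 36.0, 15.0)
        sub = crop(stack, region)
        assert sub.spec.shape == (8, 8)
        r0 = int(round((34.0 - 33.0) / 0.25))
        c0 = int(round((121.0 - 120.0) / 0.25))
        expect = stack.variables["SST"][r0:r0 + 8, c0:c0 + 8]
        got = sub.variables["SST"]
        both = np.isfinite(expect) & np.isfinite(got)
        assert np.allclose(got[both], expect[both])

    def test_misaligned_crop_raises(self):
        stack = random_stack(1)
        with pytest.raises(AlignmentError):
            crop(stack, GridSpec(121.1, 123.1, 34.0, 36.0, 15.0))
        with pytest.raises(AlignmentError):
            crop(stack, GridSpec(121.0, 123.0, 34.0, 36.0, 30.0))
        with pytest.raises(AlignmentError):
            crop(stack, GridSpec(119.0, 123.0, 34.0, 36.0, 15.0))


class TestExtract:
    def test_values_match_nearest_cell(self):
        stack = random_stack(2)
        g = stack.spec
        lon = g.lon_centers[3] + 0.01
        lat = g.lat_centers[4] + 0.01
        if not stack.mask[4, 3]:
            pytest.skip("cell happens to be missing in this draw")
        rows, dropped = extract_at_points(stack, [lon], [lat])
        assert dropped == 0
        assert rows.iloc[0]["SBT"] == stack.variables["SBT"][4, 3]
        assert rows.iloc[0]["cell"] == 4 * g.nlon + 3

    def test_outside_and_missing_dropped(self):
        stack = random_stack(2)
        miss = np.argwhere(~stack.mask)[0]
        g = stack.spec
        lons = [g.lon_min - 1.0, g.lon_centers[miss[1]], g.lon_centers[5]]
        lats = [g.lat_min - 1.0, g.lat_centers[miss[0]], g.lat_centers[5]]
        if not stack.mask[5, 5]:
            pytest.skip("cell happens to be missing in this draw")
        rows, dropped = extract_at_points(stack, lons, lats)
        assert dropped == 2 and len(rows) == 1

    def test_all_dropped_raises(self):
        stack = random_stack(2)
        with pytest.raises(ValueError, match="no usable presences"):
            extract_at_points(stack, [0.0], [0.0])


class TestVif:
    def test_independent_columns_near_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((500, 4)), columns=list(VARIABLES))
        vals, ok = vif(df)
        assert ok
        assert (vals < 1.1).all()

    def test_matches_direct_r2(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((200, 4)), columns=list(VARIABLES))
        df["SBT"] = 0.8 * df["SST"] + 0.2 * rng.standard_normal(200)
        vals, _ = vif(df)
        # independent R^2 via numpy polyfit-style regression
        y = df["SBT"].to_numpy()
        X = df[["SST", "SSS", "SBS"]].to_numpy()
        A = np.column_stack([np.ones(len(y)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r2 = 1 - ((y - A @ coef) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert vals["SBT"] == pytest.approx(1.0 / (1.0 - r2))

    def test_perfect_collinearity_is_inf_and_fails(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((50, 4)), columns=list(VARIABLES))
        df["SBS"] = 2.0 * df["SSS"]
        vals, ok = vif(df)
        assert not ok
        assert np.isinf(vals["SBS"]) and np.isinf(vals["SSS"])

    def test_constant_column_raises(self):
        df = pd.DataFrame(np.ones((30, 4)), columns=list(VARIABLES))
        df.iloc[:, :3] = np.random.default_rng(3).standard_normal((30, 3))
        with pytest.raises(ValueError, match="constant"):
            vif(df)
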
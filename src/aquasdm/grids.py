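"""Regular lon-lat grids of environmental predictors.

Grids are cell-center registered WGS84 lon-lat rasters at a fixed
arc-minute resolution.  A :class:`PredictorStack` bundles the four
predictors used throughout (sea surface/bottom temperature and
salinity) on one grid for one context: either the training
climatology or a (month, depth-layer) projection slice.  Missing data
(land, seafloor shallower than the layer) is NaN, shared across the
four fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VARIABLES = ("SST", "SBT", "SSS", "SBS")

#: valid physical ranges for sanity checks, by variable kind
_TEMP_RANGE = (-3.0, 40.0)
_SAL_RANGE = (0.0, 45.0)

_ALIGN_TOL = 1e-6  # degrees; grid-edge alignment tolerance


class AlignmentError(ValueError):
    """Raised when a requested subgrid does not fall on cell edges."""


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of a cell-center registered lon-lat grid.

    ``lon_min``/``lat_min`` etc. are the outer *edges* of the grid;
    cell centers sit half a cell inside.  ``resolution`` is in
    arc-minutes (5 for training climatologies, 15 for the monthly
    depth-layer projections).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float  # arcminutes

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon_min < self.lon_max <= 180.0 + _ALIGN_TOL):
            raise ValueError(f"bad longitude extent [{self.lon_min}, {self.lon_max}]")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError(f"bad latitude extent [{self.lat_min}, {self.lat_max}]")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for n in (self._count(self.lon_min, self.lon_max), self._count(self.lat_min, self.lat_max)):
            if abs(n - round(n)) > 1e-4:
                raise ValueError("extent is not an integer number of cells")

    def _count(self, lo: float, hi: float) -> float:
        return (hi - lo) / self.cell_deg

    @property
    def cell_deg(self) -> float:
        return self.resolution / 60.0

    @property
    def nlon(self) -> int:
        return int(round(self._count(self.lon_min, self.lon_max)))

    @property
    def nlat(self) -> int:
        return int(round(self._count(self.lat_min, self.lat_max)))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_deg * (np.arange(self.nlon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_deg * (np.arange(self.nlat) + 0.5)

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest-cell (row, col) indices plus an in-extent mask."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_deg).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell_deg).astype(int)
        inside = (col >= 0) & (col < self.nlon) & (row >= 0) & (row < self.nlat)
        return row, col, inside


@dataclass(frozen=True)
class DepthLayer:
    """A 15 m depth band, e.g. ``DepthLayer('0-15 m', 0, 15)``."""

    label: str
    top: float
    bottom: float

    def __post_init__(self) -> None:
        if self.bottom <= self.top:
            raise ValueError("layer bottom must exceed top")


#: the four standard bands used for the depth-layer suitability maps
STANDARD_LAYERS: tuple[DepthLayer, ...] = (
    DepthLayer("0-15 m", 0.0, 15.0),
    DepthLayer("15-30 m", 15.0, 30.0),
    DepthLayer("30-45 m", 30.0, 45.0),
    DepthLayer("45-60 m", 45.0, 60.0),
)

#: WOA-style standard depth levels for synthetic vertical profiles (m)
STANDARD_DEPTH_LEVELS: tuple[float, ...] = tuple(float(z) for z in range(0, 65, 5))


@dataclass
class PredictorStack:
    """The four predictor fields on one grid, NaN where missing.

    All four fields share the missing-data mask; construction unifies
    it (a cell missing in any variable is missing in all).
    """

    spec: GridSpec
    variables: dict[str, np.ndarray]
    context: str | tuple = "training climatology"

    def __post_init__(self) -> None:
        if set(self.variables) != set(VARIABLES):
            raise ValueError(f"expected variables {VARIABLES}, got {sorted(self.variables)}")
        shape = self.spec.shape
        for name, arr in self.variables.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, grid is {shape}")
            self.variables[name] = arr
        missing = np.zeros(shape, dtype=bool)
        for arr in self.variables.values():
            missing |= ~np.isfinite(arr)
        for arr in self.variables.values():
            arr[missing] = np.nan
        for name in ("SST", "SBT"):
            self._check_range(name, *_TEMP_RANGE)
        for name in ("SSS", "SBS"):
            self._check_range(name, *_SAL_RANGE)

    def _check_range(self, name: str, lo: float, hi: float) -> None:
        arr = self.variables[name]
        ok = np.isnan(arr) | ((arr >= lo) & (arr <= hi))
        if not ok.all():
            bad = arr[~ok]
            raise ValueError(f"{name} outside [{lo}, {hi}]: e.g. {bad.flat[0]:.2f}")

    @property
    def mask(self) -> np.ndarray:
        """True where data are present."""
        return np.isfinite(self.variables["SST"])

    def to_frame(self) -> pd.DataFrame:
        """Valid cells as rows; index is the flat cell index."""
        valid = self.mask.ravel()
        idx = np.flatnonzero(valid)
        data = {name: self.variables[name].ravel()[idx] for name in VARIABLES}
        return pd.DataFrame(data, index=idx)


def layer_mean(profile_grid: np.ndarray, levels: Sequence[float], layer: DepthLayer) -> np.ndarray:
    """Average a (level, lat, lon) profile grid over one depth band.

    Uses an unweighted mean of the standard levels with depth in the
    closed interval [top, bottom] (so a level on the boundary, e.g.
    15 m, contributes to both adjacent bands, matching unweighted
    climatology averaging).  A cell is NaN where every contributing
    level is missing — in particular where the seafloor is shallower
    than the band top.
    """
    profile_grid = np.asarray(profile_grid, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if profile_grid.shape[0] != levels.size:
        raise ValueError("level axis does not match levels")
    sel = (levels >= layer.top) & (levels <= layer.bottom)
    if not sel.any():
        raise ValueError(f"no standard levels fall in layer {layer.label}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN slices
        return np.nanmean(profile_grid[sel], axis=0)


def crop(stack: PredictorStack, region: GridSpec) -> PredictorStack:
    """Cell-aligned subgrid extraction; never resamples.

    Raises :class:`AlignmentError` if the region's edges or resolution
    do not coincide with the parent grid.
    """
    parent = stack.spec
    if abs(region.resolution - parent.resolution) > _ALIGN_TOL:
        raise AlignmentError("region resolution differs from stack resolution")
    for lo, plo in ((region.lon_min, parent.lon_min), (region.lat_min, parent.lat_min)):
        off = (lo - plo) / parent.cell_deg
        if abs(off - round(off)) > 1e-4:
            raise AlignmentError("region edges do not fall on parent cell edges")
    if (region.lon_min < parent.lon_min - _ALIGN_TOL or region.lon_max > parent.lon_max + _ALIGN_TOL
            or region.lat_min < parent.lat_min - _ALIGN_TOL or region.lat_max > parent.lat_max + _ALIGN_TOL):
        raise AlignmentError("region extends beyond the stack extent")
    c0 = int(round((region.lon_min - parent.lon_min) / parent.cell_deg))
    r0 = int(round((region.lat_min - parent.lat_min) / parent.cell_deg))
    sub = {
        name: arr[r0:r0 + region.nlat, c0:c0 + region.nlon].copy()
        for name, arr in stack.variables.items()
    }
    return PredictorStack(spec=region, variables=sub, context=stack.context)


def extract_at_points(
    stack: PredictorStack, lons: Sequence[float], lats: Sequence[float]
) -> tuple[pd.DataFrame, int]:
    """Nearest-cell-center predictor values at points.

    Points outside the grid or on missing cells are dropped; the count
    of dropped points is returned alongside.  Raises if no point lands
    on a usable cell.
    """
    row, col, inside = stack.spec.index_of(np.asarray(lons), np.asarray(lats))
    n = row.size
    rows = []
    kept_idx = []
    for k in range(n):
        if not inside[k]:
            continue
        vals = {name: stack.variables[name][row[k], col[k]] for name in VARIABLES}
        if any(np.isnan(v) for v in vals.values()):
            continue
        vals["cell"] = int(row[k] * stack.spec.nlon + col[k])
        rows.append(vals)
        kept_idx.append(k)
    n_dropped = n - len(rows)
    if not rows:
        raise ValueError("no usable presences: every point fell outside the grid or on missing cells")
    out = pd.DataFrame(rows, index=kept_idx)
    return out, n_dropped


def vif(table: pd.DataFrame, variables: Sequence[str] = VARIABLES) -> tuple[pd.Series, bool]:
    """Variance inflation factors of the predictor columns.

    VIF_j = 1 / (1 - R²_j), with R²_j from OLS (with intercept) of
    column j on the remaining columns.  Returns the per-variable VIFs
    and a pass flag (all <= 10).  Perfect collinearity yields +inf and
    a failing flag; a constant column is an error.
    """
    X = table[list(variables)].to_numpy(dtype=float)
    n, p = X.shape
    if n < 5:
        raise ValueError("need at least 5 rows for a VIF screen")
    if p < 2:
        raise ValueError("need at least 2 variables")
    sd = X.std(axis=0)
    for j, name in enumerate(variables):
        if sd[j] == 0:
            raise ValueError(f"variable {name} is constant; VIF undefined")
    out = {}
    for j, name in enumerate(variables):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            out[name] = np.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    series = pd.Series(out, name="VIF")
    return series, bool((series <= 10.0).all())
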
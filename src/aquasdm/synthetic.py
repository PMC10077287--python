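"""Synthetic Yellow-Sea-like ocean and virtual cold-water species.

The generator emulates the features that make the real system
interesting for depth-adjustable cage aquaculture: a seasonal surface
thermal cycle (winter ~4 degC, summer ~24 degC at the warm edge), and a
persistent cold bottom-water dome — an analogue of the Yellow Sea Cold
Water Mass — that forms in May, is fully developed through summer, and
disappears in December, keeping deep water below 10 degC while the
surface is warm.  Vertical mixing homogenizes the background water
column in autumn.  A virtual species with a known bottom-temperature
niche (plateau 5-18 degC by default) is then sampled from the
climatology, so every downstream stage can be tested for parameter
recovery without any data downloads.

All fields are deterministic given the seed; spatial texture comes
from Gaussian-blurred white noise (radius 2 cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import (
    STANDARD_DEPTH_LEVELS,
    STANDARD_LAYERS,
    DepthLayer,
    GridSpec,
    PredictorStack,
    layer_mean,
)
from .occurrences import OccurrenceSet

MONTHS = tuple(range(1, 13))

DEFAULT_GRID = GridSpec(lon_min=120.0, lon_max=130.0, lat_min=31.0, lat_max=41.0, resolution=15.0)


@dataclass(frozen=True)
class NicheSpec:
    """Known environmental response of the virtual species.

    Suitability is 1 on the bottom-temperature plateau
    [optimum_low, optimum_high] and falls off logistically outside with
    scale ``falloff_scale`` (degC); a broad Gaussian tolerance in bottom
    salinity (center 33 psu, sd 6) modulates it weakly.  The driver
    variable is SBT, mirroring the finding that bottom temperature
    dominates habitat suitability for cold-water fish.
    """

    optimum_low: float = 5.0
    optimum_high: float = 18.0
    falloff_scale: float = 1.0
    salinity_center: float = 33.0
    salinity_sd: float = 6.0

    def suitability(self, sbt: np.ndarray, sbs: np.ndarray | None = None) -> np.ndarray:
        sbt = np.asarray(sbt, dtype=float)
        # logistic tails pinned to 1 at the plateau edges
        lo = np.minimum(1.0, 2.0 / (1.0 + np.exp(-(sbt - self.optimum_low) / self.falloff_scale)))
        hi = np.minimum(1.0, 2.0 / (1.0 + np.exp((sbt - self.optimum_high) / self.falloff_scale)))
        suit = np.where(sbt < self.optimum_low, lo, np.where(sbt > self.optimum_high, hi, 1.0))
        if sbs is not None:
            sal = np.exp(-0.5 * ((np.asarray(sbs, dtype=float) - self.salinity_center) / self.salinity_sd) ** 2)
            suit = suit * sal
        return np.where(np.isfinite(sbt), suit, 0.0)


@dataclass(frozen=True)
class SyntheticOceanConfig:
    """Parameters of the synthetic ocean.

    The defaults encode the study conditions: a 40x40 cell domain at
    15 arcmin centered near 36 N, surface cycle from 4 degC (February
    minimum) to 24 degC (August maximum at the warm southern edge),
    and a cold dome capped at 8 degC at depth, present May-November.
    """

    grid: GridSpec = DEFAULT_GRID
    layers: tuple[DepthLayer, ...] = STANDARD_LAYERS
    depth_levels: tuple[float, ...] = STANDARD_DEPTH_LEVELS
    surface_winter_min: float = 4.0  # at the domain center latitude
    surface_summer_max: float = 24.0  # at the domain center latitude
    peak_month: float = 8.0  # warmest month of the surface sinusoid
    # north-south gradients (degC per degree latitude, warmer south);
    # winters steepen far more than summers, so the southern margin is
    # subtropical (small seasonal amplitude, annual mean > 18 degC)
    # while the north is cold-temperate — the meridional spread that
    # makes the 5-18 degC niche identifiable from an annual-mean
    # climatology, as the wide span of real training occurrences does
    lat_gradient_winter: float = 5.5
    lat_gradient_summer: float = 2.0
    dome_core_temp: float = 8.0  # bottom cap inside the dome (< 10 degC)
    dome_months: tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11)
    # background bottom water: cold, weakly graded meridionally and
    # seasonally damped/lagged relative to the surface (thermal
    # inertia); by late autumn surface and bottom converge outside the
    # dome (vertical homogenization)
    bottom_ref_temp: float = 9.5  # degC at the domain-center latitude
    #: bottom water warms toward the subtropical southern shelf and
    #: cools gently northward (the cold pool stays within the niche)
    lat_gradient_bottom_south: float = 0.0
    lat_gradient_bottom_north: float = 0.5
    #: latitude offsets (degrees from center) where the deep basin
    #: gives way to shallow shelves, and the taper widths; the deep
    #: bowl then underlies only the central latitudes, as the real
    #: basin underlies the cold water mass
    shelf_start_south: float = 0.6
    shelf_width: float = 0.35
    shelf_start_north: float = 3.4
    shelf_width_north: float = 0.4
    #: a mid-depth trough channel along the eastern margin reaching
    #: into the warm south: warm surface water over cold bottom water,
    #: which decouples surface and bottom temperature in the training
    #: climatology; at 40 m it floors above the deepest (45-60 m)
    #: layer, so that layer exists only over the central basin
    trough_depth: float = 40.0
    trough_lon_frac: float = 0.72  # trough east of this domain fraction
    trough_south_extent: float = 4.4  # degrees south of center
    #: depth (m) and meridional taper width (deg) of the open southern
    #: shelf; deep enough that the mid-depth layers stay wet over it,
    #: so warm-water training cells exist at intermediate depths too
    open_shelf_depth: float = 12.0
    open_shelf_width: float = 0.6
    bottom_seasonal_amp: float = 0.4
    bottom_peak_month: float = 10.0  # lagged behind the surface peak
    dome_extent_frac: float = 0.7  # ellipse semi-axes as fraction of the half-domain
    surface_salinity: float = 33.0
    deep_salinity: float = 34.0  # stable saline deep water
    #: the ocean reaches less far north than south (coastline closes
    #: the basin to the north), as a fraction of the half-domain
    basin_extent_north: float = 0.68
    #: freshwater river plume over the southwestern shelf (large-river
    #: analogue): maximum surface freshening in psu, and its reach
    plume_freshening: float = 16.0
    plume_start_south: float = 0.9  # degrees south of center
    #: convective/evaporative regulation caps open-ocean surface
    #: temperature; the warm southern margin is therefore nearly
    #: isothermal year-round (small seasonal amplitude), so monthly
    #: surface fields stay close to the annual training climatology
    #: at the warm edge
    sst_cap: float = 26.5
    noise_sd: float = 0.3  # degC; salinity noise is noise_sd * 0.5 psu
    #: independent smooth anomaly of the deep water (degC / psu*0.3):
    #: bottom water masses have their own history, which keeps the
    #: bottom fields from being collinear with the surface fields
    bottom_noise_sd: float = 1.0
    noise_radius_cells: float = 2.0
    basin_max_depth: float = 75.0
    seed: int = 0


@dataclass
class SyntheticOcean:
    """Generated fields: vertical profiles, layer stacks and mask."""

    config: SyntheticOceanConfig
    ocean_mask: np.ndarray  # (nlat, nlon) bool
    bathymetry: np.ndarray  # (nlat, nlon) seafloor depth, m; NaN on land
    temperature: dict[int, np.ndarray]  # month -> (nlev, nlat, nlon)
    salinity: dict[int, np.ndarray]
    stacks: dict[tuple[int, str], PredictorStack] = field(default_factory=dict)
    training_stack: PredictorStack | None = None

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    @property
    def layer_labels(self) -> list[str]:
        return [l.label for l in self.config.layers]


def _smooth_noise(shape: tuple[int, int], sd: float, radius: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=radius, mode="nearest")
    scale = sm.std()
    return sd * sm / scale if scale > 0 else sm


def _smoothstep(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    t = np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def surface_cycle(config: SyntheticOceanConfig, month: float, lat: float | np.ndarray = None) -> float | np.ndarray:
    """Surface temperature of the seasonal sinusoid (degC), noise-free.

    At the domain-center latitude the cycle runs from
    ``surface_winter_min`` to ``surface_summer_max``; away from the
    center, winter and summer extremes shift by their respective
    latitudinal gradients (warmer south).
    """
    if lat is None:
        lat = 0.5 * (config.grid.lat_min + config.grid.lat_max)
    lat_c = 0.5 * (config.grid.lat_min + config.grid.lat_max)
    dsouth = lat_c - np.asarray(lat, dtype=float)  # positive south of center
    winter = config.surface_winter_min + config.lat_gradient_winter * dsouth
    summer = config.surface_summer_max + config.lat_gradient_summer * dsouth
    mean = 0.5 * (summer + winter)
    amp = 0.5 * (summer - winter)
    return mean + amp * np.cos(2.0 * np.pi * (month - config.peak_month) / 12.0)


def make_ocean(config: SyntheticOceanConfig | None = None) -> SyntheticOcean:
    """Build the full synthetic ocean: 12 months x layers of predictors.

    Deterministic given ``config.seed``.  Raises on degenerate grids
    (fewer than 4x4 cells).
    """
    config = config or SyntheticOceanConfig()
    grid = config.grid
    nlat, nlon = grid.shape
    if nlat < 4 or nlon < 4:
        raise ValueError("grid too small: need at least 4x4 cells")
    rng = np.random.default_rng(config.seed)

    lon = grid.lon_centers[None, :]
    lat = grid.lat_centers[:, None]
    lon_c = 0.5 * (grid.lon_min + grid.lon_max)
    lat_c = 0.5 * (grid.lat_min + grid.lat_max)
    half_lon = 0.5 * (grid.lon_max - grid.lon_min)
    half_lat = 0.5 * (grid.lat_max - grid.lat_min)

    # bowl-shaped basin: deep center, land beyond the rim, and a broad
    # shallow shelf over the subtropical south; the rim closes in
    # sooner on the northern side (coastal boundary)
    half_lat_eff = np.where(lat > lat_c, config.basin_extent_north * half_lat, half_lat)
    r = np.sqrt(((lon - lon_c) / half_lon) ** 2 + ((lat - lat_c) / half_lat_eff) ** 2)
    dsouth = (lat_c - lat) * np.ones((1, nlon))  # positive south of center
    shelf = (
        1.0
        - 0.78 / (1.0 + np.exp(-(dsouth - config.shelf_start_south) / config.shelf_width))
        - 0.78 / (1.0 + np.exp(-(-dsouth - config.shelf_start_north) / config.shelf_width_north))
    )
    bathy = config.basin_max_depth * (1.0 - r ** 1.5) * shelf + 3.0 * _smooth_noise(
        (nlat, nlon), 1.0, config.noise_radius_cells, rng
    )
    # the southern margin is an open, flat shallow shelf spanning the
    # full domain width (the subtropical marginal-sea analogue)
    open_shelf = config.open_shelf_depth / (
        1.0 + np.exp(-(dsouth - (config.shelf_start_south + 0.3)) / config.open_shelf_width)
    )
    bathy = np.maximum(bathy, open_shelf)
    lon_frac = (lon - grid.lon_min) / (grid.lon_max - grid.lon_min) * np.ones((nlat, 1))
    trough = (
        config.trough_depth
        * _smoothstep(lon_frac, config.trough_lon_frac - 0.06, config.trough_lon_frac + 0.06)
        * _smoothstep(dsouth, 0.2, 1.0)
        * (1.0 - _smoothstep(dsouth, config.trough_south_extent - 0.6, config.trough_south_extent + 0.4))
    )
    bathy = np.maximum(bathy, trough)
    ocean = bathy > 2.0
    bathy = np.where(ocean, np.maximum(bathy, 4.0), np.nan)

    # cold dome: elliptical core over the deep basin
    a_frac = config.dome_extent_frac
    e = ((lon - lon_c) / (a_frac * half_lon)) ** 2 + ((lat - lat_c) / (a_frac * half_lat)) ** 2
    dome_w = 1.0 - _smoothstep(e, 0.5, 1.0)

    levels = np.asarray(config.depth_levels, dtype=float)
    below_floor = levels[:, None, None] > bathy[None, :, :]  # NaN bathy -> False; handled via ocean mask

    # persistent anomalies (drawn once): deep water-mass history and
    # quasi-permanent surface salinity structure (eddies, runoff paths)
    bot_anom = _smooth_noise((nlat, nlon), config.bottom_noise_sd, config.noise_radius_cells, rng)
    s_bot_anom = np.clip(
        _smooth_noise((nlat, nlon), config.bottom_noise_sd * 1.2, config.noise_radius_cells, rng), -1.2, 1.2
    )
    s_surf_anom = _smooth_noise((nlat, nlon), config.noise_sd * 1.5, config.noise_radius_cells, rng)

    temperature: dict[int, np.ndarray] = {}
    salinity: dict[int, np.ndarray] = {}
    for m in MONTHS:
        t_surf = surface_cycle(config, m, lat) * np.ones((1, nlon)) + _smooth_noise(
            (nlat, nlon), config.noise_sd, config.noise_radius_cells, rng
        )
        # bottom water: stable cold climatology + damped, lagged cycle
        wobble = config.bottom_seasonal_amp * np.cos(2.0 * np.pi * (m - config.bottom_peak_month) / 12.0)
        t_bot_bg = (
            config.bottom_ref_temp
            + (
                config.lat_gradient_bottom_south * np.maximum(dsouth, 0.0)
                - config.lat_gradient_bottom_north * np.maximum(-dsouth, 0.0)
            )
            + wobble
            + bot_anom
        )
        # winter convective adjustment: a cold surface over the warm
        # deep reservoir is convectively unstable, so over deep water
        # the column overturns and the surface relaxes to the reservoir
        # temperature — the warm winter surface tongue that deep
        # marginal seas show over their troughs
        conv = _smoothstep(np.nan_to_num(bathy, nan=0.0), 20.0, 55.0)
        t_surf = t_surf + conv * np.maximum(t_bot_bg - t_surf, 0.0)
        wz = _smoothstep(levels, 10.0, 40.0)[:, None, None]
        t_bg = t_surf[None] - (t_surf - t_bot_bg)[None] * wz
        dz = _smoothstep(levels, 30.0, 45.0)[:, None, None]
        w_dome = (dz * dome_w[None]) if m in config.dome_months else 0.0
        t = (1.0 - w_dome) * t_bg + w_dome * config.dome_core_temp

        lon_frac_row = (lon - grid.lon_min) / (grid.lon_max - grid.lon_min)
        plume_south = (
            1.0 / (1.0 + np.exp(-(dsouth - config.plume_start_south) / 0.7))
            * np.exp(-((lon_frac_row / 0.45) ** 2))
        )
        # coastal freshwater lens: river and runoff influence is
        # strongest over shallow nearshore water all around the basin,
        # and the western side of the basin carries a fresh coastal
        # current along its full length
        with np.errstate(invalid="ignore"):
            plume_coast = 0.80 / (1.0 + np.exp(-(10.0 - np.nan_to_num(bathy, nan=0.0)) / 1.5))
        plume_west = 0.9 * np.exp(-((lon_frac_row / 0.14) ** 2)) * np.ones((nlat, 1))
        plume = config.plume_freshening * np.clip(plume_south + plume_coast + plume_west, 0.0, 1.0)
        s_surf = (
            config.surface_salinity
            + 0.5 * (1.0 - r)  # slightly saltier offshore
            - plume
            + s_surf_anom
            + _smooth_noise((nlat, nlon), config.noise_sd * 0.5, config.noise_radius_cells, rng)
        )
        s_bot = config.deep_salinity + s_bot_anom
        sz = _smoothstep(levels, 5.0, 30.0)[:, None, None]
        s = s_surf[None] * (1.0 - sz) + s_bot[None] * sz

        t = np.clip(t, -3.0, config.sst_cap)
        s = np.clip(s, 0.0, 45.0)
        t = np.where(ocean[None] & ~below_floor, t, np.nan)
        s = np.where(ocean[None] & ~below_floor, s, np.nan)
        temperature[m] = t
        salinity[m] = s

    oc = SyntheticOcean(
        config=config,
        ocean_mask=ocean,
        bathymetry=bathy,
        temperature=temperature,
        salinity=salinity,
    )
    surface_layer = config.layers[0]
    for m in MONTHS:
        sst = layer_mean(temperature[m], levels, surface_layer)
        sss = layer_mean(salinity[m], levels, surface_layer)
        for layer in config.layers:
            sbt = layer_mean(temperature[m], levels, layer)
            sbs = layer_mean(salinity[m], levels, layer)
            oc.stacks[(m, layer.label)] = PredictorStack(
                spec=grid,
                variables={"SST": sst.copy(), "SBT": sbt, "SSS": sss.copy(), "SBS": sbs},
                context=(m, layer.label),
            )
    oc.training_stack = _training_climatology(oc)
    return oc


def _training_climatology(oc: SyntheticOcean) -> PredictorStack:
    """Annual-mean climatology: surface SST/SSS, deepest-level SBT/SBS.

    Mirrors the convention of pairing surface fields with
    "mean at mean (bottom) depth" fields for model training.
    """
    nlat, nlon = oc.grid.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN land columns
        t_mean = np.nanmean(np.stack([oc.temperature[m] for m in MONTHS]), axis=0)
        s_mean = np.nanmean(np.stack([oc.salinity[m] for m in MONTHS]), axis=0)
    sst = t_mean[0]
    sss = s_mean[0]
    finite = np.isfinite(t_mean)
    deepest = np.where(finite.any(axis=0), finite.shape[0] - 1 - finite[::-1].argmax(axis=0), 0)
    ii, jj = np.meshgrid(np.arange(nlat), np.arange(nlon), indexing="ij")
    sbt = t_mean[deepest, ii, jj]
    sbs = s_mean[deepest, ii, jj]
    sbt = np.where(oc.ocean_mask, sbt, np.nan)
    sbs = np.where(oc.ocean_mask, sbs, np.nan)
    return PredictorStack(
        spec=oc.grid,
        variables={"SST": sst, "SBT": sbt, "SSS": sss, "SBS": sbs},
        context="training climatology",
    )


def dome_region(oc: SyntheticOcean, depth_at_least: float = 45.0) -> np.ndarray:
    """Cells in the cold-dome core deep enough for the bottom layer."""
    grid = oc.grid
    lon = grid.lon_centers[None, :]
    lat = grid.lat_centers[:, None]
    lon_c = 0.5 * (grid.lon_min + grid.lon_max)
    lat_c = 0.5 * (grid.lat_min + grid.lat_max)
    half_lon = 0.5 * (grid.lon_max - grid.lon_min)
    half_lat = 0.5 * (grid.lat_max - grid.lat_min)
    a_frac = oc.config.dome_extent_frac
    e = ((lon - lon_c) / (a_frac * half_lon)) ** 2 + ((lat - lat_c) / (a_frac * half_lat)) ** 2
    with np.errstate(invalid="ignore"):
        deep = np.nan_to_num(oc.bathymetry, nan=0.0) >= depth_at_least
    return (e <= 0.5) & oc.ocean_mask & deep


def sample_virtual_presences(
    oc: SyntheticOcean,
    niche: NicheSpec,
    n_target: int,
    month_weights: np.ndarray | None = None,
    seed: int = 0,
    jitter_frac: float = 0.2,
) -> OccurrenceSet:
    """Draw presence records from the known niche.

    Cells are drawn (with replacement) with probability proportional to
    niche suitability evaluated on the annual-mean training
    climatology; coordinates are jittered uniformly within a fraction
    of the cell so records are not all at cell centers.  The true
    suitability of each record's cell is stored for recovery tests.
    """
    if n_target < 20:
        raise ValueError("n_target must be at least 20")
    stack = oc.training_stack
    suit = niche.suitability(stack.variables["SBT"], stack.variables["SBS"])
    suit = np.where(oc.ocean_mask, suit, 0.0)
    total = suit.sum()
    if total <= 0:
        raise ValueError("niche suitability is zero everywhere on the ocean")
    rng = np.random.default_rng(seed)
    p = (suit / total).ravel()
    cells = rng.choice(p.size, size=n_target, p=p, replace=True)
    rows, cols = np.unravel_index(cells, oc.grid.shape)
    half = jitter_frac * oc.grid.cell_deg
    lons = oc.grid.lon_centers[cols] + rng.uniform(-half, half, size=n_target)
    lats = oc.grid.lat_centers[rows] + rng.uniform(-half, half, size=n_target)
    if month_weights is None:
        months = rng.integers(1, 13, size=n_target)
    else:
        w = np.asarray(month_weights, dtype=float)
        months = rng.choice(np.arange(1, 13), size=n_target, p=w / w.sum())
    df = pd.DataFrame(
        {
            "species": "virtual_coldwater_fish",
            "lon": lons,
            "lat": lats,
            "realm": "marine",
            "month": months,
            "true_suitability": suit[rows, cols],
        }
    )
    return OccurrenceSet(records=df, provenance={"raw": n_target})
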
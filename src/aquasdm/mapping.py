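"""Decision products: high-SI areas, vertical-refuge potential area,
sinking schedules.

The vertical-refuge rule says a grid cell has aquaculture potential
if, in *every* month, at least one depth layer's SI meets the
threshold — i.e. a depth-adjustable cage can always find suitable
water somewhere in the column.  Areas are accumulated per
pseudo-absence set and summarized as mean, standard error and a
normal-approximation 95% CI (mean +/- 1.96 SE).

Cell areas come either from the WGS84 ellipsoidal area of each lon-lat
quadrangle or from a fixed constant (default 623.75 km^2, the area of
a 15-arcmin cell at 36 N), replicating the fixed-area accounting used
for the published tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec

# WGS84
_A_KM = 6378.137
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_E = np.sqrt(_E2)

#: fixed per-cell area used for reported tables (15-arcmin cell at 36 N)
FIXED_CELL_AREA_KM2 = 623.75

DEFAULT_THRESHOLDS = (0.4, 0.5, 0.6)

CI_MULTIPLIER = 1.96  # normal-approximation 95% CI


@dataclass(frozen=True)
class ThresholdPolicy:
    """SI thresholds and the qualification rule's comparison.

    ``inclusive`` reads "above the threshold" as SI >= t (the default,
    so the three reported thresholds partition maps consistently).
    """

    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    inclusive: bool = True

    def __post_init__(self) -> None:
        ts = tuple(self.thresholds)
        if any(not (0.0 < t < 1.0) for t in ts):
            raise ValueError("thresholds must lie in (0, 1)")
        if list(ts) != sorted(ts):
            raise ValueError("thresholds must be sorted ascending")

    def meets(self, si: np.ndarray, threshold: float) -> np.ndarray:
        si = np.asarray(si, dtype=float)
        ok = si >= threshold if self.inclusive else si > threshold
        return ok & np.isfinite(si)


def _authalic_q(phi: float) -> float:
    s = np.sin(phi)
    return s / (1.0 - _E2 * s * s) + np.log((1.0 + _E * s) / (1.0 - _E * s)) / (2.0 * _E)


def quadrangle_area_km2(lat_bottom: float, lat_top: float, dlon_deg: float) -> float:
    """Surface area of a lon-lat quadrangle on the WGS84 ellipsoid."""
    b2 = _A_KM**2 * (1.0 - _E2)
    dlam = np.radians(dlon_deg)
    q = _authalic_q(np.radians(lat_top)) - _authalic_q(np.radians(lat_bottom))
    return float(0.5 * b2 * dlam * q)


def cell_area_km2(
    lat_center: float,
    resolution_arcmin: float,
    mode: str = "ellipsoidal",
    fixed_value: float = FIXED_CELL_AREA_KM2,
) -> float:
    """Area of one grid cell centered at ``lat_center``.

    ``ellipsoidal`` evaluates the WGS84 quadrangle area; ``fixed``
    returns the configured constant regardless of latitude.
    """
    if mode == "fixed":
        return float(fixed_value)
    if mode != "ellipsoidal":
        raise ValueError(f"unknown area mode {mode!r}")
    if abs(lat_center) >= 89.0:
        raise ValueError("cell center too close to the pole")
    half = resolution_arcmin / 60.0 / 2.0
    return quadrangle_area_km2(lat_center - half, lat_center + half, 2.0 * half)


def cell_area_grid(spec: GridSpec, mode: str = "fixed", fixed_value: float = FIXED_CELL_AREA_KM2) -> np.ndarray:
    """(nlat, nlon) per-cell areas for a grid."""
    if mode == "fixed":
        return np.full(spec.shape, float(fixed_value))
    areas = np.array([cell_area_km2(lat, spec.resolution, mode="ellipsoidal") for lat in spec.lat_centers])
    return np.repeat(areas[:, None], spec.nlon, axis=1)


def high_si_area_series(
    cube: np.ndarray,
    threshold: float,
    cell_areas: np.ndarray | float,
    months: tuple[int, ...],
    layer_labels: tuple[str, ...],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> pd.DataFrame:
    """Area meeting the threshold, per month x layer.

    ``cube`` is (month, layer, lat, lon) SI; returns a tidy frame with
    columns month, layer, area_km2 — the seasonal expansion/contraction
    series of the high-SI habitat.
    """
    cube = np.asarray(cube, dtype=float)
    areas = np.broadcast_to(np.asarray(cell_areas, dtype=float), cube.shape[2:])
    rows = []
    for mi, m in enumerate(months):
        for li, lab in enumerate(layer_labels):
            ok = policy.meets(cube[mi, li], threshold)
            rows.append({"month": m, "layer": lab, "area_km2": float(areas[ok].sum())})
    return pd.DataFrame(rows)


def refuge_mask(
    cube: np.ndarray,
    threshold: float,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> np.ndarray:
    """Vertical-refuge qualification mask for one pseudo-absence set.

    ``cube`` is (12, n_layers, nlat, nlon).  A cell qualifies iff for
    every month the maximum SI over its *available* layers meets the
    threshold; cells missing in all layers of any month never qualify.
    """
    cube = np.asarray(cube, dtype=float)
    if cube.ndim != 4 or cube.shape[0] != 12:
        raise ValueError("refuge rule needs all 12 months: cube must be (12, layer, lat, lon)")
    ok_any_layer = policy.meets(cube, threshold).any(axis=1)  # (12, nlat, nlon)
    has_data = np.isfinite(cube).any(axis=1)
    return (ok_any_layer & has_data).all(axis=0)


def refuge_mask_bruteforce(
    cube: np.ndarray, threshold: float, inclusive: bool = True
) -> np.ndarray:
    """Per-cell per-month enumeration of the refuge rule (test oracle)."""
    cube = np.asarray(cube, dtype=float)
    n_months, n_layers, nlat, nlon = cube.shape
    out = np.zeros((nlat, nlon), dtype=bool)
    for i in range(nlat):
        for j in range(nlon):
            qualifies = True
            for m in range(n_months):
                month_ok = False
                for l in range(n_layers):
                    v = cube[m, l, i, j]
                    if np.isfinite(v) and (v >= threshold if inclusive else v > threshold):
                        month_ok = True
                        break
                if not month_ok:
                    qualifies = False
                    break
            out[i, j] = qualifies
    return out


@dataclass
class PotentialAreaResult:
    """Potential-area statistic for one SI threshold."""

    threshold: float
    masks: np.ndarray  # (n_sets, nlat, nlon) bool
    areas_km2: np.ndarray  # per set
    mean_km2: float
    se_km2: float
    ci_low_km2: float
    ci_high_km2: float

    @property
    def ci_halfwidth_km2(self) -> float:
        return CI_MULTIPLIER * self.se_km2


def area_ci(mean: float, se: float, multiplier: float = CI_MULTIPLIER) -> tuple[float, float]:
    """Normal-approximation CI bounds mean +/- multiplier * SE."""
    return mean - multiplier * se, mean + multiplier * se


def potential_area(
    masks: np.ndarray,
    cell_areas: np.ndarray | float,
    threshold: float = np.nan,
) -> PotentialAreaResult:
    """Summarize qualifying-cell masks across pseudo-absence sets.

    Per-set area is the sum of qualifying-cell areas; the result
    reports the mean, SE (sd/sqrt(n), n = sets) and 95% CI
    (mean +/- 1.96 SE), as in the published area tables.
    """
    masks = np.asarray(masks, dtype=bool)
    if masks.ndim != 3 or masks.shape[0] < 2:
        raise ValueError("need (n_sets >= 2, nlat, nlon) masks")
    areas_grid = np.broadcast_to(np.asarray(cell_areas, dtype=float), masks.shape[1:])
    per_set = np.array([float(areas_grid[m].sum()) for m in masks])
    mean = float(per_set.mean())
    se = float(per_set.std(ddof=1) / np.sqrt(len(per_set)))
    lo, hi = area_ci(mean, se)
    return PotentialAreaResult(
        threshold=float(threshold),
        masks=masks,
        areas_km2=per_set,
        mean_km2=mean,
        se_km2=se,
        ci_low_km2=lo,
        ci_high_km2=hi,
    )


def potential_area_table(results: list[PotentialAreaResult], species: str) -> pd.DataFrame:
    """Reporting table, areas rounded to integer km^2."""
    rows = [
        {
            "species": species,
            "threshold": r.threshold,
            "mean_km2": round(r.mean_km2),
            "se_km2": round(r.se_km2),
            "ci_low_km2": round(r.ci_low_km2),
            "ci_high_km2": round(r.ci_high_km2),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def sinking_schedule(
    cube: np.ndarray,
    threshold: float,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> np.ndarray:
    """Shallowest qualifying layer per cell per month.

    Returns an int array (n_months, nlat, nlon): the index of the
    shallowest layer with SI meeting the threshold, or -1 where no
    layer qualifies that month.  Layer order in ``cube`` must be
    shallow to deep.
    """
    cube = np.asarray(cube, dtype=float)
    ok = policy.meets(cube, threshold)  # (month, layer, lat, lon)
    any_ok = ok.any(axis=1)
    first = ok.argmax(axis=1)
    return np.where(any_ok, first, -1)


def sinking_schedule_bruteforce(cube: np.ndarray, threshold: float) -> np.ndarray:
    """Per-cell enumeration of the sinking schedule (test oracle)."""
    cube = np.asarray(cube, dtype=float)
    n_months, n_layers, nlat, nlon = cube.shape
    out = np.full((n_months, nlat, nlon), -1, dtype=int)
    for m in range(n_months):
        for i in range(nlat):
            for j in range(nlon):
                for l in range(n_layers):
                    v = cube[m, l, i, j]
                    if np.isfinite(v) and v >= threshold:
                        out[m, i, j] = l
                        break
    return out
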
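"""TSS-weighted ensemble suitability index (SI).

Replicate fits passing the skill filter (TSS > 0.40 and AUC > 0.70,
strict) are combined within each pseudo-absence set by a TSS-weighted
average of their predicted probabilities; the resulting SI field lies
in [0, 1].  Uncertainty comes from the spread across pseudo-absence
sets (cellwise mean and standard error, N = number of sets).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, PredictorStack
from .models import Evaluation, SdmModel


@dataclass(frozen=True)
class EnsembleSpec:
    """Skill filter and weighting for ensemble membership."""

    auc_min: float = 0.70
    tss_min: float = 0.40


@dataclass(eq=False)
class FittedReplicate:
    """One algorithm fit on one pseudo-absence set x bootstrap split."""

    algorithm: str
    pa_set_id: int
    bootstrap_id: int
    model: SdmModel
    evaluation: Evaluation


def select_members(
    replicates: list[FittedReplicate], spec: EnsembleSpec = EnsembleSpec()
) -> tuple[list[FittedReplicate], list[FittedReplicate]]:
    """Strictly filter replicates on AUC and TSS.

    Returns (members, excluded).  Raises if nothing passes, naming the
    best skill seen.
    """
    if not replicates:
        raise ValueError("no evaluations supplied")
    passing = [
        r.evaluation.auc > spec.auc_min and r.evaluation.tss > spec.tss_min
        for r in replicates
    ]
    members = [r for r, ok in zip(replicates, passing) if ok]
    excluded = [r for r, ok in zip(replicates, passing) if not ok]
    if not members:
        best_auc = max(r.evaluation.auc for r in replicates)
        best_tss = max(r.evaluation.tss for r in replicates)
        raise ValueError(
            f"no skilled models: best AUC {best_auc:.3f} (need > {spec.auc_min}), "
            f"best TSS {best_tss:.3f} (need > {spec.tss_min})"
        )
    return members, excluded


def ensemble_predict(members: list[FittedReplicate], X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """TSS-weighted average of member probabilities on rows."""
    weights = np.array([r.evaluation.tss for r in members], dtype=float)
    if (weights <= 0).any():
        raise RuntimeError("internal error: member with non-positive TSS weight")
    preds = np.stack([r.model.predict_probability(X) for r in members])
    return np.average(preds, axis=0, weights=weights)


def ensemble_si(members: list[FittedReplicate], stack: PredictorStack) -> np.ndarray:
    """SI field on a grid: weighted average per cell, NaN propagates."""
    if not members:
        raise ValueError("empty member list")
    weights = np.array([r.evaluation.tss for r in members], dtype=float)
    if (weights <= 0).any():
        raise RuntimeError("internal error: member with non-positive TSS weight")
    fields = np.stack([r.model.predict_stack(stack) for r in members])
    return np.average(fields, axis=0, weights=weights)


@dataclass
class SiCube:
    """SI on grid x month x layer, per pseudo-absence set.

    ``si`` has shape (n_sets, n_months, n_layers, nlat, nlon);
    aggregation over sets gives the mean map and its standard error.
    """

    si: np.ndarray
    months: tuple[int, ...]
    layer_labels: tuple[str, ...]
    spec: GridSpec

    def __post_init__(self) -> None:
        self.si = np.asarray(self.si, dtype=float)
        if self.si.ndim != 5:
            raise ValueError("SI cube must be 5-D (set, month, layer, lat, lon)")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.si) < 0 or np.nanmax(self.si) > 1:
                raise ValueError("SI outside [0, 1]")

    @property
    def n_sets(self) -> int:
        return self.si.shape[0]

    def set_cube(self, k: int) -> np.ndarray:
        """(month, layer, lat, lon) SI for pseudo-absence set k."""
        return self.si[k]

    def aggregate(self) -> tuple[np.ndarray, np.ndarray]:
        return aggregate_si(list(self.si))

    def to_dataset(self):
        """CF-style xarray Dataset with si_mean and si_se."""
        import xarray as xr

        mean, se = self.aggregate()
        coords = {
            "month": list(self.months),
            "layer": list(self.layer_labels),
            "lat": self.spec.lat_centers,
            "lon": self.spec.lon_centers,
        }
        dims = ("month", "layer", "lat", "lon")
        ds = xr.Dataset(
            {
                "si_mean": (dims, mean),
                "si_se": (dims, se),
                "si": (("pa_set",) + dims, self.si),
            },
            coords={**coords, "pa_set": np.arange(1, self.n_sets + 1)},
        )
        ds["si_mean"].attrs["long_name"] = "ensemble suitability index, mean over pseudo-absence sets"
        ds["si_se"].attrs["long_name"] = "standard error of the suitability index (N = pseudo-absence sets)"
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        return ds

    @classmethod
    def from_dataset(cls, ds, resolution: float) -> "SiCube":
        lat = np.asarray(ds["lat"])
        lon = np.asarray(ds["lon"])
        cell = resolution / 60.0
        spec = GridSpec(
            lon_min=float(lon.min() - cell / 2),
            lon_max=float(lon.max() + cell / 2),
            lat_min=float(lat.min() - cell / 2),
            lat_max=float(lat.max() + cell / 2),
            resolution=resolution,
        )
        return cls(
            si=np.asarray(ds["si"]),
            months=tuple(int(m) for m in np.asarray(ds["month"])),
            layer_labels=tuple(str(l) for l in np.asarray(ds["layer"].values)),
            spec=spec,
        )


def aggregate_si(cubes: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Cellwise mean and SE (sd/sqrt(n)) over pseudo-absence sets.

    All cubes must share shape and missing-data mask.
    """
    if len(cubes) < 2:
        raise ValueError("need at least 2 pseudo-absence sets to aggregate")
    arr = np.stack([np.asarray(c, dtype=float) for c in cubes])
    masks = np.isfinite(arr)
    if not (masks == masks[0]).all():
        raise ValueError("mismatched missing-data masks across sets")
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
    return mean, se
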
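#!/usr/bin/env python
"""Step 1: synthesize the ocean climatology and virtual-species occurrences.

Writes the training climatology, monthly depth-layer predictor grids
(as one NetCDF), the raw and thinned occurrence sets, and a truth file
recording the virtual species' niche parameters.

Usage: python analysis/01_simulate_ocean.py [--out analysis/results/data]
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import xarray as xr

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from aquasdm import (  # noqa: E402
    NicheSpec,
    SyntheticOceanConfig,
    clean_occurrences,
    make_ocean,
    sample_virtual_presences,
    stage_seed,
    thin_occurrences,
    write_occurrences_csv,
)
from aquasdm.synthetic import MONTHS  # noqa: E402


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("analysis/results/data"))
    parser.add_argument("--n-presences", type=int, default=300)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SyntheticOceanConfig()
    niche = NicheSpec()
    ocean = make_ocean(cfg)

    grid = ocean.grid
    coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
    ds = xr.Dataset(
        {name: (("lat", "lon"), arr) for name, arr in ocean.training_stack.variables.items()},
        coords=coords,
    )
    ds["bathymetry"] = (("lat", "lon"), ocean.bathymetry)
    ds.to_netcdf(args.out / "training_climatology.nc", engine="scipy")

    labels = ocean.layer_labels
    sbt = np.stack([[ocean.stacks[(m, lab)].variables["SBT"] for lab in labels] for m in MONTHS])
    xr.Dataset(
        {"SBT": (("month", "layer_index", "lat", "lon"), sbt)},
        coords={"month": list(MONTHS), "layer_index": np.arange(len(labels)), **coords},
        attrs={"layer_labels": ", ".join(labels)},
    ).to_netcdf(args.out / "monthly_layer_sbt.nc", engine="scipy")

    raw = sample_virtual_presences(ocean, niche, args.n_presences, seed=stage_seed(cfg.seed, "presences"))
    write_occurrences_csv(raw, args.out / "occurrences_raw.csv")
    cleaned = clean_occurrences(raw.records, ocean.ocean_mask, grid)
    thinned = thin_occurrences(cleaned, min_dist_km=10.0, iterations=100, seed=stage_seed(cfg.seed, "thin"))
    write_occurrences_csv(thinned, args.out / "occurrences_thinned.csv")

    (args.out / "truth.json").write_text(
        json.dumps(
            {
                "niche": {
                    "optimum_low_degC": niche.optimum_low,
                    "optimum_high_degC": niche.optimum_high,
                    "salinity_center_psu": niche.salinity_center,
                },
                "ocean_seed": cfg.seed,
                "n_ocean_cells": int(ocean.ocean_mask.sum()),
                "n_raw": len(raw),
                "n_thinned": len(thinned),
            },
            indent=2,
        )
    )
    print(f"ocean: {grid.shape} cells, {int(ocean.ocean_mask.sum())} marine; "
          f"occurrences {len(raw)} -> {len(thinned)} after thinning; wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
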
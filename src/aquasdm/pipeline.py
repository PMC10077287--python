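"""End-to-end run orchestration.

A single :class:`RunConfig` (loadable from YAML) drives the full
chain: synthesize (or load) the environment, sample and thin the
virtual presences, screen predictors for collinearity, fit the four
algorithms over pseudo-absence sets x bootstrap replicates, filter and
TSS-weight the ensemble, project SI over months x depth layers, and
derive the mapping products (high-SI area series, refuge masks,
potential-area statistics, sinking schedules).

Every stage's randomness derives deterministically from the master
seed via ``stage_seed``; a manifest records counts, seeds and hashes
so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import EnsembleSpec, FittedReplicate, SiCube, ensemble_si, select_members
from .grids import VARIABLES, extract_at_points, vif
from .mapping import (
    FIXED_CELL_AREA_KM2,
    PotentialAreaResult,
    ThresholdPolicy,
    cell_area_grid,
    high_si_area_series,
    potential_area,
    potential_area_table,
    refuge_mask,
    sinking_schedule,
)
from .models import (
    ALGORITHMS,
    bootstrap_splits,
    build_training_table,
    evaluate,
    fit_model,
    response_curve,
    sample_pseudo_absences,
    variable_importance,
)
from .occurrences import OccurrenceSet, clean_occurrences, thin_occurrences, write_occurrences_csv
from .synthetic import MONTHS, NicheSpec, SyntheticOcean, SyntheticOceanConfig, make_ocean, sample_virtual_presences

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str, replicate: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Changing one replicate's seed leaves the others untouched; values
    stay below 2^31.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}:{replicate}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class RunConfig:
    """All knobs of one reproducible run, with the published defaults.

    Thinning 10 km x 100 iterations; 10 pseudo-absence sets; 1:1
    background for RF/SVM/BRT and 10,000 for MaxEnt; 75/25 bootstrap
    x 10 replicates; skill filter AUC > 0.70, TSS > 0.40; SI
    thresholds 0.4/0.5/0.6; fixed 623.75 km^2 cell area.
    """

    species_id: str = "virtual_coldwater_fish"
    ocean: SyntheticOceanConfig = field(default_factory=SyntheticOceanConfig)
    niche: NicheSpec = field(default_factory=NicheSpec)
    n_presences: int = 300
    thin_dist_km: float = 10.0
    thin_iterations: int = 100
    n_pa_sets: int = 10
    n_background_maxent: int = 10_000
    n_bootstrap: int = 10
    train_frac: float = 0.75
    algorithms: tuple[str, ...] = ALGORITHMS
    ensemble: EnsembleSpec = field(default_factory=EnsembleSpec)
    thresholds: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    area_mode: str = "fixed"  # or "ellipsoidal"
    fixed_cell_area_km2: float = FIXED_CELL_AREA_KM2
    master_seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "ocean" in kwargs:
            oc = dict(kwargs["ocean"])
            if "grid" in oc:
                from .grids import GridSpec

                oc["grid"] = GridSpec(**oc["grid"])
            kwargs["ocean"] = SyntheticOceanConfig(**oc)
        if "niche" in kwargs:
            kwargs["niche"] = NicheSpec(**kwargs["niche"])
        if "ensemble" in kwargs:
            kwargs["ensemble"] = EnsembleSpec(**kwargs["ensemble"])
        if "thresholds" in kwargs:
            th = kwargs["thresholds"]
            kwargs["thresholds"] = (
                ThresholdPolicy(thresholds=tuple(th)) if isinstance(th, (list, tuple)) else ThresholdPolicy(**th)
            )
        if "algorithms" in kwargs:
            kwargs["algorithms"] = tuple(kwargs["algorithms"])
        return cls(**kwargs)


@dataclass
class RunResult:
    """Everything a run produces, in memory."""

    config: RunConfig
    ocean: SyntheticOcean
    occurrences: OccurrenceSet
    vif: pd.Series
    replicates: list[FittedReplicate]
    members_per_set: dict[int, list[FittedReplicate]]
    si_cube: SiCube
    area_series: dict[float, pd.DataFrame]
    potential: dict[float, PotentialAreaResult]
    schedules: dict[float, np.ndarray]
    importance: pd.DataFrame  # rows: pa_set, columns: variables
    response_curves: dict[str, pd.DataFrame]
    evaluations: pd.DataFrame
    manifest: dict


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage
        self.manifest = manifest


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full modelling and mapping chain for one species."""
    manifest: dict = {
        "version": __version__,
        "species": config.species_id,
        "master_seed": config.master_seed,
        "stages": {},
    }

    def fail(stage: str, exc: Exception) -> StageError:
        return StageError(stage, str(exc), manifest)

    # --- synthetic environment -------------------------------------------
    # The ocean and the occurrence sample are the *data* of the study:
    # they are governed by the ocean config's own seed, not the master
    # seed, which drives only the analysis randomness (pseudo-absence
    # sets, bootstrap splits, model fits) — as reruns of the published
    # analysis would re-randomize the modelling but not the downloads.
    stage = "synth_ocean"
    try:
        ocean = make_ocean(config.ocean)
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc)
    manifest["stages"][stage] = {
        "seed": ocean.config.seed,
        "grid": ocean.grid.shape,
        "ocean_cells": int(ocean.ocean_mask.sum()),
        "hash": _hash_array(np.nan_to_num(ocean.training_stack.variables["SBT"])),
    }
    log.info("ocean: %s cells, %d marine", ocean.grid.shape, ocean.ocean_mask.sum())

    # --- occurrences: sample, clean, thin --------------------------------
    stage = "occurrences"
    try:
        occ_raw = sample_virtual_presences(
            ocean,
            config.niche,
            n_target=config.n_presences,
            seed=stage_seed(config.ocean.seed, "presences"),
        )
        occ_clean = clean_occurrences(occ_raw.records, ocean.ocean_mask, ocean.grid)
        occ = thin_occurrences(
            occ_clean,
            min_dist_km=config.thin_dist_km,
            iterations=config.thin_iterations,
            seed=stage_seed(config.ocean.seed, "thin"),
        )
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc)
    manifest["stages"][stage] = dict(occ.provenance)
    log.info("occurrences: %s", occ.provenance)

    # --- training rows and collinearity screen ---------------------------
    stage = "screen"
    try:
        presence_rows, n_dropped = extract_at_points(ocean.training_stack, occ.lons, occ.lats)
        vifs, vif_pass = vif(presence_rows)
        if not vif_pass:
            raise ValueError(
                "collinearity screen failed: "
                + ", ".join(f"{k} VIF={v:.1f}" for k, v in vifs.items() if not v <= 10.0)
            )
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc)
    manifest["stages"][stage] = {
        "n_presence_rows": len(presence_rows),
        "dropped_on_missing": n_dropped,
        "vif": {k: float(v) for k, v in vifs.items()},
    }
    log.info("VIF screen passed: %s", dict(vifs.round(2)))

    # --- fit x evaluate over pseudo-absence sets and bootstraps ----------
    stage = "fit"
    replicates: list[FittedReplicate] = []
    members_per_set: dict[int, list[FittedReplicate]] = {}
    si_sets: list[np.ndarray] = []
    importance_rows = []
    curve_store: dict[str, list[pd.DataFrame]] = {v: [] for v in VARIABLES}
    presence_cells = presence_rows["cell"].to_numpy()
    layer_labels = tuple(ocean.layer_labels)
    try:
        for pa_id in range(1, config.n_pa_sets + 1):
            rng_bg = np.random.default_rng(stage_seed(config.master_seed, "background", pa_id))
            bg_one, _ = sample_pseudo_absences(
                ocean.training_stack, presence_cells, len(presence_rows), rng_bg
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # cap warning expected on small synthetic oceans
                bg_maxent, _ = sample_pseudo_absences(
                    ocean.training_stack, presence_cells, config.n_background_maxent, rng_bg
                )
            table_one = build_training_table(presence_rows, bg_one)
            table_maxent = build_training_table(presence_rows, bg_maxent)
            splits_one = bootstrap_splits(
                table_one, config.train_frac, config.n_bootstrap,
                seed=stage_seed(config.master_seed, "split_one", pa_id),
            )
            splits_maxent = bootstrap_splits(
                table_maxent, config.train_frac, config.n_bootstrap,
                seed=stage_seed(config.master_seed, "split_maxent", pa_id),
            )
            set_reps: list[FittedReplicate] = []
            for boot_id in range(1, config.n_bootstrap + 1):
                for algo in config.algorithms:
                    table, splits = (
                        (table_maxent, splits_maxent) if algo == "MaxEnt" else (table_one, splits_one)
                    )
                    tr, te = splits[boot_id - 1]
                    seed = stage_seed(config.master_seed, f"fit_{algo}", pa_id * 1000 + boot_id)
                    model = fit_model(algo, table.iloc[tr], seed=seed)
                    ev = evaluate(model, table.iloc[te])
                    set_reps.append(
                        FittedReplicate(
                            algorithm=algo, pa_set_id=pa_id, bootstrap_id=boot_id, model=model, evaluation=ev
                        )
                    )
            replicates.extend(set_reps)
            members, excluded = select_members(set_reps, config.ensemble)
            members_per_set[pa_id] = members
            log.info("PA set %d: %d/%d replicates pass the skill filter", pa_id, len(members), len(set_reps))

            # per-set SI cube over months x layers
            cube = np.stack(
                [
                    np.stack([ensemble_si(members, ocean.stacks[(m, lab)]) for lab in layer_labels])
                    for m in MONTHS
                ]
            )
            si_sets.append(np.clip(cube, 0.0, 1.0))

            # per-set interpretation on this set's 1:1 table
            imp_seed = stage_seed(config.master_seed, "importance", pa_id)
            imps = []
            for rep in members:
                imps.append(variable_importance(rep.model, table_one, seed=imp_seed))
            if imps:
                w = np.array([r.evaluation.tss for r in members])
                imp = pd.concat(imps, axis=1).T.mul(w, axis=0).sum() / w.sum()
                importance_rows.append(imp.rename(pa_id))
            for var in VARIABLES:
                curves = [response_curve(rep.model, var) for rep in members]
                if curves:
                    w = np.array([r.evaluation.tss for r in members])
                    grid = curves[0]["value"]
                    probs = np.average(
                        np.stack([np.interp(grid, c["value"], c["probability"]) for c in curves]),
                        axis=0,
                        weights=w,
                    )
                    curve_store[var].append(pd.DataFrame({"value": grid, "probability": probs, "pa_set": pa_id}))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc)

    evaluations = pd.DataFrame(
        [
            {
                "algorithm": r.algorithm,
                "pa_set": r.pa_set_id,
                "bootstrap": r.bootstrap_id,
                "auc": r.evaluation.auc,
                "tss": r.evaluation.tss,
                "threshold": r.evaluation.threshold,
            }
            for r in replicates
        ]
    )
    manifest["stages"][stage] = {
        "n_fits": len(replicates),
        "n_pa_sets": config.n_pa_sets,
        "n_bootstrap": config.n_bootstrap,
        "algorithms": list(config.algorithms),
        "n_members": {k: len(v) for k, v in members_per_set.items()},
        "mean_auc": float(evaluations["auc"].mean()),
        "mean_tss": float(evaluations["tss"].mean()),
    }

    # --- aggregate SI and mapping products -------------------------------
    stage = "map"
    try:
        si_cube = SiCube(
            si=np.stack(si_sets), months=MONTHS, layer_labels=layer_labels, spec=ocean.grid
        )
        areas = cell_area_grid(ocean.grid, mode=config.area_mode, fixed_value=config.fixed_cell_area_km2)
        mean_si, _ = si_cube.aggregate()
        area_series = {}
        potential = {}
        schedules = {}
        for t in config.thresholds.thresholds:
            area_series[t] = high_si_area_series(
                mean_si, t, areas, MONTHS, layer_labels, policy=config.thresholds
            )
            masks = np.stack([refuge_mask(si_cube.set_cube(k), t, config.thresholds) for k in range(si_cube.n_sets)])
            potential[t] = potential_area(masks, areas, threshold=t)
            schedules[t] = sinking_schedule(mean_si, t, config.thresholds)
    except Exception as exc:  # noqa: BLE001
        raise fail(stage, exc)
    manifest["stages"][stage] = {
        "si_hash": _hash_array(np.nan_to_num(si_cube.si)),
        "potential_area_km2": {
            str(t): {"mean": r.mean_km2, "se": r.se_km2, "ci": [r.ci_low_km2, r.ci_high_km2]}
            for t, r in potential.items()
        },
    }

    importance = pd.DataFrame(importance_rows)
    curves = {v: pd.concat(c, ignore_index=True) for v, c in curve_store.items() if c}

    result = RunResult(
        config=config,
        ocean=ocean,
        occurrences=occ,
        vif=vifs,
        replicates=replicates,
        members_per_set=members_per_set,
        si_cube=si_cube,
        area_series=area_series,
        potential=potential,
        schedules=schedules,
        importance=importance,
        response_curves=curves,
        evaluations=evaluations,
        manifest=manifest,
    )
    if config.out_dir:
        write_outputs(result, Path(config.out_dir))
    return result


def write_outputs(result: RunResult, out_dir: Path) -> None:
    """Persist the run: CSV tables, NetCDF SI cube, JSON manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    write_occurrences_csv(result.occurrences, out_dir / "occurrences_thinned.csv")
    result.evaluations.to_csv(out_dir / "evaluations.csv", index=False)
    result.importance.rename_axis("pa_set").to_csv(out_dir / "variable_importance.csv")
    pd.concat(
        [df.assign(threshold=t) for t, df in result.area_series.items()], ignore_index=True
    ).to_csv(out_dir / "high_si_area_series.csv", index=False)
    potential_area_table(
        list(result.potential.values()), result.config.species_id
    ).to_csv(out_dir / "potential_area.csv", index=False)
    for var, df in result.response_curves.items():
        df.to_csv(out_dir / f"response_curve_{var}.csv", index=False)
    ds = result.si_cube.to_dataset()
    ds.to_netcdf(out_dir / "si_cube.nc", engine="scipy")
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))
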
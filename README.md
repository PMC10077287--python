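# aquasdm

Ensemble species-distribution modelling (SDM) for offshore-aquaculture
site suitability, with depth-stratified monthly suitability maps and
vertical-refuge potential-area statistics.

The motivating question: where could cold-water fish (salmonids) be
farmed offshore in a temperate marginal sea whose surface is too warm
in summer, if depth-adjustable cages can sink into cold bottom water —
the "cool refuge" under the seasonal thermocline?  The package answers
it end to end on a fully synthetic, self-contained testbed: a
Yellow-Sea-like ocean climatology with a seasonal cold bottom-water
dome, a virtual cold-water species with a known thermal niche, an
ensemble of four presence/background classifiers, and area accounting
for cells where *some* depth layer is suitable in *every* month.

Because the species' niche is known by construction, every stage can
be validated by parameter recovery rather than by eye.

## Layout

- `src/aquasdm/` — the library:
  - `grids.py` — lon-lat grids, depth layers, predictor stacks, VIF screen
  - `occurrences.py` — occurrence cleaning and spThin-style spatial thinning
  - `synthetic.py` — the synthetic ocean and virtual species
  - `models.py` — RF / MaxEnt-equivalent / SVM / BRT learners, AUC/TSS,
    permutation importance, response curves
  - `ensemble.py` — skill filter, TSS-weighted SI, SI cubes
  - `mapping.py` — cell areas, high-SI area series, vertical-refuge rule,
    potential-area statistics, sinking schedules
  - `pipeline.py` — one-config end-to-end orchestration with a manifest
  - `cli.py` — `aquasdm synth|thin|run|map`
- `analysis/` — numbered drivers reproducing the study:
  `01_simulate_ocean.py`, `02_fit_ensemble.py`, `03_map_potential_areas.py`
- `scripts/acceptance.py` — computes the headline quantities as JSON
- `tests/` — unit, property-based and acceptance suites
- `docs/methods.md` — methods and design notes

## Install and run

```sh
pip install --no-build-isolation -e .[test]
pytest

# the three-step analysis
python analysis/01_simulate_ocean.py
python analysis/02_fit_ensemble.py --seed 0
python analysis/03_map_potential_areas.py

# or in one shot
aquasdm run --seed 0 --out results/run
```

Outputs land under `analysis/results/` (or `--out`): thinned
occurrences, per-replicate evaluations, TSS-weighted variable
importance, response curves, the monthly × depth-layer SI cube
(NetCDF), high-SI area series, potential-area tables with 95%
confidence intervals over pseudo-absence sets, and a JSON manifest of
seeds, counts and hashes.

## Method in one paragraph

Virtual-species presences are drawn from the known niche on the
annual-mean climatology, cleaned and spatially thinned (10 km,
best-of-100 randomized maximal-degree deletion).  Predictors (surface
and bottom temperature and salinity) pass a VIF ≤ 10 collinearity
screen.  Random forest, a MaxEnt equivalent (L1-penalized logistic
regression on linear/quadratic/product/hinge features), an RBF SVM and
boosted regression trees are fitted per pseudo-absence set (1:1
background for the tree/SVM models, large fixed background for
MaxEnt) over stratified 75/25 bootstrap splits.  Replicates with
held-out AUC > 0.70 and TSS > 0.40 form the ensemble; their
TSS-weighted mean probability is the suitability index (SI), projected
for each calendar month × 15 m depth layer.  A cell has aquaculture
potential if in every month at least one layer's SI meets the
threshold (0.4 / 0.5 / 0.6); areas are summed per pseudo-absence set
and reported as mean ± SE with a 1.96·SE normal 95% CI.

## Reproducibility

All randomness derives from two seeds: the synthetic-ocean seed fixes
the *data* (ocean fields, presence sample, thinning), and the master
seed drives the *analysis* randomness (pseudo-absence sets, bootstrap
splits, model fits).  Rerunning with the same seeds reproduces every
artifact bit for bit; the manifest records stage hashes so this can be
checked.
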
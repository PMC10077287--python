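# Methods and design notes

This note records the modelling conventions and the design of the
synthetic testbed in enough detail to re-derive every number the
package produces.

## 1. Grids, layers and areas

Grids are cell-center registered WGS84 lon-lat rasters; the extent
bounds are outer cell edges and the resolution is in arc-minutes.  The
default study domain is 120–130°E, 31–41°N at 15′ (40 × 40 cells).
Depth is discretized at the standard levels 0, 5, …, 60 m and
aggregated into four 15 m bands (0–15, 15–30, 30–45, 45–60 m) by
unweighted averaging of the levels falling in the closed interval, so
a boundary level (e.g. 15 m) contributes to both adjacent bands.  A
band is missing wherever the seafloor is shallower than its top.

Cell areas use either the exact WGS84 ellipsoidal quadrangle area
(closed form via the authalic integral, verified against numerical
quadrature) or a fixed 623.75 km² per cell — the 15′ quadrangle area
near 36°N — matching fixed-area accounting in reported tables.  The
ellipsoidal value at 36°N is 625.3 km², within 0.25% of the fixed
constant.

## 2. Occurrences

Cleaning stages, each logged in a provenance dict: coordinate
validation → exact-duplicate removal (6-decimal rounding) → marine
filter (a realm flag wins where present, otherwise a nearest-cell
ocean-mask lookup).  Spatial thinning enforces a 10 km minimum
pairwise haversine distance (R = 6371 km) with the spThin algorithm:
repeatedly delete a maximum-degree record from the proximity graph
(ties broken uniformly at random), run 100 independent attempts, and
keep the largest retained set.  On ≤ 12 points this matches a
brute-force maximum independent set almost always (tested).

## 3. Predictors and screening

Four predictors: sea-surface temperature and salinity (SST, SSS) and
"bottom" temperature and salinity (SBT, SBS).  Training uses the
annual-mean climatology with SST/SSS from the surface and SBT/SBS from
the deepest wet level per cell; monthly depth-layer projection stacks
pair the surface-layer SST/SSS with the target layer's SBT/SBS.
Collinearity is screened at the presence cells with VIF = 1/(1−R²)
from OLS; any VIF > 10 aborts the run at the screening stage.

## 4. Models and evaluation

Per pseudo-absence set, background cells are sampled uniformly without
replacement from marine non-presence cells: one background per
presence for RF/SVM/BRT and a fixed 10,000 for the MaxEnt equivalent
(capped at the eligible-cell count on small domains, with a warning).
Splits are stratified 75/25 random partitions, repeated per bootstrap
replicate.

- RF: 500-tree random forest, probability = vote fraction.
- SVM: RBF kernel with probability calibration, standardized inputs.
- BRT: gradient boosting with logistic loss, learning rate 0.01, up to
  3000 trees with internal-holdout early stopping.
- MaxEnt equivalent: L1-penalized presence/background logistic
  regression on a MaxEnt-style basis (linear, quadratic, pairwise
  products, 10 hinge knots per variable at training quantiles), the
  penalty chosen by cross-validated held-out likelihood.  This is the
  penalized-GLM formulation of MaxEnt (the `maxnet` equivalence), used
  because no MaxEnt binary is assumed available.

Held-out skill: AUC as the normalized Mann–Whitney U (ties counted
half) and TSS = max(sensitivity + specificity − 1) over an exhaustive
scan of the observed scores with the "predict present if score ≥ t"
rule.  Replicates pass into the ensemble iff AUC > 0.70 and
TSS > 0.40 (strict).  The ensemble SI is the TSS-weighted mean of
member probabilities, in [0, 1].

Interpretation: permutation importance is the mean over permutations
of 1 − Pearson r between intact and permuted-column predictions,
clipped to [0, 1], TSS-weighted over ensemble members; response curves
sweep one variable over its training range with the others held at
training means.  Note the off-manifold caveat: with correlated
predictors a one-variable sweep leaves the training manifold, so
curves are trustworthy near the data and arbitrary far from it — the
recovery claims below are therefore about the peak location, not the
tails.

## 5. Mapping products

For each SI threshold (0.4 / 0.5 / 0.6, inclusive ≥):

- High-SI area series: per month × layer, the sum of cell areas with
  SI ≥ t (the seasonal expansion/contraction of suitable habitat).
- Vertical-refuge rule: a cell qualifies iff in every month the
  maximum SI over its available layers meets the threshold.  Masks are
  computed per pseudo-absence set; per-set areas are summarized as
  mean ± SE (sd/√n over sets) with a 1.96·SE 95% CI.  Masks nest
  monotonically across thresholds by construction.
- Sinking schedule: per qualifying cell and month, the shallowest
  layer with SI ≥ t (the depth a cage must sink to that month).

## 6. The synthetic ocean

The generator builds a deterministic (seeded) marginal-sea analogue
whose physics create exactly the structure the method is meant to
detect:

- Basin: a bowl-shaped deep basin (to 75 m) closed by land, with the
  rim drawn in on the northern side; broad shallow shelves to the
  south and far north, plus a flat open shelf spanning the southern
  margin.  A mid-depth (40 m) trough channel runs along the eastern
  margin into the warm south; it floors above the deepest (45–60 m)
  layer, so that layer exists only over the central basin.
- Surface cycle: a sinusoid between winter minimum and summer maximum
  with latitude gradients much steeper in winter than summer, so the
  south is subtropical (warm, small amplitude) and the north
  cold-temperate — the meridional spread that makes a 5–18 °C niche
  identifiable from an annual-mean climatology.  Open-ocean SST is
  capped (convective regulation), which also bounds the warm-edge
  extrapolation of monthly projections relative to training.  In
  winter a convective adjustment acts over deep water: a cold surface
  over the warm deep reservoir is statically unstable, so the column
  overturns and the surface relaxes to the reservoir temperature —
  the warm winter surface tongue that deep marginal seas show over
  their troughs.  This keeps winter SST over the basin inside the
  training envelope instead of below seawater freezing.
- Cold dome: an elliptical bottom-water core over the deep basin is
  pinned at 8 °C (< 10 °C) from May to November below ~30–45 m, under
  a warm summer surface — the cold-water-mass analogue that provides
  the vertical refuge.  Outside the dome, bottom water follows a
  cold, weakly graded background with a damped, lagged seasonal
  wobble (thermal inertia), so surface and bottom converge in late
  autumn (vertical homogenization).
- Salinity: fresh river plume over the southwestern shelf, a coastal
  freshwater lens over shallow water, a fresh western-boundary strip,
  and stable saline deep water.  Persistent smooth anomalies give the
  bottom fields their own history so they are not collinear with the
  surface fields (keeping VIFs well under 10).
- The eastern trough matters for model identifiability: it places
  genuinely cold bottom water under a subtropical surface, so the
  training climatology contains (warm SST, cold SBT) presences and
  the models learn that bottom temperature, not surface temperature,
  controls suitability.  Without it, tree ensembles veto warm-surface
  cells and the deep summer refuge is spuriously penalized.

The virtual species has suitability 1 on an SBT plateau (default
5–18 °C) with logistic tails (1 °C scale) and a weak Gaussian bottom-
salinity tolerance (33 ± 6 psu).  Presences are drawn with replacement
∝ suitability on the training climatology, jittered within cells.

## 7. Seeding and reproducibility

`stage_seed(master, stage, replicate)` derives independent 31-bit
stage seeds by SHA-256.  The ocean config's own seed governs the
*data*: ocean fields, presence sampling and thinning.  The run's
master seed governs only *analysis* randomness: pseudo-absence sets,
bootstrap splits and stochastic model fits.  Re-running the analysis
with a new master seed re-randomizes the modelling but not the data,
mirroring how a published analysis would be replicated against fixed
downloads.  The run manifest records seeds, counts and SHA-256 field
hashes per stage; a failed stage aborts with its name and the partial
manifest.

## 8. Validation strategy

- Closed-form pieces (areas, CI arithmetic, AUC/TSS) are checked
  against independent oracles: quadrature for ellipsoidal areas,
  pairwise counting/`roc_auc_score` for AUC, exhaustive scans for TSS,
  per-cell enumeration for refuge masks and sinking schedules,
  brute-force maximum independent sets for thinning.
- The synthetic study is checked by parameter recovery: SBT has the
  largest ensemble importance, the SBT response peak falls inside the
  true plateau (±2 °C), the deepest layer's high-SI area is stable
  across months while the surface layer contracts strongly in
  July–September, and refuge masks nest across thresholds.
- A null-skill control with permuted labels confirms held-out AUC
  near 0.5 and that the skill filter rejects everything.
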
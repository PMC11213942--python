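# Methods

This note documents the models, algorithms and numerical choices behind
`temporalcropnet`, the assumptions each stage makes, and what the synthetic
data can and cannot tell you about real terrestrial-laser-scanning (TLS)
campaigns.

## 1. From point cloud to per-plant records

### Outlier removal

"Neighbourhood thresholding" is implemented as statistical outlier removal
on k-nearest-neighbour distances: for each point the mean distance `d_i` to
its `k` nearest neighbours is computed (k-d tree), and points with
`d_i > mean(d) + m·sd(d)` are excised. Defaults `k = 8`, `m = 3.0`. The
rule is scale-free but sensitive to strong density mixtures (dense canopy
next to sparse ground raises the threshold); for the densities the package
targets this is benign. Note that on a finite regular grid the rule removes
extreme boundary points (corner neighbourhoods are genuinely sparser) —
this is the rule working as stated, not a defect.

### Tiling

Large clouds are split into a regular grid of tiles with a configurable
buffer (default 1 m) so the ground filter sees context beyond each tile's
core. Core ownership uses half-open intervals; points on the global max
edge belong to the last row/column, so tile cores partition the cloud
exactly.

### Ground classification (progressive TIN densification)

Seed points are the lowest return per coarse cell (default 1 m, roughly the
planting spacing). A Delaunay triangulation of the current ground set is
iteratively densified: an unclassified point whose xy falls in a facet is
accepted as ground when

* its perpendicular distance to the facet is ≤ `max_dist`, and
* the segment to the facet's nearest vertex makes an angle ≤ `max_angle`
  with the facet plane.

Two robustness measures are added on top of this classic acceptance rule:

* **Facet-slope guard.** Facets steeper than `max_facet_slope` (default
  45°) never accept points. Without it, near-vertical sliver facets that
  arise along canopy fringes accept the points directly above them (both
  criteria are trivially satisfied against a vertical plane) and the
  densification ladders up any dense, smooth canopy surface. Agricultural
  terrain is nearly flat, so the guard costs nothing there.
* **Final buffer pass.** After the iteration converges, all points within
  `max_dist` of the converged surface are classified ground. At TLS point
  densities the angle criterion is conservative: a noisy ground return a
  few sigma above a locally dense TIN is geometrically indistinguishable
  from low vegetation, and without the pass ~25% of noisy ground points
  are never accepted. This mirrors the buffer classification used by
  production ground filters.

Points outside the current hull (boundary strips) are tested against the
nearest ground vertex with the same distance bound and the angle measured
from the horizontal; on terrain steeper than `max_angle` this boundary
treatment would be biased, which is irrelevant at field slopes of a few
percent.

Parameter scales matter: for 0.1–1 m vegetable crops the pipeline default
is `max_dist = 0.05 m`, `max_angle = 30°`, seed grid 1 m. The buffer pass
makes `max_dist` an effective *minimum detectable canopy height*: crowns
shorter than roughly `max_dist` plus the local TIN error are absorbed into
the ground class. A 0.10 m threshold (appropriate for rougher terrain)
visibly truncates 0.2 m plants; 0.05 m (≈4–5 sigma of centimetre sensor
noise) keeps ≥99% ground accuracy while leaving short crowns intact.
`classify_ground_ptd` itself defaults to 0.10 m for standalone use.

### Normalization and the canopy height model

Heights are normalized point-wise against the barycentric interpolation of
the ground TIN ("furrow-level datum"), not against a single plane constant;
queries outside the hull extrapolate the nearest vertex's elevation and are
flagged. Negative normalized heights (sensor noise below the fitted ground)
are clamped to zero with a logged count.

The CHM stores, per cell, the maximum normalized height of above-ground
points; cells containing only ground points are 0 and empty cells carry the
nodata sentinel (−1.0 internally; tagged in GeoTIFF output). Convention:
south-west origin, row 0 southernmost, half-open cells; the GeoTIFF writer
flips rows at the file boundary (TIFF row 0 is north) and writes
ModelPixelScale/ModelTiepoint/GDAL_NODATA tags.

Default resolution is 0.015 m: about twice the study-scale TLS point
spacing (6.1 mm at 10 m), ≥13 cells across the smallest crowns, and per-cell
occupancy ≥ ~2 points at the preset densities. Isolated nodata pits (the
apex region of a crown is horizontally sparse when surfaces are sampled
uniformly in height) are filled by a median filter over valid neighbours —
a nodata cell is filled when at least half its window is valid; each call
is a single pass, and the pipeline applies two passes by default so
two-cell pits also close while large true gaps stay open.

### Crown tops, delineation, records

The variable window filter marks a cell as a crown top when its value is at
least `min_height` (default 0.10 m, above soil roughness) and strictly
greater than every valid cell whose center lies within
`r(h) = max(r_min, c·h)` of it — defaults `r_min = 0.10 m`, `c = 0.3`
(vegetable crown radius ≈ 30% of height). Ties on plateaus keep only the
first cell in row-major order, preventing double counting.

Crowns are delineated by marker-based watershed on the negated CHM
(compactness 0), restricted to the canopy mask `CHM ≥ min_height`, with the
detected tops as markers; segments without a top are pruned and survivors
renumbered in top order. Per segment: height = max CHM value, crown area =
cell count × resolution², centroid = mean of cell centers. Plants are
chained across dates by greedy nearest-centroid matching (closest pairs
first) under a 0.3 m displacement bound — plants do not move; the bound
absorbs centroid jitter. Only plants present at every date yield a series.

## 2. The forecaster

`TemporalCropNet` consumes, per plant, the (height, crown area) pairs of
the first `input_len` growth stages (default 3) and predicts both
parameters at the next stage. Branch cells are the canonical LSTM and GRU
formulations (per-gate input weights, recurrent weights and biases; see
the README for the equations). Stacked layers each consume the full hidden
sequence of the layer below; zero initial states.

Choices left open by the architecture description, fixed here:

* stack depth 2 per branch (the minimum that is genuinely "stacked"),
  50 hidden units, both configurable;
* branch FCN activation ReLU, final layer linear (regression output);
* loss MSE on scaled targets, Adam (lr 1e-3, β = 0.9/0.999), batch 50,
  400 epochs;
* per-feature min–max scaling fitted on the training split only, shared by
  inputs and targets (they live in the same feature space), inverse-applied
  to predictions;
* when a validation set is given, the parameters with the best validation
  loss are returned (the history keeps every epoch).

All array math is float64 numpy; gradients are hand-written reverse-mode
and checked against central finite differences to ~1e-10 relative (with a
smooth activation) in the test suite. Training is bit-reproducible under a
seed: weight initialization is scaled-uniform `±1/sqrt(fan_in)` from a
seeded PCG64 generator, and batch shuffling uses the same stream.
Single-branch ablations (`branches="lstm"`/`"gru"`) keep the branch FCN
and final layer so the comparison isolates the branch architecture.

Dataset utilities split by plant (a series never straddles splits) with
largest-remainder rounding, and `cross_validate` runs a plant-level k-fold
(default 5) reporting SMAPE and log deviation per fold with mean ± sd.

## 3. Evaluation metrics

SMAPE is implemented with the plain-magnitude denominator,
`(100/n) Σ |y−x| / (|y|+|x|)`, bounded by 100%; the halved-denominator
variant common elsewhere is deliberately not used. Pairs with both values
zero contribute 0. The logarithmic deviation is `ln(y/x)` per pair
(base-10 optional), positive for overestimation; reports carry the per-pair
values, their sum, and over/under counts.

## 4. Synthetic data: what it emulates, what it does not

`generate_field_series` builds, per acquisition date: ground points on a
gently sloping plane (default slopes 2%/1%) with Gaussian micro-roughness
(σ = 0.01 m); plants on a regular grid whose heights follow per-plant
logistic growth `H∞ / (1 + e^{−r(t−t0)})` (asymptote uniform in a
configured range, r = 1.2 per stage, midpoint at stage 2 of 4); crowns as
upper half-ellipsoids (footprint radius 0.3 × height) sampled on the
surface — a scanner sees surfaces, not volumes — with a one-sided radial
"shell depth" (`1 − |N(0, 0.05)|`, floored at 0.3) because foliage returns
scatter inward from the crown hull, and an infinitely thin smooth shell is
both unphysical and degenerate for any ground filter; and sparse outliers
in a band 1.5–3 m above the local ground (support infrastructure and
boundary-tree multipath produce high returns; near-ground noise is already
the roughness term). Truth tables carry the hull height, hull footprint
area and plant position per date.

The `well_separated_preset` (100 plants, 1 m spacing, asymptotes
0.7–1.0 m, 2000 points/plant) guarantees crowns never touch and that even
first-date plants (~0.16–0.23 m) stand above the canopy-mask threshold. On
this preset the pipeline recovers the plant count exactly and, at the
mature stage, per-plant height within ±3.5% and crown area within ±4%
(three generator seeds checked). At the first date, heights are biased low
by up to ~50% and areas are strongly truncated: a 0.1 m mask threshold
plus a 0.05 m ground buffer genuinely consume a large fraction of a 0.18 m
plant. This is a physical limitation of CHM-based phenotyping at early
growth stages, not an implementation artifact; field campaigns typically
begin once crops are established.

`generate_growth_dataset` produces the tabular analog (logistic heights
with 5% multiplicative Gaussian noise, crown area `π(0.3h)²` with
independent noise) used for forecaster training experiments. It requires at
least 3 stages so the 3-date crop configuration (two stages in, third out)
remains expressible.

What passing tests on these data do **not** show: robustness to occlusion
(ground under crowns is fully sampled here; real TLS sees it only
obliquely), registration error between scans, wind-deformed crowns,
intensity effects, row-crop canopy closure (crowns here never touch), and
real growth curves deviating from a logistic. Forecast-quality numbers on
synthetic logistic growth are an upper bound on what heterogeneous field
data would give.

## 5. Known limitations

* Plants shorter than `min_height` + ground-buffer scale are undetectable;
  early-stage records are biased low (see above).
* The hybrid's advantage over well-trained single-branch baselines
  vanishes on clean synthetic growth: all three architectures reach the
  observation-noise floor, and their held-out SMAPEs differ by less than
  run-to-run jitter (~0.2 pp). Architectural differences only matter on
  harder, more heterogeneous data.
* The PTD boundary treatment assumes near-horizontal terrain outside the
  seed hull.
* LAZ (compressed LAS) is not read; decompress upstream. LAS I/O is
  limited to point formats 0–3, coordinates and classification.
* One model is trained per crop/run; no pooling across crops, no
  multi-step rollout, no uncertainty quantification.
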
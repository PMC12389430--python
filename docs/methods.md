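# Methods

## Scope and data model

The package analyses square forest plots (default 25 m side) at two levels:
a point cloud of the whole plot (metres, arbitrary vertical datum) and a
tree table (`tree_id, species, x_m, y_m, dbh_cm, height_m`). Everything
downstream of the tree table — spatial indices, diversity, importance
values, evaluation — is exact arithmetic on that table; everything upstream
is geometry on the cloud. The census rule is that trees enter analyses only
with DBH ≥ 5 cm; the extractor drops fitted stems below that diameter.

## Synthetic stands

The generator exists because plot censuses of protected communities are
generally not distributable; it reproduces the statistical features the
analyses are sensitive to, with exact ground truth.

* **Pattern.** `poisson` is complete spatial randomness; `grid` a centred
  square lattice; `cluster` a Thomas-style parent–offspring process
  (parents uniform, offspring isotropic Gaussian with sd `cluster_sd`,
  default 2 m, reflected at the plot edges so the stem count and density
  are conserved). Any clustered process would do for an "aggregated"
  community; Thomas was chosen for its two interpretable parameters.
* **DBH.** `5 + Exponential(rate)` cm, rate 0.08 cm⁻¹ by default — the
  negative-exponential ("inverse-J") diameter distribution of actively
  regenerating uneven-aged stands. The truncation at 5 cm is the census
  minimum, not a model choice.
* **Species.** A geometric abundance series (ratio 0.65) over the species
  pool, so one species dominates the way the tea tree dominates its
  community; `uniform` is available for calibration tests. Note the
  realized richness of a draw can be below the pool size.
* **Heights.** `H = 1.3 · DBH^0.6 + N(0, 0.5 m)`, floored at 1.5 m. This
  allometry only needs to give plausible heights above the breast-height
  slice; it is not fitted to any real stand.
* **Reference plots.** `reference_plot_specs()` bundles seven clustered
  stands with the published per-plot stem counts (23–166) and species
  pools spanning the reported 10–28 range, used by the `analysis/` drivers.
* **Stem clouds.** Cylinder-surface points (radius `dbh/200` m, optional
  linear taper and lean) with Gaussian radial noise; the true top and base
  points are pinned when no truncation is requested, so height extraction
  is exact on clean stems. `top_truncation` emulates the occlusion that
  makes real scanner heights underestimates. Crowns are optional ellipsoid
  blobs — enough to distract a position extractor, not a radiative model.
* **Paired measurements.** `estimate = field − bias + noise`, so the
  evaluation bias statistic (field minus estimate) recovers `+bias` in
  expectation; this fixes the sign convention once for all tests.

All generators are deterministic functions of `(spec, seed)`.

## Pre-processing

Cropping keeps points covered by the quadrilateral of the four surveyed
corner markers (boundary inclusive). Random thinning retains
`round(0.8·n)` points (banker's rounding), uniformly without replacement,
survivors in input order. SOR computes each point's mean distance to its
k = 10 nearest neighbours and removes points above the global
mean + 2·sd of that statistic; the threshold carries a 1e-9 relative slack
so a cloud whose statistics are all equal up to floating-point jitter loses
nothing. A second SOR pass on a finite grid can still trim corner points —
the global-threshold rule is not idempotent in general, which is a known
property of the conventional formulation, not a defect here.

Ground classification is a deliberately simple stand-in for
cloth-simulation filtering (which the original workflow ran in external
software with unstated parameters): the lowest point of each 0.5 m grid
cell seeds a lower-envelope surface (linear TIN over seeds, nearest
neighbour outside the hull), and points within 0.2 m of the envelope are
ground. It recovers planar and gently tilted terrain essentially exactly,
which is all the synthetic scenes exercise; on broken real terrain a real
CSF should be substituted upstream and its labels passed in.

The DEM is a Delaunay TIN over ground points, linear inside the hull,
nearest-point outside (documented extrapolation, exact for planes).
Normalization sets `z' = z − DEM(x, y)` and never touches x, y.

## Tree segmentation and parameters

Trunk detection is DBSCAN (eps 0.3 m, min 15 points) on the horizontal
coordinates of points with normalized height 1–2 m; every cloud point then
joins the trunk with the nearest horizontal axis. This replaces the
comparative-shortest-path crown assignment of the original workflow, which
relied on third-party software plus manual correction; nearest-axis
assignment is exact for separated stems and degrades gracefully for
touching crowns (the tests require ≥ 95 % correct assignment at ≥ 1 m
spacing).

DBH comes from the 1.25–1.35 m slice (≥ 10 points required) projected to
the horizontal plane and fitted with the algebraic Kåsa circle fit —
closed-form, exact on noiseless arcs; an optional geometric refinement
(`refine=True`, Levenberg–Marquardt on radial residuals) is available but
unnecessary for dense, mildly noisy slices. Height is `max z − min z`.
Position is the centroid of the lowest 0.3 m of points, falling back to
the slice-circle centre when fewer than 3 base points exist (crown-only
clouds). Collinear slices and sub-minimum slices raise; fitted DBH < 5 cm
drops the tree.

## Spatial structure

A structure unit is a core central tree plus its four nearest neighbours
by horizontal distance (ties broken by tree id, coincident stems are an
error). Core means at least 2.5 m from every plot edge; buffer trees act
only as neighbours, eliminating edge bias. Voronoi/Delaunay adjacency is
provided (`voronoi_units`) as the alternative neighbour definition but the
indices default to 4-NN, which is what the index definitions assume.

For the uniform angle index the four circular gaps between azimuth-sorted
neighbours are folded to ≤ 180° (`fold_reflex=True`; at most one gap can
exceed 180°, and folding matches the convention that the angle between two
neighbour rays is the smaller one) and compared strictly with α₀ = 72°.
Dominance uses a strict "larger than" comparison, so DBH ties count as
not-larger. Azimuths are 0° = north, clockwise — the convention is
irrelevant to W (only gaps matter) but fixed for reproducibility.

With four neighbours all of W, M, U lie on {0, 0.25, 0.5, 0.75, 1}; the
five-grade summary is exact counting, and off-grid values are an error
rather than silently binned. Expected values used as calibration checks:
mean U = 0.5 for i.i.d. continuous DBH; mean W ≈ 0.5 on Poisson stands
(the 72° standard angle is chosen to make that so); mean W ordered
grid < Poisson < cluster. Hegyi CI is invariant to rescaling all DBH and
inversely proportional to rescaling all distances.

## Non-spatial structure

Richness, diversity and evenness are the standard forms (natural logs
throughout). Relative frequency needs within-plot sampling units that the
field protocol never defines; a 5 m × 5 m quadrat grid (25 quadrats per
plot) is used, with the denominator the total number of species–quadrat
occupancies so RF sums to 100 % — plot-level presence/absence would make
RF degenerate in a single plot. This choice means published importance
values cannot be reproduced beyond their printed-component arithmetic.
Basal area is `π(DBH/2)²` in cm²; units cancel in RD. Diameter classes are
half-open `[5+10k, 15+10k)` cm bins labelled with Roman numerals; the
inverse-J diagnosis is "counts non-increasing", which on finite samples
can legitimately fail in near-empty tail classes.

## Evaluation

R² is computed about the 1:1 line (`1 − SSE/SST` with SSE of the estimates
about the field values), not from a refitted regression; RMSE divides by
n, not n − 1; bias is mean(field − estimate), so underestimation is
positive. Tables join on `tree_id`; when tags are absent,
`match_by_position` pairs each field tree with the nearest scanner stem
under a distance cap (default 1 m) and drops the rest — ambiguous at stem
spacings comparable to the cap, which is inherent to position matching.

## Problem sizes and determinism

The test suite and analysis drivers use plots of 16–700 stems, stem clouds
of ~10³–10⁵ points, 5–20 Monte-Carlo replicates for distributional checks
and 100 seeds for noisy-DBH recovery; these sizes put Monte-Carlo standard
errors comfortably inside the asserted bands while keeping a full run in
seconds. Every stochastic step takes an explicit seed and the pipeline
writes byte-identical reports on rerun.

## Known limitations

The ground classifier assumes smooth terrain; segmentation assumes
separable trunks and will merge coppiced or heavily leaning stems; species
labels must come from the field census (scanner clouds carry none); the
quadrat scheme behind relative frequency is a documented convention, not
the field protocol's; and synthetic stems lack occlusion, understory and
beam-divergence artefacts, so parameter-recovery results bound the
method's best case, not its field accuracy.
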
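# Methods

This note documents the models, the synthetic study system, the numerical
choices, and the limitations of `corridorscape`.  Nothing here asserts an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The estimation chain

### Single-season occupancy model

The data are a site × occasion binary detection matrix built by cutting
each camera deployment into consecutive 5-day segments (trailing partial
segments are dropped so occasions have equal effort; deployments shorter
than one segment are excluded with a warning).  The likelihood is the
zero-inflated binomial

L_i = ψ_i ∏_t p_it^y_it (1−p_it)^(1−y_it) + (1−ψ_i)·1[all y_it = 0],

with ψ logit-linear in site covariates and p logit-linear in occasion
covariates (lure applied, temperature class with low as reference, camera
view).  Missing occasions (NaN) drop out of the product, so ragged
deployments are handled without imputation.  The negative log-likelihood
and its analytic gradient are minimised by L-BFGS-B from multiple jittered
starts (default 5); coefficients are box-bounded at |logit| = 15 and fits
that end on that bound are flagged `boundary`, so saturated data (all
detections, no detections) terminate cleanly.

Continuous covariates are z-scored before fitting (the covariate set
spans meters to category codes; standardization stabilises the
optimisation), and the standardization constants travel with each fit
so predictions are on the right scale.  Predictions additionally clamp
each covariate to the range observed at fit time: a logit-linear form is
only trusted inside its data, which matters when scenario edits push a
distance covariate (e.g. distance to the nearest large residence after all
have been removed) far beyond anything surveyed.

### Covariate preparation

* Distance layers: Euclidean distance from cell centers to the nearest
  feature of a class (shapely); when a class has no features the layer is
  capped at the grid diagonal so covariates stay finite.
* Slope: Horn's 8-neighbour kernel, edge cells by replicated-edge
  (one-sided) differences; classes cut left-closed at 5° and 20°.
* Collinearity screen: zero-variance covariates are dropped first, then
  greedy elimination — while any pair has |r| ≥ 0.7, the member of the
  worst pair with the larger mean |r| to the others is removed, ties broken
  by a configurable keep-priority then alphabetically.  The algorithm is
  deterministic, idempotent, and insensitive to column order.
* Functional form: each continuous covariate is offered raw, log(x+1)
  (tolerant of zero distances) and quadratic single-covariate occupancy
  models; the minimal-AIC form wins, exact ties going to the simpler form.

### Selection and averaging

Detection covariates are chosen first by fitting the full occupancy model
once per subset of the detection pool (ties → fewer terms, then
lexicographic).  With the detection set fixed, all subsets of the occupancy
pool are fitted and ranked by AIC.  Models with ΔAIC ≤ 2 form the top set;
their weights are renormalized, and coefficients are averaged with zero
substitution — a model lacking a term contributes zero at its weight — so
averaged coefficients and per-covariate importance weights (the summed
weight of models containing the covariate) are mutually consistent.
Non-convergent subsets are logged and excluded.

### Validation

Sign-transect segments are labelled presence (any sign) or confirmed
absence (no sign at the segment and no sign-bearing segment within 1 km);
no-sign segments near sign are ambiguous and dropped rather than treated
as absences.  AUC uses the rank (Mann–Whitney) formulation with the ½ tie
convention — exact, and invariant to monotone transforms of the scores.

## Connectivity

Suitability inverts to cost by the affine map cost = cost_min + S·(1−ψ)
(defaults 1 + 99·(1−ψ), range 1–100): strictly positive and bounded, the
dominant convention for resistance surfaces.  A reciprocal option (1/ψ) is
available for sensitivity analysis.  Cells are nodes of the 8-neighbour
graph; an edge costs the mean of its two cell costs times the step length
(√2·cell size on diagonals); nodata cells are impassable.  Accumulated
cost and backlinks come from Dijkstra (scipy.sparse.csgraph); backlinks
are compass-coded (0 = source, 1–8 = N…NW) so paths can be traced without
re-solving.  The 5×5 pathway design solves one source at a time and traces
to each sink; the globally cheapest of the 25 paths is flagged optimal.
Pathway quality is cost per 100 m of geometric length, which is the
length-weighted mean of per-edge cost density ×100 and therefore comparable
across paths of different lengths.

The circuit model reuses the identical surface as resistance, so the two
connectivity analyses are directly comparable.  Conductance is the
reciprocal of the edge weight; the sparse graph Laplacian is solved with
the ground set eliminated (fixed at 0 V) rather than via a pseudo-inverse.
Per-cell current density is half the summed absolute branch currents plus
half the injected current at terminals.  Omnidirectional maps pad the
surface with a uniform-cost buffer (default: the mean passable cost),
spread focal nodes evenly along the outer ring, solve unit-current node
pairs (all pairs or a seeded subsample) with a single matrix
factorisation, sum the current maps, and crop the buffer.  Corridor width
is summarised as the longest contiguous run of transect cells whose
current exceeds the transect's 0.75 quantile, times the cell size — an
explicit artifact convention, since published corridor widths are map
readings with no stated method.

## Scenario analysis

Three edits are supported: restore_forest (a polygon becomes primary
forest with bamboo present), remove_residences (by size class, optionally
within a region), and tunnel (a chainage interval of a road is carried
underground; only the surface segment is removed — no tunnel-mouth
disturbance is modelled, as no parameters exist for one).  After edits,
every derived layer whose inputs changed (the distance rasters) is
recomputed; untouched layers are bit-identical, which the tests assert.

The 25 pathway geometries found under the baseline are held fixed and
re-costed under each scenario's re-predicted suitability — the comparison
is "what would these same routes cost", not "where would new routes go".
Cost matrices are compared by two-way ANOVA without interaction (one
observation per path × scenario cell leaves no residual df for an
interaction) and by paired t-tests with Holm's step-down adjustment
(sorted raw p multiplied by m−i, cumulative-maximum enforced, capped at
1).  Identical columns make the paired t undefined; such comparisons are
reported with t = NaN and adjusted p = 1.

## The synthetic study system

The generator emulates a valley-corridor landscape: a smooth ridge–valley
elevation field with correlated noise, a winding two-lane highway along
the valley axis, residences clustered beside the road (size classes from a
3-household threshold), cropland rectangles near the road, national
reserves on both flanks, patchy forest age/composition fields, bamboo with
an elevation-band preference, and a continuous human-dominated strip along
the road (default 1.2 km) where mature forest and bamboo understory are
absent — the farmland belt that makes the valley floor a coherent barrier
rather than a mosaic of small unsuitable patches.  All layers and features
are deterministic given the seed.

The default generating parameters produce a strongly bimodal suitability
surface (most cells clearly suitable or clearly unsuitable), with
occupancy favouring low elevation, gentle slope, bamboo and mature forest
and suppressed near roads and large residences, and detection helped by
lure and cold weather and unaffected by camera view.  Surveys follow a
rotating-panel design: 8 east–west arrays, 3 concurrent cameras per array
per period with ≥500 m spacing, deployments of 30–50 days cut into 5-day
occasions.  Latent occupancy z is drawn once per site (closed population).

Validation transects mimic a walked sign survey: straight lines of 250-m
segments at random positions and bearings, optionally stratified so a
fraction starts in low-suitability habitat (a survey designed to cover
unused areas).  Latent use is drawn once per cell from a landscape-level
seed and shared by every segment and survey round crossing that cell, so
sign records cluster at the occupancy scale while each segment keeps its
Bernoulli(ψ) marginal.  The pipeline adds adaptive survey effort: if the
1-km rule leaves fewer than 5 confirmed absences, follow-up rounds walk
short transects inside the bottom-15% suitability stratum, and the
best-balanced cumulative set is kept.  Without the clustering, the strip,
and the adaptive rounds, the 1-km rule yields essentially no confirmed
absences at desk-scale landscapes — a structural property of the rule, not
a software choice.

What the generator does not emulate: terrain hydrology, animal movement
paths (no telemetry process), observation error in the covariate layers,
and spatial autocorrelation in occupancy beyond what the smooth covariate
fields induce.  Passing tests therefore demonstrate correctness of the
estimation and connectivity machinery under the stated model, not
robustness to real-data pathologies such as mis-registered rasters or
non-stationary detection.

## The scenario fixture

The qualitative scenario benchmark uses a constructed averaged model on a
generated valley: road proximity dominates suitability (coefficient 1.6 on
the standardized distance), forest age and bamboo carry moderate effects
(0.25 each, so restoring the valley belt helps every pathway), and the
large-residence coefficient is averaged to exactly zero, so relocating
residences cannot change predicted cost — the zero-effect case the
comparison must classify as "not significant".  The tunnel replaces the
road section spanned by the baseline corridor crossings (±500 m), i.e. it
is sited under the primary movement pathway, which is the management logic
of a wildlife tunnel.  The fixture pins a gently winding road: with strong
meanders, neighbouring road loops remain close to any removed section and
dilute the tunnel's effect.  Under this construction the expected ordering
is tunnel < restoration < baseline = relocation, and the Holm-corrected
paired tests reproduce it; the ordering is computed, never asserted.

## Numerical and statistical notes

* Likelihood clipping at 1e-12 keeps logs finite; the NLL agrees with an
  independent scalar per-site implementation to 1e-10 on random instances.
* Dijkstra, the circuit solver, ANOVA, paired t and Holm adjustment are
  each checked against independent oracles (exact label-correcting
  relaxation and networkx; dense numpy solves and series/parallel closed
  forms; statsmodels; scipy; a hand-computed step-down case).
* The parameter-recovery study (100 replicates of 250 sites × 8 occasions)
  compares the Monte-Carlo mean of model-averaged estimates with the
  generating values via z = (mean − truth)/SE.  The occupancy MLE carries
  the classic O(k/n) logistic bias (measured at ≈2.7% coefficient
  inflation at n = 250 over 600 replicates), so per-coefficient expected
  |z| is roughly 0.2–1.5 and the |z| ≤ 2 check is near its operating
  boundary: it can exceed 2 on unlucky seeds without indicating a defect.
  Larger site counts shrink the bias as 1/n.
* AIC subset selection retains truly null detection terms at the
  well-known AIC background rate (~15–25%); the tests assert the true
  effect is always kept and bound the spurious inclusions rather than
  demand an exact set.
* Problem sizes: the library tests use 30×50 to 70×90-cell landscapes and
  the pipeline demo 80×100 at 100-m resolution; these are the package's
  default study dimensions and all statistical checks are calibrated to
  them.

## Known limitations

* One road per landscape template; multi-road networks are representable
  in `FeatureSet` but the generator does not create them.
* No standard errors for model-averaged coefficients (no unconditional
  variance estimator); importance weights and the recovery study are the
  uncertainty summaries provided.
* The two-way ANOVA is the standard additive decomposition; published
  analyses of this design occasionally print degrees of freedom that do
  not match any additive layout, and no attempt is made to reproduce
  nonstandard bookkeeping.
* Planar coordinates only (no geodesy, no reprojection): appropriate for
  study areas of tens of kilometres.
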
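# Methods

## Model

`catchprop` treats catchment estimation as a competitive growth process
on the region adjacency graph. The study area is a tessellation of *N*
small regions with demand *D(Vₙ) ≥ 0*; *M ≪ N* facilities with capacity
*S(P_m) > 0* each occupy one host region (co-located facilities are
merged first, so "one facility per region" holds by construction). Each
facility's label grows outward one graph neighbourhood at a time, gated
by an accumulating score: at iteration *k* every unlabelled region
adjacent to catchment *m* gains

    score(V, m) += S_m / max(D_m(k), d0)

where *D_m(k)* is the demand already absorbed by catchment *m* and *d0*
is the demand floor. A region is claimed by the first label whose score
reaches the threshold *τ*; claimed regions are final. Growth therefore
decelerates as a catchment fills with demand, and two adjacent
catchments stop expanding into each other roughly where their
supply-per-demand ratios meet — the model's equilibrium notion of a
fair boundary. Propagation ends when no unlabelled region has a
labelled neighbour. Note that an iteration may label nothing while
scores are still climbing toward *τ*; this is normal mid-run behaviour,
not termination, which is why the stop condition is an empty frontier
rather than an idle iteration.

Assumptions worth stating plainly: demand is taken as uniformly spread
within each small region; travel is possible exactly between contiguous
regions (no road network, no travel-time weighting); supply and demand
are static during a run; and catchments are non-overlapping — one label
per region. Tertiary referral flows, patient choice, and overflow
between hospitals violate that last assumption in real activity data,
which is precisely what the validation metrics are for.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `score_threshold` (τ) | 1.0 | dimensionless | the natural scale at which accumulated supply-per-demand "covers" a region; since every score increment is divided by the same τ-relative scale, changing τ changes granularity of the advance, not the equilibrium boundary |
| `demand_floor` (d0) | 1.0 | demand units | keeps zero-population regions (parks, industrial estates) traversable instead of division-by-zero sinks |
| `tie_break` | highest-score | — | when several labels cross τ for one region in one iteration: highest score wins, residual ties by facility-id sort order; `supply-id-order` skips the score comparison |
| `max_iterations` | 1,000,000 | iterations | a non-termination guard only. With positive capacities every frontier region is eventually claimed; the literal ratio increment needs on the order of Σ D/S iterations, ~10⁵ for a 2,500-region geography at realistic beds-per-head ratios, so the cap is set well above that |
| `bridge_islands` | off | — | graph components without a facility are reported as `unreached` by default; opt-in bridging attaches each such component wholesale to the facility nearest its demand-weighted centroid (keeping the component under a single label), with `labelled_at = -1` marking regions that were never propagated to |
| `normalize_rates` | off | — | optionally rescales all rates each iteration so the fastest label advances one ring per iteration; it compresses the iteration count but can reorder claims when relative rates shift between iterations, so the literal ratio is the default and the option is documented as an uncertainty, not an equivalence |
| contiguity | shared-edge | — | rook-style contiguity is the default because corner-touching regions are not traversable on the ground; queen-style (`shared-point`) is available |

Boundary-sitting supply points are assigned to the candidate region with
the lexicographically smallest id — an arbitrary but documented and
deterministic rule. Invalid polygons are repaired (`make_valid`) with a
warning before any containment or intersection test. No CRS
reprojection is performed: all layers must arrive in one planar CRS,
which is recorded and checked for equality where layers meet.

## Validation machinery

* **Coarse aggregation.** A fine-region catchment map is converted into
  a probabilistic coarse-unit → facility mapping: weight(c, m) is the
  demand share of coarse unit c assigned to m, and expected cases are
  weight × coarse demand. Zero-demand coarse units get uniform weights
  and a flag.
* **Areal interpolation.** Demand is transferred between incompatible
  polygon layers proportionally to overlap area (uniform-density
  assumption). Mass is conserved exactly when the target layer re-tiles
  the source; coverage gaps are reported.
* **Prediction.** Catchment mode assigns each case the label of its
  containing region; cross-mapping mode assigns the argmax-weight
  facility of the case's coarse unit (ties by facility id).
  Unresolvable cases are dropped from denominators and reported.
* **Metrics.** Multinomial accuracy; one-vs-all balanced accuracy
  (sensitivity undefined when a class is never observed — the
  specificity is returned with a flag rather than a silent NaN);
  multiclass Matthews correlation (Gorodkin's confusion-matrix
  generalisation, via scikit-learn); and ICC(2,k) — two-way random
  effects, absolute agreement, average measures — computed from the
  two-way ANOVA mean squares with the 95% CI built from the
  single-measures F-bounds stepped up by Spearman–Brown. Absolute
  agreement is deliberate: a constant offset between two mappings *is* a
  disagreement about expected cases. When two mappings are compared,
  every (coarse unit, facility) pair with nonzero weight under either
  mapping is a subject and the two mappings are the raters; pairs absent
  from one mapping contribute zero expected cases. Zero between-subject
  variance makes the ICC unidentifiable; it is reported as 0 with a
  `degenerate` flag.

## Synthetic geographies

The generator emulates the structure of census-unit data: contiguous
tessellations (square grid, 1×n path, or clipped Voronoi), demand drawn
as uniform, lognormal (default mean 1,500 per region, the order of an
LSOA population, σ = 0.5), or a Gaussian hotspot on a background; and
facilities placed in distinct regions with equal or lognormal
capacities (default mean 300, σ = 0.7 — bed counts spanning roughly an
order of magnitude). Activity records place cases in regions with
probability proportional to demand; each case reports its true
catchment's facility with probability 1 − `activity_noise`, otherwise a
uniformly random facility (or always the largest facility under the
`largest` noise model, mimicking the pull of tertiary referral
centres). All draws flow through `numpy.random.Generator(PCG64)` from a
single integer seed, so outputs are bit-reproducible across platforms.

What passing tests on these fixtures does **not** show: real geographies
have coastline, holes and multi-part polygons beyond what the clipped
Voronoi produces; real demand surfaces are spatially autocorrelated
rather than i.i.d.; real misclassification is structured (referral
networks, overflow) rather than uniform relabelling; and real capacity
data carry measurement error. The closed-loop results (perfect recovery
at zero noise) validate the pipeline's internal consistency, not the
model's fidelity to any particular health system.

## Numerical and design choices

* Scores accumulate monotonically; claims are evaluated after all
  increments of an iteration, with rates frozen at the iteration start,
  so the result is independent of region iteration order.
* A catchment's demand is updated when regions are *claimed*, not when
  scoring starts — demand counts the population assigned, not the
  frontier.
* The host region's own demand seeds *D_m* at iteration 0.
* Zero-capacity facilities are rejected outright (their label could
  never cross the threshold, silently producing an empty catchment).
* Score comparisons use `>=` against the threshold, so a unit rate
  advances one ring per iteration exactly.
* Problem sizes in the test suite and acceptance script (grids up to
  50×50, Voronoi up to 2,000 cells, 10⁴ simulated cases) were chosen as
  the smallest scales at which the partition, balance and agreement
  properties are meaningfully exercised; the engine itself is O(frontier
  × labels) per iteration and handles these in seconds.

## Known limitations

* Dense facility clusters produce small central catchments with high
  supply per head — a direct consequence of the non-overlap constraint,
  visible in any big-city geography. Layered (overlapping) catchments
  are out of scope.
* No travel-time or road-network penalty; contiguity is the only notion
  of reachability.
* The ICC subject construction for comparing two mappings (nonzero-
  weight pairs under either method) is one reasonable interpretation of
  a many-to-many agreement problem; alternatives (all pairs, observed
  pairs only) would change the estimate.
* Shapefile/GeoPackage input is not supported; convert to GeoJSON
  first.
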
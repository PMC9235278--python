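# catchprop

Facility catchment area estimation by label propagation on spatial
adjacency graphs.

## The problem

A hospital's *catchment area* is the geographic region whose resident
population it primarily serves. Catchments underpin capacity planning —
how many beds per head a population can reach — and they are needed most
urgently exactly when no patient-flow data exist yet, e.g. in the early
weeks of an infectious-disease outbreak, after a service reconfiguration,
or when modelling a hypothetical new hospital. `catchprop` estimates
non-overlapping, contiguous catchments from only two ingredients:

* a tessellation of small regions *V₁ … V_N* (census units such as
  LSOAs), each with a known demand *D(Vₙ)* (resident population, or any
  demand surrogate such as predicted infections), and
* *M ≪ N* supply points *P₁ … P_M* with capacities *S(P_m)* (staffed
  beds, or any supply surrogate).

No admission or referral records are required.

## The algorithm

The tessellation is turned into an adjacency graph *G* (regions are
nodes; polygon contiguity defines edges, so estuaries and other physical
barriers are respected automatically — regions separated by water share
no boundary and hence no edge). Each facility is resolved to its host
region; co-located facilities are merged into one entity with summed
capacity.

Every facility seeds a label in its host region, and a score
*c(V, m)* — initially zero — is kept for every (region, label)
combination. At iteration *k*, every unlabelled region adjacent to a
region labelled *m* gains

&nbsp;&nbsp;&nbsp;&nbsp;*c(V, m) ← c(V, m) + S_m / max(D_m, d₀)*

where *S_m* is the catchment's capacity, *D_m* the total demand of the
regions labelled *m* so far, and *d₀* a small demand floor that keeps
zero-population regions traversable. The first label whose score reaches
a threshold (default 1.0) claims the region; claimed regions never
change hands, so each catchment stays a connected sub-graph and the
final labelling is a partition. Labels therefore spread fast from
high-capacity facilities through sparsely populated country and slow
down as their catchment's demand accrues — the emergent equilibrium is
that neighbouring catchments have similar supply per head,
*S_m / D_m ≈ S_m′ / D_m′*, at their shared boundary. Every tie-break is
deterministic (score first, then facility id), so identical inputs give
byte-identical output.

The validation toolkit scores a catchment map against observed facility
usage: multinomial accuracy, one-vs-all balanced accuracy per facility,
the multiclass Matthews correlation coefficient, and the intraclass
correlation ICC(2,k) (two-way random effects, absolute agreement,
average measures, with 95% CI) between expected-case totals of two
competing mappings. A synthetic-geography generator (grid / path /
Voronoi layouts, configurable demand and capacity distributions, and a
simulator of activity records with controllable noise) makes the whole
pipeline testable end-to-end with known ground truth.

## Worked example

```python
import catchprop as cp

spec = cp.SyntheticSpec(layout="grid", n_regions=100, n_supply=3, seed=7,
                        demand_model="lognormal",
                        capacity_model="lognormal")
regions = cp.make_regions(spec)          # 10x10 tessellation, ~1,500 people/cell
supply = cp.place_supply(regions, spec)  # 3 hospitals, lognormal bed counts

graph = cp.build_adjacency(regions, "shared-edge")
resolved = cp.locate_and_merge_supply(regions, supply)
cmap = cp.propagate_labels(graph, regions, resolved)

table, dist = cp.catchment_summary(cmap, scale=100_000)
print(table.round(1))
```

```
           total_supply  total_demand  supply_per_scale  zero_demand
supply_id
H00               183.6       65113.7             281.9        False
H01                46.5        5928.0             784.8        False
H02               205.7       62269.8             330.4        False
```

Each row is one catchment: H00's 184 beds serve a population of 65,114,
i.e. 282 beds per 100,000 residents, and the three catchments partition
all 100 regions into connected blocks. Closing the loop — simulating
1,000 admissions from the true catchments with zero noise and
re-predicting the facility from each case's location — recovers the
assignment exactly:

```python
cases = cp.simulate_activity(cmap, regions, 1000, spec)
preds = cp.predict_facility(cmap, cases, regions=regions)
stats = cp.agreement_stats(preds)
print(f"accuracy {stats.multinomial_accuracy:.3f} "
      f"({stats.n_correct}/{stats.n_total}), MCC {stats.mcc:.3f}")
# accuracy 1.000 (1000/1000), MCC 1.000
```

## Command line

```sh
catchprop simulate  --spec spec.json --out data/        # synthetic inputs
catchprop catchment --regions data/regions.geojson --id region_id \
                    --demand demand --supply data/supply.csv --out run/
catchprop validate  --catchment run/assignment.csv --cases data/cases.csv \
                    --regions data/regions.geojson --out val/
catchprop compare   --mapping-a a.csv --mapping-b b.csv --out icc.json
```

`catchment` writes the per-region assignment with iteration indices, a
per-catchment summary, dissolved catchment polygons (GeoJSON), and a run
manifest (config snapshot, input digests, per-iteration labelling
counts). Exit codes: 0 success, 2 configuration error, 3 data error,
4 non-termination.

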
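"""Label-propagation engine for supply/demand-balanced catchment areas.

Each supply point seeds a label in its host region. At every iteration,
each unlabelled region adjacent to a region carrying label ``m``
accumulates score for ``m`` at a rate equal to the catchment's running
supply-to-demand ratio::

    rate(m) = capacity(m) / max(catchment_demand(m), demand_floor)

so labels spread quickly from high-capacity facilities through sparsely
populated regions and slow down as the demand already absorbed by the
catchment grows. A region is claimed by the first label whose accumulated
score reaches the threshold; once claimed it never changes label, which
guarantees a non-overlapping partition whose catchments are connected
sub-graphs of the adjacency graph. Propagation ends when no unlabelled
region borders a labelled one. The emergent property is that neighbouring
catchments end up with similar supply per unit demand.

All arithmetic is deterministic: ties are broken first by score (or
directly by supply-id order, configurable) and then by supply-id sort
order, so identical inputs yield identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, NonTerminationError
from .geometry import RegionSet, SupplySet

logger = logging.getLogger(__name__)

TIE_BREAKS = ("highest-score", "supply-id-order")


@dataclass
class PropagationConfig:
    """Tunable parameters of the propagation engine.

    score_threshold : float
        Accumulated supply-per-demand score at which a label claims a
        region. 1.0 is the natural scale (the catchment's supply has
        "covered" one unit of its demand per unit region); the absolute
        value only sets the granularity of the advance, not the final
        balance.
    demand_floor : float
        Lower bound on the demand denominator so that zero-population
        regions (parks, industrial estates) are traversable rather than
        division-by-zero sinks. In demand units.
    tie_break : {"highest-score", "supply-id-order"}
        How to pick among several labels crossing the threshold for the
        same region in the same iteration.
    max_iterations : int
        Hard cap on iterations; exceeding it with reachable regions still
        unlabelled raises :class:`NonTerminationError`.
    bridge_islands : bool
        Attach graph components that contain no supply point to the
        facility nearest their demand-weighted centroid instead of
        reporting them as unreached.
    normalize_rates : bool
        Rescale all rates each iteration so the fastest label advances one
        region per iteration. Off by default: the literal supply/demand
        ratio is used. The partition is identical either way when the
        threshold is reached in a single step; normalization only
        compresses the iteration count.
    """

    score_threshold: float = 1.0
    demand_floor: float = 1.0
    tie_break: str = "highest-score"
    max_iterations: int = 1_000_000
    bridge_islands: bool = False
    normalize_rates: bool = False

    def validate(self) -> None:
        if self.score_threshold <= 0:
            raise ConfigurationError("score_threshold must be > 0")
        if self.demand_floor <= 0:
            raise ConfigurationError("demand_floor must be > 0")
        if self.tie_break not in TIE_BREAKS:
            raise ConfigurationError(
                f"tie_break must be one of {TIE_BREAKS}, got {self.tie_break!r}"
            )
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


@dataclass
class CatchmentMap:
    """Result of a propagation run.

    assignment : dict region_id -> supply_id
    labelled_at : dict region_id -> iteration index (0 for host regions,
        -1 for regions attached by island bridging)
    unreached : set of region_id in components with no supply point
    totals : DataFrame indexed by supply_id with total_supply,
        total_demand and supply_per_capita columns
    iterations : number of iterations run
    newly_labelled : per-iteration counts of regions labelled
    """

    assignment: dict[str, str]
    labelled_at: dict[str, int]
    unreached: set[str]
    totals: pd.DataFrame
    iterations: int
    newly_labelled: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        df = pd.DataFrame(rows, columns=["region_id", "supply_id"])
        df["labelled_at"] = [self.labelled_at[r] for r in df["region_id"]]
        return df


def propagate_labels(graph: nx.Graph, regions: RegionSet, supply: SupplySet,
                     config: PropagationConfig | None = None) -> CatchmentMap:
    """Partition the region graph into one catchment per supply point.

    ``supply`` must be resolved (each entry has a host region present in
    the graph). Raises :class:`DataError` for zero supply points or
    all-zero capacities (no label could ever cross the threshold) and
    :class:`NonTerminationError` if ``max_iterations`` is reached while
    reachable regions remain unlabelled.
    """
    config = config or PropagationConfig()
    config.validate()
    if len(supply) == 0:
        raise DataError("no supply points")
    if not supply.resolved:
        raise DataError("supply must be resolved to host regions first")
    if np.all(supply.capacity == 0):
        raise DataError("all supply capacities are zero; no label can propagate")
    zero_cap = [s for s, c in zip(supply.supply_id, supply.capacity) if c == 0]
    if zero_cap:
        raise DataError(f"zero-capacity supply points not allowed: {zero_cap}")
    missing = [h for h in supply.host_region if h not in graph]
    if missing:
        raise DataError(f"host regions absent from graph: {missing}")

    demand = {r: regions.demand_of(r) for r in graph.nodes}
    capacity = dict(zip(supply.supply_id, (float(c) for c in supply.capacity)))
    label_order = {s: i for i, s in enumerate(sorted(supply.supply_id))}

    assignment: dict[str, str] = {}
    labelled_at: dict[str, int] = {}
    catchment_demand: dict[str, float] = {}

    # iteration 0: each host region takes its own facility's label and
    # seeds the running demand total
    for sid, host in zip(supply.supply_id, supply.host_region):
        if host in assignment:  # cannot happen after merge, but guard anyway
            raise DataError(f"two supply points share host region {host!r}")
        assignment[host] = sid
        labelled_at[host] = 0
        catchment_demand[sid] = demand[host]

    # frontier bookkeeping: for each unlabelled region, which labels are
    # adjacent, and the accumulated score per label
    adjacent_labels: dict[str, set[str]] = {}
    scores: dict[str, dict[str, float]] = {}
    for host in list(assignment):
        for nb in graph.neighbors(host):
            if nb not in assignment:
                adjacent_labels.setdefault(nb, set()).add(assignment[host])

    iteration = 0
    newly_counts: list[int] = []
    while adjacent_labels:
        iteration += 1
        if iteration > config.max_iterations:
            raise NonTerminationError(
                f"max_iterations={config.max_iterations} reached with "
                f"{len(adjacent_labels)} regions still on the frontier",
                stuck_regions=sorted(adjacent_labels),
            )
        rate = {
            m: capacity[m] / max(catchment_demand[m], config.demand_floor)
            for m in catchment_demand
        }
        if config.normalize_rates:
            fastest = max(rate.values())
            if fastest > 0:
                scale = config.score_threshold / fastest
                rate = {m: v * scale for m, v in rate.items()}

        newly: list[tuple[str, str]] = []
        for region, labels in adjacent_labels.items():
            sc = scores.setdefault(region, {})
            crossed = []
            for m in labels:
                s = sc.get(m, 0.0) + rate[m]
                sc[m] = s
                if s >= config.score_threshold:
                    crossed.append(m)
            if crossed:
                if config.tie_break == "highest-score":
                    winner = min(crossed, key=lambda m: (-sc[m], label_order[m]))
                else:
                    winner = min(crossed, key=lambda m: label_order[m])
                newly.append((region, winner))

        newly_counts.append(len(newly))
        logger.info("iteration %d: %d newly labelled regions", iteration, len(newly))
        for region, winner in newly:
            assignment[region] = winner
            labelled_at[region] = iteration
            catchment_demand[winner] += demand[region]
            del adjacent_labels[region]
            scores.pop(region, None)
        for region, winner in newly:
            for nb in graph.neighbors(region):
                if nb not in assignment:
                    adjacent_labels.setdefault(nb, set()).add(winner)

    unreached = set(graph.nodes) - set(assignment)
    if unreached and config.bridge_islands:
        _bridge_islands(graph, regions, supply, unreached, assignment,
                        labelled_at, catchment_demand, demand)
        unreached = set()

    totals = _totals(capacity, catchment_demand)
    return CatchmentMap(assignment=assignment, labelled_at=labelled_at,
                        unreached=unreached, totals=totals,
                        iterations=iteration, newly_labelled=newly_counts)


def _bridge_islands(graph, regions, supply, unreached, assignment,
                    labelled_at, catchment_demand, demand) -> None:
    """Attach each supply-free component wholesale to the facility nearest
    its demand-weighted centroid (keeps the component single-labelled)."""
    sub = graph.subgraph(unreached)
    for comp in nx.connected_components(sub):
        comp = sorted(comp)
        pts = [regions.geometry[regions.index_of(r)].centroid for r in comp]
        w = np.array([max(demand[r], 1e-12) for r in comp])
        cx = float(np.average([p.x for p in pts], weights=w))
        cy = float(np.average([p.y for p in pts], weights=w))
        dists = [((loc.x - cx) ** 2 + (loc.y - cy) ** 2, sid)
                 for sid, loc in zip(supply.supply_id, supply.location)]
        _, winner = min(dists)
        for r in comp:
            assignment[r] = winner
            labelled_at[r] = -1
            catchment_demand[winner] += demand[r]


def _totals(capacity: dict[str, float], catchment_demand: dict[str, float]) -> pd.DataFrame:
    sids = sorted(capacity)
    supply_tot = np.array([capacity[s] for s in sids])
    demand_tot = np.array([catchment_demand.get(s, 0.0) for s in sids])
    with np.errstate(divide="ignore", invalid="ignore"):
        per_capita = np.where(demand_tot > 0, supply_tot / demand_tot, np.nan)
    return pd.DataFrame(
        {"total_supply": supply_tot, "total_demand": demand_tot,
         "supply_per_capita": per_capita},
        index=pd.Index(sids, name="supply_id"),
    )


def catchment_summary(cmap: CatchmentMap, scale: float = 100_000.0
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Supply per ``scale`` persons for each catchment, plus distribution
    summaries (min, quartiles, max) over catchments.

    A catchment with zero demand gets NaN per-capita supply (flagged via
    the ``zero_demand`` column) and is excluded from the distribution
    summary.
    """
    if scale <= 0:
        raise ConfigurationError("scale must be positive")
    df = cmap.totals.copy()
    df["supply_per_scale"] = df["supply_per_capita"] * scale
    df["zero_demand"] = df["total_demand"] == 0
    valid = df.loc[~df["zero_demand"], "supply_per_scale"]
    summary = valid.describe()[["min", "25%", "50%", "75%", "max"]]
    summary.index = ["min", "q1", "median", "q3", "max"]
    return df[["total_supply", "total_demand", "supply_per_scale", "zero_demand"]], summary


def trace_iterations(cmap: CatchmentMap) -> pd.DataFrame:
    """Per-region propagation trace: (region_id, supply_id, labelled_at).

    Within each catchment, labelled_at is non-decreasing along any shortest
    path from the host region outward, so the trace visualises the
    wavefront of the algorithm.
    """
    return cmap.to_frame()
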
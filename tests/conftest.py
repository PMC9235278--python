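import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point, box

from catchprop import PropagationConfig, RegionSet, SupplySet

sys.path.insert(0, str(Path(__file__).parent))  # makes `reference` importable


def grid_regions(rows: int, cols: int, demand=100.0) -> RegionSet:
    """Rectangular tessellation of unit squares, row-major ids."""
    ids, geoms = [], []
    for r in range(rows):
        for c in range(cols):
            ids.append(f"R{r * cols + c:04d}")
            geoms.append(box(c, r, c + 1, r + 1))
    dem = np.full(len(ids), demand) if np.isscalar(demand) else np.asarray(demand)
    return RegionSet(region_id=ids, geometry=geoms, demand=dem, crs="planar")


def path_graph_setup(n: int, demand=1.0):
    """A 1 x n strip as (regions, graph). Region i is 'R{i:04d}'."""
    regions = grid_regions(1, n, demand)
    graph = nx.Graph()
    graph.add_nodes_from(regions.region_id)
    for i in range(n - 1):
        graph.add_edge(regions.region_id[i], regions.region_id[i + 1])
    return regions, graph


def supply_at(regions: RegionSet, placements: dict[str, tuple[str, float]]) -> SupplySet:
    """Resolved SupplySet from {supply_id: (host_region, capacity)}."""
    items = sorted(placements.items())
    return SupplySet(
        supply_id=[sid for sid, _ in items],
        location=[regions.geometry[regions.index_of(host)].representative_point()
                  for _, (host, _) in items],
        capacity=np.array([cap for _, (_, cap) in items]),
        host_region=[host for _, (host, _) in items],
        crs=regions.crs,
    )


def random_graph_fixture(rng: np.random.Generator, max_regions: int = 12):
    """Random connected graph + demands + seeded supply, for oracle checks."""
    n = int(rng.integers(3, max_regions + 1))
    while True:
        g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    mapping = {i: f"R{i:04d}" for i in range(n)}
    g = nx.relabel_nodes(g, mapping)
    demand = {mapping[i]: float(rng.integers(1, 11)) for i in range(n)}
    n_supply = int(rng.integers(1, min(4, n) + 1))
    hosts = rng.choice(n, size=n_supply, replace=False)
    seeds = {f"H{j:02d}": mapping[int(h)] for j, h in enumerate(hosts)}
    capacity = {sid: float(rng.integers(1, 21)) for sid in seeds}
    return g, demand, seeds, capacity


def as_package_inputs(g, demand, seeds, capacity):
    """Convert a random_graph_fixture into RegionSet/SupplySet (geometry is
    immaterial for the engine, so regions get dummy unit squares)."""
    ids = sorted(g.nodes)
    geoms = [box(i, 0, i + 1, 1) for i in range(len(ids))]
    regions = RegionSet(region_id=ids, geometry=geoms,
                        demand=np.array([demand[r] for r in ids]), crs="planar")
    supply = supply_at(regions, {sid: (host, capacity[sid])
                                 for sid, host in seeds.items()})
    return regions, supply


@pytest.fixture
def default_config() -> PropagationConfig:
    return PropagationConfig()
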
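"""Region tessellations, supply points, and spatial adjacency.

The estimator views a study area as a tessellation of small regions
(census-style units), each carrying a non-negative demand value (typically
resident population), plus a sparse set of supply points (facilities with a
capacity, typically hospital bed counts). This module reads those layers,
derives the region adjacency graph from polygon contiguity, and resolves
each supply point to the region that hosts it — merging co-located
facilities so that no region hosts more than one supply entity.

Polygon layers are GeoJSON FeatureCollections; supply tables are CSV with
coordinate columns or GeoJSON point layers. All layers must share a single
planar CRS: no reprojection is attempted, but a ``crs`` string is carried
through and checked for consistency where two layers meet.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point, mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .errors import ConfigurationError, DataError

CONTIGUITY_RULES = ("shared-edge", "shared-point")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """A polygon tessellation with one demand value per region.

    Parameters
    ----------
    region_id : list of str
        Unique opaque identifiers, one per region.
    geometry : list of shapely geometries
        Polygon or MultiPolygon per region, in ``crs``.
    demand : array-like of float
        Non-negative demand (e.g. resident population) per region.
    crs : str, optional
        Identifier of the planar CRS the geometries are expressed in.
    """

    region_id: list[str]
    geometry: list[BaseGeometry]
    demand: np.ndarray
    crs: str | None = None

    def __post_init__(self):
        self.region_id = [str(r) for r in self.region_id]
        self.demand = np.asarray(self.demand, dtype=float)
        if not (len(self.region_id) == len(self.geometry) == len(self.demand)):
            raise DataError("region_id, geometry and demand lengths differ")
        dupes = pd.Index(self.region_id)[pd.Index(self.region_id).duplicated()]
        if len(dupes):
            raise DataError(
                f"duplicate region ids: {sorted(set(dupes))}"
            )
        neg = [r for r, d in zip(self.region_id, self.demand) if d < 0]
        if neg:
            raise DataError(f"negative demand for regions: {neg}")
        if np.isnan(self.demand).any():
            bad = [r for r, d in zip(self.region_id, self.demand) if np.isnan(d)]
            raise DataError(f"missing demand for regions: {bad}")
        self.geometry = [self._repair(g, r) for g, r in zip(self.geometry, self.region_id)]
        self._index = {r: i for i, r in enumerate(self.region_id)}

    @staticmethod
    def _repair(geom: BaseGeometry, rid: str) -> BaseGeometry:
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise DataError(f"region {rid!r}: non-polygon geometry ({geom.geom_type})")
        if not geom.is_valid:
            repaired = make_valid(geom)
            if repaired.geom_type == "GeometryCollection":
                # keep only the areal parts of the repair output
                parts = [g for g in repaired.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
                if not parts:
                    raise DataError(f"region {rid!r}: geometry not repairable")
                repaired = parts[0] if len(parts) == 1 else parts[0].union(*parts[1:])
            warnings.warn(f"region {rid!r}: invalid geometry repaired", stacklevel=3)
            return repaired
        return geom

    def __len__(self) -> int:
        return len(self.region_id)

    def index_of(self, region_id: str) -> int:
        return self._index[region_id]

    def demand_of(self, region_id: str) -> float:
        return float(self.demand[self._index[region_id]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region_id": self.region_id, "demand": self.demand})


@dataclass
class SupplySet:
    """Point-located supply (facilities with capacity).

    Before resolution ``host_region`` is None. After
    :func:`locate_and_merge_supply` every entry has a host region, at most
    one entry exists per host region, and ``merged_from`` lists the original
    supply ids folded into each entry (length >= 1); total capacity is
    preserved under merging.
    """

    supply_id: list[str]
    location: list[Point]
    capacity: np.ndarray
    host_region: list[str] | None = None
    merged_from: list[list[str]] | None = None
    crs: str | None = None

    def __post_init__(self):
        self.supply_id = [str(s) for s in self.supply_id]
        self.capacity = np.asarray(self.capacity, dtype=float)
        if len(set(self.supply_id)) != len(self.supply_id):
            seen, dupes = set(), set()
            for s in self.supply_id:
                (dupes if s in seen else seen).add(s)
            raise DataError(f"duplicate supply ids: {sorted(dupes)}")
        if (self.capacity < 0).any():
            bad = [s for s, c in zip(self.supply_id, self.capacity) if c < 0]
            raise DataError(f"negative capacity for supply points: {bad}")
        if self.merged_from is None:
            self.merged_from = [[s] for s in self.supply_id]

    def __len__(self) -> int:
        return len(self.supply_id)

    @property
    def resolved(self) -> bool:
        return self.host_region is not None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "supply_id": self.supply_id,
                "x": [p.x for p in self.location],
                "y": [p.y for p in self.location],
                "capacity": self.capacity,
            }
        )
        if self.resolved:
            df["host_region"] = self.host_region
            df["merged_from"] = ["|".join(m) for m in self.merged_from]
        return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_regions(path: str | Path, id_field: str, demand_field: str) -> RegionSet:
    """Read a polygon tessellation with demand from a GeoJSON file.

    Each feature must carry ``id_field`` and ``demand_field`` in its
    properties. Raises :class:`ConfigurationError` when a named field is
    missing and :class:`DataError` for duplicate ids, negative demand, or
    non-polygon geometry.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features")
    if doc.get("type") != "FeatureCollection" or feats is None:
        raise DataError(f"{path}: not a GeoJSON FeatureCollection")
    ids, geoms, demands = [], [], []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        for fname in (id_field, demand_field):
            if fname not in props:
                raise ConfigurationError(
                    f"{path}: feature {i} has no field {fname!r}"
                )
        ids.append(str(props[id_field]))
        demands.append(float(props[demand_field]))
        geoms.append(shape(feat["geometry"]))
    crs = _geojson_crs(doc)
    return RegionSet(region_id=ids, geometry=geoms, demand=np.array(demands), crs=crs)


def write_regions(regions: RegionSet, path: str | Path,
                  id_field: str = "region_id", demand_field: str = "demand") -> None:
    """Write a RegionSet as a GeoJSON FeatureCollection."""
    feats = [
        {
            "type": "Feature",
            "properties": {id_field: rid, demand_field: float(dem)},
            "geometry": mapping(geom),
        }
        for rid, geom, dem in zip(regions.region_id, regions.geometry, regions.demand)
    ]
    doc: dict = {"type": "FeatureCollection", "features": feats}
    if regions.crs:
        doc["crs"] = {"type": "name", "properties": {"name": regions.crs}}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_supply(path: str | Path, id_field: str = "supply_id",
                x_field: str = "x", y_field: str = "y",
                capacity_field: str = "capacity") -> SupplySet:
    """Read unresolved supply points from CSV (coordinate columns) or a
    GeoJSON point layer."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            doc = json.load(fh)
        ids, pts, caps = [], [], []
        for i, feat in enumerate(doc.get("features", [])):
            props = feat.get("properties") or {}
            for fname in (id_field, capacity_field):
                if fname not in props:
                    raise ConfigurationError(f"{path}: feature {i} has no field {fname!r}")
            geom = shape(feat["geometry"])
            if geom.geom_type != "Point":
                raise DataError(f"{path}: feature {i} is not a point")
            ids.append(str(props[id_field]))
            caps.append(float(props[capacity_field]))
            pts.append(geom)
        return SupplySet(ids, pts, np.array(caps), crs=_geojson_crs(doc))
    df = pd.read_csv(path)
    for fname in (id_field, x_field, y_field, capacity_field):
        if fname not in df.columns:
            raise ConfigurationError(f"{path}: no column {fname!r}")
    pts = [Point(x, y) for x, y in zip(df[x_field], df[y_field])]
    return SupplySet(list(df[id_field].astype(str)), pts,
                     df[capacity_field].to_numpy(dtype=float))


def write_supply(supply: SupplySet, path: str | Path) -> None:
    supply.to_frame().to_csv(path, index=False)


def write_adjacency(graph: nx.Graph, path: str | Path) -> None:
    """Write the adjacency graph as an edge-list CSV (region_a, region_b)."""
    rows = sorted(tuple(sorted(e)) for e in graph.edges)
    pd.DataFrame(rows, columns=["region_a", "region_b"]).to_csv(path, index=False)


def _geojson_crs(doc: dict) -> str | None:
    crs = doc.get("crs")
    if isinstance(crs, dict):
        return crs.get("properties", {}).get("name")
    return None


# ---------------------------------------------------------------------------
# Adjacency
# ---------------------------------------------------------------------------

def build_adjacency(regions: RegionSet, contiguity: str = "shared-edge") -> nx.Graph:
    """Construct the region adjacency graph from polygon contiguity.

    ``shared-edge`` (rook-like) connects regions whose boundaries share a
    one-dimensional stretch; ``shared-point`` (queen-like) additionally
    connects regions that touch only at corner points. The graph is
    undirected with no self-loops; its node set equals the region ids.
    Regions with no neighbours remain as isolated nodes (a warning lists
    them). Regions that are disconnected in physical space — e.g. separated
    by an estuary so their polygons never touch — are simply non-adjacent,
    which is how coastline and river topology constrains propagation.
    """
    if contiguity not in CONTIGUITY_RULES:
        raise ConfigurationError(
            f"unknown contiguity rule {contiguity!r}; expected one of {CONTIGUITY_RULES}"
        )
    graph = nx.Graph()
    graph.add_nodes_from(regions.region_id)
    tree = STRtree(regions.geometry)
    pairs = tree.query(regions.geometry, predicate="intersects")
    overlapping = []
    for i, j in pairs.T:
        if i >= j:
            continue
        inter = regions.geometry[i].intersection(regions.geometry[j])
        if inter.is_empty:
            continue
        if getattr(inter, "area", 0.0) > 0:
            overlapping.append((regions.region_id[i], regions.region_id[j]))
        elif contiguity == "shared-edge" and inter.length == 0:
            continue  # corner touch only
        graph.add_edge(regions.region_id[i], regions.region_id[j])
    if overlapping:
        warnings.warn(
            f"{len(overlapping)} region pairs have overlapping interiors "
            f"(treated as adjacent), e.g. {overlapping[:3]}", stacklevel=2
        )
    isolated = [n for n in graph.nodes if graph.degree(n) == 0]
    if isolated:
        warnings.warn(f"{len(isolated)} isolated regions: {isolated[:10]}", stacklevel=2)
    return graph


# ---------------------------------------------------------------------------
# Supply resolution
# ---------------------------------------------------------------------------

def locate_and_merge_supply(regions: RegionSet, supply: SupplySet) -> SupplySet:
    """Resolve each supply point to its host region and merge co-located
    facilities.

    Every point is assigned to the region containing it (point-in-polygon,
    boundary inclusive). A point on a shared boundary is assigned to the
    candidate region with the lexicographically smallest id, which keeps the
    result deterministic. All points resolving to the same region are merged
    into one entry whose capacity is the sum of the originals and whose
    ``merged_from`` records them; total capacity is conserved.
    """
    if regions.crs and supply.crs and regions.crs != supply.crs:
        raise ConfigurationError(
            f"CRS mismatch: regions {regions.crs!r} vs supply {supply.crs!r}"
        )
    tree = STRtree(regions.geometry)
    hosts: list[str] = []
    for sid, pt in zip(supply.supply_id, supply.location):
        cand = tree.query(pt, predicate="intersects")
        cand = [int(c) for c in cand if regions.geometry[int(c)].covers(pt)]
        if not cand:
            raise DataError(f"supply point {sid!r} falls outside every region")
        hosts.append(min(regions.region_id[c] for c in cand))

    merged: dict[str, dict] = {}
    for sid, pt, cap, host in zip(supply.supply_id, supply.location,
                                  supply.capacity, hosts):
        if host not in merged:
            merged[host] = {"supply_id": sid, "location": pt,
                            "capacity": 0.0, "merged_from": []}
        merged[host]["capacity"] += float(cap)
        merged[host]["merged_from"].append(sid)

    entries = sorted(merged.items(), key=lambda kv: kv[1]["supply_id"])
    return SupplySet(
        supply_id=[e["supply_id"] for _, e in entries],
        location=[e["location"] for _, e in entries],
        capacity=np.array([e["capacity"] for _, e in entries]),
        host_region=[host for host, _ in entries],
        merged_from=[e["merged_from"] for _, e in entries],
        crs=supply.crs or regions.crs,
    )
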
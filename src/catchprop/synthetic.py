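"""Self-contained synthetic geographies with known ground truth.

Generates the three inputs the estimator needs — a contiguous polygon
tessellation, a heterogeneous non-negative demand surface, and a sparse
set of supply points with heterogeneous capacity — plus simulated
"activity" records (cases drawn from a known catchment assignment with
configurable boundary noise), so the whole pipeline is testable without
any external data.

Layouts: ``grid`` (unit squares), ``path`` (a 1 x n strip, handy because
one-dimensional propagation runs can be simulated by hand), and
``voronoi`` (random planar tessellation clipped to a box). All randomness
flows through one integer seed via :class:`numpy.random.Generator`
(PCG64), so every artefact is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point, box
from shapely.ops import voronoi_diagram
from shapely.geometry import MultiPoint

from .core import CatchmentMap
from .errors import ConfigurationError, DataError
from .geometry import RegionSet, SupplySet

LAYOUTS = ("grid", "voronoi", "path")
DEMAND_MODELS = ("uniform", "lognormal", "hotspot")
CAPACITY_MODELS = ("equal", "lognormal")
NOISE_MODELS = ("uniform", "largest")


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study geography.

    demand defaults emulate small census units (~1,500 residents each,
    lognormally dispersed); capacity defaults emulate a sparse hospital
    network whose bed numbers vary over roughly an order of magnitude.
    ``activity_noise`` is the probability that a simulated case ignores
    its true catchment: under the ``uniform`` noise model it picks any
    facility uniformly at random; under ``largest`` it picks the
    highest-capacity facility, mimicking pull toward tertiary centres.
    """

    layout: str = "grid"
    n_regions: int = 100
    demand_model: str = "lognormal"
    demand_params: dict = field(default_factory=lambda: {"mean": 1500.0, "sigma": 0.5})
    n_supply: int = 4
    capacity_model: str = "lognormal"
    capacity_params: dict = field(default_factory=lambda: {"mean": 300.0, "sigma": 0.7})
    seed: int = 0
    activity_noise: float = 0.0
    noise_model: str = "uniform"

    def validate(self) -> None:
        if self.layout not in LAYOUTS:
            raise ConfigurationError(f"layout must be one of {LAYOUTS}")
        if self.demand_model not in DEMAND_MODELS:
            raise ConfigurationError(f"demand_model must be one of {DEMAND_MODELS}")
        if self.capacity_model not in CAPACITY_MODELS:
            raise ConfigurationError(f"capacity_model must be one of {CAPACITY_MODELS}")
        if self.noise_model not in NOISE_MODELS:
            raise ConfigurationError(f"noise_model must be one of {NOISE_MODELS}")
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be positive")
        if not (1 <= self.n_supply <= self.n_regions):
            raise ConfigurationError("need 1 <= n_supply <= n_regions")
        if not (0.0 <= self.activity_noise <= 1.0):
            raise ConfigurationError("activity_noise must be in [0, 1]")


def _grid_dims(n: int) -> tuple[int, int]:
    """Largest divisor pair (rows <= cols) for an n-cell rectangular grid."""
    rows = int(np.sqrt(n))
    while rows > 1 and n % rows:
        rows -= 1
    return rows, n // rows


def _draw_demand(spec: SyntheticSpec, centroids: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    n = len(centroids)
    p = spec.demand_params
    if spec.demand_model == "uniform":
        return np.full(n, float(p.get("value", 1500.0)))
    if spec.demand_model == "lognormal":
        mean, sigma = float(p.get("mean", 1500.0)), float(p.get("sigma", 0.5))
        mu = np.log(mean) - sigma**2 / 2  # mean-parameterised lognormal
        return rng.lognormal(mu, sigma, size=n)
    # hotspot: background plus a Gaussian bump around a random centre
    base = float(p.get("base", 500.0))
    peak = float(p.get("peak", 5000.0))
    width = float(p.get("width", 0.25))  # fraction of the layout extent
    extent = centroids.max(axis=0) - centroids.min(axis=0)
    centre = centroids.min(axis=0) + rng.uniform(0.2, 0.8, 2) * extent
    s = width * max(extent.max(), 1e-9)
    d2 = ((centroids - centre) ** 2).sum(axis=1)
    return base + peak * np.exp(-d2 / (2 * s**2))


def make_regions(spec: SyntheticSpec) -> RegionSet:
    """Generate a contiguous tessellation with demands drawn from the
    spec's demand model. Deterministic given the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if spec.layout in ("grid", "path"):
        if spec.layout == "path":
            rows, cols = 1, spec.n_regions
        else:
            rows, cols = _grid_dims(spec.n_regions)
        geoms, ids = [], []
        for r in range(rows):
            for c in range(cols):
                geoms.append(box(c, r, c + 1, r + 1))
                ids.append(f"R{r * cols + c:04d}")
    else:  # voronoi
        side = float(np.sqrt(spec.n_regions))
        pts = rng.uniform(0, side, size=(spec.n_regions, 2))
        envelope = box(0, 0, side, side)
        cells = voronoi_diagram(MultiPoint([Point(*p) for p in pts]),
                                envelope=envelope)
        clipped = [g.intersection(envelope) for g in cells.geoms]
        # voronoi_diagram does not preserve seed order; match cells back
        tree = STRtree(clipped)
        geoms = [None] * spec.n_regions
        for i, p in enumerate(pts):
            cand = tree.query(Point(*p), predicate="intersects")
            hit = [int(c) for c in cand if clipped[int(c)].covers(Point(*p))]
            if not hit:
                raise DataError("voronoi cell matching failed (degenerate seed layout)")
            geoms[i] = clipped[hit[0]]
        ids = [f"R{i:04d}" for i in range(spec.n_regions)]
    centroids = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
    demand = _draw_demand(spec, centroids, rng)
    return RegionSet(region_id=ids, geometry=geoms, demand=demand,
                     crs="synthetic-planar")


def place_supply(regions: RegionSet, spec: SyntheticSpec) -> SupplySet:
    """Place ``n_supply`` facilities at interior points of distinct
    regions, with capacities from the spec's capacity model."""
    spec.validate()
    if spec.n_supply > len(regions):
        raise ConfigurationError("n_supply exceeds number of regions")
    rng = np.random.default_rng(spec.seed + 1)
    host_idx = np.sort(rng.choice(len(regions), size=spec.n_supply, replace=False))
    pts = [regions.geometry[i].representative_point() for i in host_idx]
    p = spec.capacity_params
    if spec.capacity_model == "equal":
        caps = np.full(spec.n_supply, float(p.get("value", 300.0)))
    else:
        mean, sigma = float(p.get("mean", 300.0)), float(p.get("sigma", 0.7))
        mu = np.log(mean) - sigma**2 / 2
        caps = rng.lognormal(mu, sigma, size=spec.n_supply)
    ids = [f"H{j:02d}" for j in range(spec.n_supply)]
    return SupplySet(supply_id=ids, location=pts, capacity=caps, crs=regions.crs)


def simulate_activity(cmap: CatchmentMap, regions: RegionSet, n_cases: int,
                      spec: SyntheticSpec) -> pd.DataFrame:
    """Simulate observed facility-use records from a known catchment map.

    Cases land in regions with probability proportional to demand; each
    case's observed facility is its region's assigned facility with
    probability ``1 - activity_noise``, otherwise drawn from the noise
    model. Returns a DataFrame with columns (case_id, region_id, x, y,
    observed). Deterministic given the spec seed.
    """
    spec.validate()
    if n_cases < 1:
        raise DataError("n_cases must be >= 1")
    rng = np.random.default_rng(spec.seed + 2)
    assigned = sorted(cmap.assignment)
    weights = np.array([regions.demand_of(r) for r in assigned])
    if weights.sum() <= 0:
        raise DataError("no demand to draw cases from")
    probs = weights / weights.sum()
    region_idx = rng.choice(len(assigned), size=n_cases, p=probs)

    facilities = sorted(set(cmap.assignment.values()))
    largest = cmap.totals["total_supply"].idxmax()
    noisy = rng.random(n_cases) < spec.activity_noise
    noise_pick = rng.integers(0, len(facilities), size=n_cases)

    rows = []
    for i, ridx in enumerate(region_idx):
        rid = assigned[ridx]
        pt = regions.geometry[regions.index_of(rid)].representative_point()
        if noisy[i]:
            obs = largest if spec.noise_model == "largest" else facilities[noise_pick[i]]
        else:
            obs = cmap.assignment[rid]
        rows.append((f"C{i:06d}", rid, pt.x, pt.y, obs))
    return pd.DataFrame(rows, columns=["case_id", "region_id", "x", "y", "observed"])
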
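"""Comparison machinery for catchment assignments.

Supports benchmarking a propagated catchment map against an independent
facility-assignment source (e.g. observed admission records): aggregation
of fine-grained catchments into probabilistic coarse-unit-to-facility
mappings weighted by demand, areal interpolation of demand onto foreign
polygon boundaries, and the agreement statistics — multinomial accuracy,
one-vs-all balanced accuracy, multiclass Matthews correlation, and the
intraclass correlation coefficient ICC(2,k) (two-way random effects,
absolute agreement, average of k raters) with its 95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely import STRtree
from sklearn.metrics import matthews_corrcoef

from .core import CatchmentMap
from .errors import DataError
from .geometry import RegionSet

__all__ = [
    "aggregate_to_coarse", "interpolate_demand", "multinomial_accuracy",
    "one_vs_all_balanced_accuracy", "mcc", "icc_two_way", "predict_facility",
    "agreement_stats", "AgreementStats", "ICCResult",
]


# ---------------------------------------------------------------------------
# Cross mappings and areal interpolation
# ---------------------------------------------------------------------------

def aggregate_to_coarse(cmap: CatchmentMap, lookup: pd.DataFrame,
                        regions: RegionSet,
                        fine_col: str = "fine_id",
                        coarse_col: str = "coarse_id") -> pd.DataFrame:
    """Coarse-grain a fine-region catchment map into a probabilistic
    coarse-unit -> facility mapping weighted by demand.

    For each coarse unit c and facility m,
    ``weight(c, m) = demand of fine regions in c assigned to m / total
    demand of fine regions in c`` and ``expected_cases = weight * coarse
    demand``. Returns a DataFrame with columns (coarse_id, supply_id,
    weight, expected_cases, zero_demand). Coarse units whose total demand
    is zero get uniform weights over the facilities present and are
    flagged.
    """
    lut = dict(zip(lookup[fine_col].astype(str), lookup[coarse_col].astype(str)))
    missing = sorted(set(cmap.assignment) - set(lut))
    if missing:
        raise DataError(f"fine regions missing from lookup: {missing[:10]}"
                        f"{'...' if len(missing) > 10 else ''}")
    rows = []
    for fine, sid in cmap.assignment.items():
        rows.append((lut[fine], sid, regions.demand_of(fine)))
    df = pd.DataFrame(rows, columns=["coarse_id", "supply_id", "demand"])
    grp = df.groupby(["coarse_id", "supply_id"], as_index=False)["demand"].sum()
    coarse_tot = grp.groupby("coarse_id")["demand"].transform("sum")
    out = grp.copy()
    zero = coarse_tot == 0
    out["weight"] = 0.0
    out.loc[~zero, "weight"] = grp.loc[~zero, "demand"] / coarse_tot[~zero]
    out["zero_demand"] = False
    if zero.any():
        for c in out.loc[zero, "coarse_id"].unique():
            mask = out["coarse_id"] == c
            out.loc[mask, "weight"] = 1.0 / mask.sum()
            out.loc[mask, "zero_demand"] = True
        warnings.warn("coarse units with zero total demand assigned uniform "
                      f"weights: {sorted(out.loc[zero, 'coarse_id'].unique())}",
                      stacklevel=2)
    coarse_demand = grp.groupby("coarse_id")["demand"].sum()
    out["expected_cases"] = out["weight"] * out["coarse_id"].map(coarse_demand)
    return out[["coarse_id", "supply_id", "weight", "expected_cases",
                "zero_demand"]].sort_values(["coarse_id", "supply_id"],
                                            ignore_index=True)


def interpolate_demand(source: RegionSet, targets: RegionSet) -> pd.Series:
    """Areal interpolation: apportion each source region's demand to
    target polygons proportionally to overlap area.

    Returns a Series indexed by target region id. Total demand is
    conserved when the targets tile the sources exactly; coverage gaps
    (source area falling outside every target) are reported with a
    warning. Assumes demand is uniformly distributed within each source
    region.
    """
    if source.crs and targets.crs and source.crs != targets.crs:
        raise DataError(f"CRS mismatch: {source.crs!r} vs {targets.crs!r}")
    out = pd.Series(0.0, index=pd.Index(targets.region_id, name="region_id"))
    tree = STRtree(targets.geometry)
    covered = 0.0
    total_src_area = 0.0
    for geom, dem in zip(source.geometry, source.demand):
        area = geom.area
        total_src_area += area
        if area == 0:
            continue
        for t in tree.query(geom, predicate="intersects"):
            overlap = geom.intersection(targets.geometry[int(t)]).area
            if overlap > 0:
                out.iloc[int(t)] += dem * overlap / area
                covered += overlap
    if covered == 0:
        warnings.warn("source and target layers do not overlap; all "
                      "interpolated demand is zero", stacklevel=2)
    elif covered < total_src_area * (1 - 1e-9):
        gap = 1 - covered / total_src_area
        warnings.warn(f"targets cover only {100 * (1 - gap):.2f}% of the "
                      "source area; demand in the gap is dropped", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Facility prediction
# ---------------------------------------------------------------------------

def predict_facility(assignment_source, cases: pd.DataFrame,
                     regions: RegionSet | None = None) -> pd.DataFrame:
    """Predict the serving facility for each case.

    Two modes, selected by the type of ``assignment_source``:

    * :class:`CatchmentMap` — each case must have ``x``/``y`` columns (or a
      ``region_id`` column); the prediction is the catchment label of the
      containing region (``regions`` required for point resolution).
    * cross-mapping DataFrame from :func:`aggregate_to_coarse` — each case
      must have a ``coarse_id`` column; the prediction is the
      maximum-weight facility of that coarse unit, ties broken by facility
      id order.

    Cases that cannot be resolved (point outside every region, unknown
    coarse id) are excluded; the returned frame's ``dropped`` attribute
    (``result.attrs["dropped"]``) lists their case ids. Columns of the
    result: case_id, predicted, plus observed when present in ``cases``.
    """
    dropped: list = []
    preds: list[tuple] = []
    has_obs = "observed" in cases.columns

    if isinstance(assignment_source, CatchmentMap):
        cmap = assignment_source
        if "region_id" in cases.columns:
            resolve = lambda row: str(row["region_id"])  # noqa: E731
        else:
            if regions is None:
                raise DataError("regions required to resolve case coordinates")
            tree = STRtree(regions.geometry)

            def resolve(row):
                from shapely.geometry import Point
                pt = Point(row["x"], row["y"])
                cand = [int(c) for c in tree.query(pt, predicate="intersects")
                        if regions.geometry[int(c)].covers(pt)]
                if not cand:
                    return None
                return min(regions.region_id[c] for c in cand)

        for _, row in cases.iterrows():
            rid = resolve(row)
            if rid is None or rid not in cmap.assignment:
                dropped.append(row["case_id"])
                continue
            rec = (row["case_id"], cmap.assignment[rid])
            preds.append(rec + ((str(row["observed"]),) if has_obs else ()))
    else:
        mapping = assignment_source
        best = (mapping.sort_values(["weight", "supply_id"],
                                    ascending=[False, True])
                .drop_duplicates("coarse_id").set_index("coarse_id")["supply_id"])
        for _, row in cases.iterrows():
            c = str(row["coarse_id"])
            if c not in best.index:
                dropped.append(row["case_id"])
                continue
            rec = (row["case_id"], best[c])
            preds.append(rec + ((str(row["observed"]),) if has_obs else ()))

    cols = ["case_id", "predicted"] + (["observed"] if has_obs else [])
    out = pd.DataFrame(preds, columns=cols)
    out.attrs["dropped"] = dropped
    return out


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def multinomial_accuracy(preds: pd.DataFrame) -> float:
    """Fraction of cases whose predicted facility matches the observed one."""
    if len(preds) == 0:
        raise DataError("empty prediction set")
    return float((preds["predicted"] == preds["observed"]).mean())


def one_vs_all_balanced_accuracy(preds: pd.DataFrame, class_id: str
                                 ) -> tuple[float, bool]:
    """Balanced accuracy, (sensitivity + specificity) / 2, after collapsing
    labels to ``class_id`` vs rest.

    Returns ``(value, sensitivity_defined)``. When ``class_id`` never
    occurs among the observed labels sensitivity is undefined and the
    value is the specificity alone, flagged False.
    """
    if len(preds) == 0:
        raise DataError("empty prediction set")
    obs = preds["observed"] == class_id
    pred = preds["predicted"] == class_id
    if not obs.any() and not pred.any():
        raise DataError(f"class {class_id!r} absent from both observed and "
                        "predicted labels")
    tn = int((~obs & ~pred).sum())
    fp = int((~obs & pred).sum())
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    if not obs.any():
        return float(specificity), False
    tp = int((obs & pred).sum())
    fn = int((obs & ~pred).sum())
    sensitivity = tp / (tp + fn)
    if np.isnan(specificity):  # every case observed in class_id
        return float(sensitivity), True
    return float((sensitivity + specificity) / 2), True


def mcc(preds: pd.DataFrame) -> float:
    """Multiclass Matthews correlation coefficient (Gorodkin
    generalisation) over the full confusion matrix."""
    if len(preds) == 0:
        raise DataError("empty prediction set")
    if preds["observed"].nunique() < 2:
        raise DataError("MCC undefined for a single observed class")
    return float(matthews_corrcoef(preds["observed"], preds["predicted"]))


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def icc_two_way(ratings: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(2,k): two-way random effects, absolute agreement, average of k
    raters, with a confidence interval from the F-distribution bounds.

    ``ratings`` is an n-subjects x k-raters matrix with no missing cells.
    The estimate follows the standard two-way ANOVA decomposition::

        ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    where MSR, MSC and MSE are the mean squares for rows (subjects),
    columns (raters) and error. Absolute agreement means a constant offset
    between raters (captured by MSC) lowers the estimate, unlike the
    consistency model. Zero between-subject variance yields estimate 0
    with ``degenerate=True``.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise DataError("ratings must be a 2-D matrix (subjects x raters)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise DataError("need at least 2 subjects and 2 raters")
    if np.isnan(x).any():
        raise DataError("missing cells are not supported")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if np.allclose(row_means, row_means[0]):
        # no between-subject variance: agreement is unidentifiable
        return ICCResult(0.0, np.nan, np.nan, degenerate=True)

    denom_k = msr + (msc - mse) / n
    est_k = (msr - mse) / denom_k
    # single-measures estimate drives the Satterthwaite df of the CI
    est_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    tiny = 1e-12 * max(msr, 1.0)
    if mse <= tiny and msc <= tiny:
        # perfect absolute agreement: interval collapses onto the estimate
        return ICCResult(float(est_k), float(est_k), float(est_k))
    alpha = 1 - confidence
    a = k * est_1 / (n * (1 - est_1))
    b = 1 + k * est_1 * (n - 1) / (n * (1 - est_1))
    v = ((a * msc + b * mse) ** 2 /
         ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    l1 = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    u1 = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lk = l1 * k / (1 + (k - 1) * l1)
    uk = u1 * k / (1 + (k - 1) * u1)
    return ICCResult(float(est_k), float(lk), float(uk))


@dataclass
class AgreementStats:
    """Bundle of all agreement metrics for one prediction set."""

    multinomial_accuracy: float
    n_correct: int
    n_total: int
    mcc: float
    per_class_balanced_accuracy: pd.DataFrame
    icc: ICCResult | None = None

    def to_dict(self) -> dict:
        d = {
            "multinomial_accuracy": self.multinomial_accuracy,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "mcc": self.mcc,
        }
        if self.icc is not None:
            d["icc"] = {"estimate": self.icc.estimate,
                        "ci_low": self.icc.ci_low,
                        "ci_high": self.icc.ci_high,
                        "degenerate": self.icc.degenerate}
        return d


def agreement_stats(preds: pd.DataFrame) -> AgreementStats:
    """Compute the full metric bundle for a predicted-vs-observed set."""
    acc = multinomial_accuracy(preds)
    n_total = len(preds)
    n_correct = int((preds["predicted"] == preds["observed"]).sum())
    classes = sorted(set(preds["observed"]) | set(preds["predicted"]))
    rows = []
    for c in classes:
        val, defined = one_vs_all_balanced_accuracy(preds, c)
        rows.append((c, val, defined))
    per_class = pd.DataFrame(rows, columns=["supply_id", "balanced_accuracy",
                                            "sensitivity_defined"])
    m = mcc(preds) if preds["observed"].nunique() >= 2 else np.nan
    return AgreementStats(multinomial_accuracy=acc, n_correct=n_correct,
                          n_total=n_total, mcc=m,
                          per_class_balanced_accuracy=per_class)


def icc_from_crossmappings(map_a: pd.DataFrame, map_b: pd.DataFrame
                           ) -> ICCResult:
    """ICC(2,k) between the expected-cases matrices of two cross-mappings.

    Each (coarse_id, supply_id) pair with nonzero weight under either
    mapping is one subject; the two mappings are the raters; absent pairs
    contribute zero expected cases.
    """
    key = ["coarse_id", "supply_id"]
    a = map_a.loc[map_a["weight"] > 0].set_index(key)["expected_cases"]
    b = map_b.loc[map_b["weight"] > 0].set_index(key)["expected_cases"]
    idx = a.index.union(b.index)
    mat = np.column_stack([a.reindex(idx, fill_value=0.0).to_numpy(),
                           b.reindex(idx, fill_value=0.0).to_numpy()])
    return icc_two_way(mat)
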
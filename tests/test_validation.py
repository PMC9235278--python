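"""Agreement metrics, coarse aggregation, and areal interpolation, each
checked against brute-force oracles and (for the ICC) against pingouin."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from catchprop import (
    CatchmentMap,
    DataError,
    RegionSet,
    aggregate_to_coarse,
    icc_from_crossmappings,
    icc_two_way,
    interpolate_demand,
    mcc,
    multinomial_accuracy,
    one_vs_all_balanced_accuracy,
    predict_facility,
)

from conftest import grid_regions
from reference import (
    ref_balanced_accuracy,
    ref_icc2k,
    ref_interpolate,
    ref_mcc,
    ref_multinomial_accuracy,
)


def make_cmap(assignment):
    totals = (pd.Series(assignment).value_counts().rename("n").to_frame()
              .assign(total_supply=1.0, total_demand=1.0, supply_per_capita=1.0))
    totals.index.name = "supply_id"
    return CatchmentMap(assignment=dict(assignment),
                        labelled_at={r: 0 for r in assignment},
                        unreached=set(), totals=totals, iterations=0)


def preds_frame(pairs):
    return pd.DataFrame(
        [(f"c{i}", p, o) for i, (p, o) in enumerate(pairs)],
        columns=["case_id", "predicted", "observed"])


def random_pairs(rng, n=60, k=3):
    labels = [f"H{j:02d}" for j in range(k)]
    return [(labels[rng.integers(k)], labels[rng.integers(k)]) for _ in range(n)]


class TestMultinomialAccuracy:
    def test_perfect_and_zero(self):
        assert multinomial_accuracy(preds_frame([("A", "A")] * 10)) == 1.0
        assert multinomial_accuracy(preds_frame([("A", "B")] * 10)) == 0.0

    def test_29_of_40(self):
        pairs = [("A", "A")] * 29 + [("A", "B")] * 11
        assert multinomial_accuracy(preds_frame(pairs)) == pytest.approx(0.725)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            multinomial_accuracy(preds_frame([]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle(self, seed):
        pairs = random_pairs(np.random.default_rng(seed))
        assert multinomial_accuracy(preds_frame(pairs)) == pytest.approx(
            ref_multinomial_accuracy(pairs))


class TestBalancedAccuracy:
    def test_perfect_predictions_score_one_for_every_class(self):
        pairs = [("A", "A"), ("B", "B"), ("C", "C")] * 5
        for c in "ABC":
            val, defined = one_vs_all_balanced_accuracy(preds_frame(pairs), c)
            assert val == 1.0 and defined

    def test_constant_predictor_is_chance_level(self):
        # always predicts A; A observed half the time -> sens 1, spec 0
        pairs = [("A", "A")] * 10 + [("A", "B")] * 10
        val, defined = one_vs_all_balanced_accuracy(preds_frame(pairs), "A")
        assert val == pytest.approx(0.5) and defined

    def test_class_absent_from_observed_returns_flagged_specificity(self):
        pairs = [("A", "B"), ("B", "B"), ("C", "B")]
        val, defined = one_vs_all_balanced_accuracy(preds_frame(pairs), "A")
        assert not defined
        assert val == pytest.approx(2 / 3)  # pure specificity

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_confusion_matrix_oracle(self, seed):
        pairs = random_pairs(np.random.default_rng(100 + seed))
        frame = preds_frame(pairs)
        for c in sorted({o for _, o in pairs}):
            val, defined = one_vs_all_balanced_accuracy(frame, c)
            exp_val, exp_def = ref_balanced_accuracy(pairs, c)
            assert val == pytest.approx(exp_val) and defined == exp_def


class TestMCC:
    def test_perfect_is_one(self):
        assert mcc(preds_frame([("A", "A"), ("B", "B")] * 5)) == pytest.approx(1.0)

    def test_permuted_two_class_is_minus_one(self):
        pairs = [("A", "B")] * 5 + [("B", "A")] * 5
        assert mcc(preds_frame(pairs)) == pytest.approx(-1.0)

    def test_single_observed_class_rejected(self):
        with pytest.raises(DataError):
            mcc(preds_frame([("A", "A"), ("B", "A")]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_gorodkin_oracle(self, seed):
        pairs = random_pairs(np.random.default_rng(200 + seed), n=80, k=4)
        assert mcc(preds_frame(pairs)) == pytest.approx(ref_mcc(pairs))


class TestICC:
    def test_duplicated_columns_give_one(self):
        col = np.array([1.0, 4.0, 2.5, 7.0, 3.3, 5.1])
        res = icc_two_way(np.column_stack([col, col]))
        assert res.estimate == pytest.approx(1.0)

    def test_constant_offset_penalized_vs_consistency(self):
        col = np.array([1.0, 4.0, 2.5, 7.0, 3.3, 5.1])
        res = icc_two_way(np.column_stack([col, col + 50.0]))
        # absolute agreement: a large offset between raters crushes the ICC,
        # whereas a consistency model would still score 1
        assert res.estimate < 1.0
        assert res.estimate < 0.5

    def test_common_constant_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 2, (8, 3))
        a, b = icc_two_way(x), icc_two_way(x + 123.0)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.ci_low == pytest.approx(b.ci_low)

    def test_zero_between_subject_variance_flagged(self):
        x = np.array([[2.0, 3.0], [3.0, 2.0], [2.5, 2.5]])
        res = icc_two_way(x)
        assert res.estimate == 0.0 and res.degenerate

    def test_6x2_fixture_matches_anova_oracle(self):
        x = np.array([[9.0, 2.0], [4.5, 4.0], [5.0, 5.5],
                      [7.0, 7.0], [3.0, 3.5], [8.0, 8.5]])
        res = icc_two_way(x)
        est, lo, hi = ref_icc2k(x.tolist())
        assert res.estimate == pytest.approx(est)
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pingouin(self, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(300 + seed)
        n, k = int(rng.integers(6, 15)), int(rng.integers(2, 4))
        x = rng.normal(10, 3, (n, 1)) + rng.normal(0, 1.5, (n, k))
        res = icc_two_way(x)
        df = pd.DataFrame({"subj": np.repeat(range(n), k),
                           "rater": list(range(k)) * n,
                           "y": x.ravel()})
        row = pg.intraclass_corr(df, targets="subj", raters="rater",
                                 ratings="y").set_index("Type").loc["ICC(A,k)"]
        assert res.estimate == pytest.approx(row["ICC"], abs=1e-9)
        lo, hi = row["CI95"]
        assert res.ci_low == pytest.approx(lo, abs=5.1e-3)  # pingouin rounds
        assert res.ci_high == pytest.approx(hi, abs=5.1e-3)

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(DataError):
            icc_two_way(x)


class TestAggregateToCoarse:
    def test_weighted_share(self):
        regions = grid_regions(1, 2, demand=np.array([300.0, 700.0]))
        cmap = make_cmap({"R0000": "A", "R0001": "B"})
        lookup = pd.DataFrame({"fine_id": ["R0000", "R0001"],
                               "coarse_id": ["C1", "C1"]})
        out = aggregate_to_coarse(cmap, lookup, regions)
        w = out.set_index("supply_id")["weight"]
        assert w["A"] == pytest.approx(0.3)
        assert w["B"] == pytest.approx(0.7)
        assert out["expected_cases"].sum() == pytest.approx(1000.0)

    def test_single_facility_degenerate(self):
        regions = grid_regions(1, 3, demand=np.array([10.0, 20.0, 5.0]))
        cmap = make_cmap({r: "A" for r in regions.region_id})
        lookup = pd.DataFrame({"fine_id": regions.region_id,
                               "coarse_id": ["C1"] * 3})
        out = aggregate_to_coarse(cmap, lookup, regions)
        assert list(out["weight"]) == [1.0]

    def test_missing_lookup_entry_rejected(self):
        regions = grid_regions(1, 2, demand=np.array([1.0, 1.0]))
        cmap = make_cmap({"R0000": "A", "R0001": "A"})
        lookup = pd.DataFrame({"fine_id": ["R0000"], "coarse_id": ["C1"]})
        with pytest.raises(DataError, match="R0001"):
            aggregate_to_coarse(cmap, lookup, regions)

    def test_zero_demand_coarse_unit_uniform_and_flagged(self):
        regions = grid_regions(1, 2, demand=np.array([0.0, 0.0]))
        cmap = make_cmap({"R0000": "A", "R0001": "B"})
        lookup = pd.DataFrame({"fine_id": ["R0000", "R0001"],
                               "coarse_id": ["C1", "C1"]})
        with pytest.warns(UserWarning, match="zero"):
            out = aggregate_to_coarse(cmap, lookup, regions)
        assert list(out["weight"]) == [0.5, 0.5]
        assert out["zero_demand"].all()

    def test_random_fixture_matches_group_by_oracle(self):
        rng = np.random.default_rng(77)
        regions = grid_regions(4, 5, demand=rng.uniform(50, 500, 20))
        labels = [f"H{rng.integers(3):02d}" for _ in range(20)]
        cmap = make_cmap(dict(zip(regions.region_id, labels)))
        coarse = [f"C{i % 4}" for i in range(20)]
        lookup = pd.DataFrame({"fine_id": regions.region_id, "coarse_id": coarse})
        out = aggregate_to_coarse(cmap, lookup, regions)
        # brute-force recomputation
        demand = dict(zip(regions.region_id, regions.demand))
        lut = dict(zip(lookup.fine_id, lookup.coarse_id))
        for _, row in out.iterrows():
            num = sum(demand[r] for r in regions.region_id
                      if lut[r] == row.coarse_id
                      and cmap.assignment[r] == row.supply_id)
            den = sum(demand[r] for r in regions.region_id
                      if lut[r] == row.coarse_id)
            assert row.weight == pytest.approx(num / den)
        sums = out.groupby("coarse_id")["weight"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestInterpolateDemand:
    def test_identity_overlap(self):
        src = grid_regions(1, 1, demand=np.array([42.0]))
        tgt = RegionSet(["T0"], [box(0, 0, 1, 1)], np.array([0.0]), crs="planar")
        out = interpolate_demand(src, tgt)
        assert out["T0"] == pytest.approx(42.0)

    def test_half_square_gets_half_demand(self):
        src = grid_regions(1, 1, demand=np.array([100.0]))
        tgt = RegionSet(["T0"], [box(0, 0, 0.5, 1)], np.array([0.0]), crs="planar")
        with pytest.warns(UserWarning, match="cover"):
            out = interpolate_demand(src, tgt)
        assert out["T0"] == pytest.approx(50.0)

    def test_disjoint_layers_warn_and_zero(self):
        src = grid_regions(1, 1, demand=np.array([10.0]))
        tgt = RegionSet(["T0"], [box(5, 5, 6, 6)], np.array([0.0]), crs="planar")
        with pytest.warns(UserWarning, match="overlap"):
            out = interpolate_demand(src, tgt)
        assert out["T0"] == 0.0

    def test_shifted_grid_matches_pairwise_oracle_and_conserves(self):
        rng = np.random.default_rng(13)
        src = grid_regions(4, 4, demand=rng.uniform(10, 100, 16))
        # half-cell shifted 5x5 target grid fully covering the source
        tgt_geoms, tgt_ids = [], []
        for r in range(5):
            for c in range(5):
                tgt_geoms.append(box(c - 0.5, r - 0.5, c + 0.5, r + 0.5))
                tgt_ids.append(f"T{r * 5 + c:03d}")
        tgt = RegionSet(tgt_ids, tgt_geoms, np.zeros(25), crs="planar")
        out = interpolate_demand(src, tgt)
        expected = ref_interpolate(src.geometry, src.demand, tgt.geometry)
        assert np.allclose(out.to_numpy(), expected)
        assert out.sum() == pytest.approx(src.demand.sum(), rel=1e-12)


class TestPredictFacility:
    def test_catchment_mode_lookup(self):
        regions = grid_regions(1, 2, demand=np.array([1.0, 1.0]))
        cmap = make_cmap({"R0000": "A", "R0001": "B"})
        cases = pd.DataFrame({"case_id": ["c1", "c2"],
                              "x": [0.5, 1.5], "y": [0.5, 0.5],
                              "observed": ["A", "A"]})
        out = predict_facility(cmap, cases, regions=regions)
        assert list(out["predicted"]) == ["A", "B"]

    def test_case_outside_regions_dropped_and_reported(self):
        regions = grid_regions(1, 1, demand=np.array([1.0]))
        cmap = make_cmap({"R0000": "A"})
        cases = pd.DataFrame({"case_id": ["in", "out"],
                              "x": [0.5, 9.0], "y": [0.5, 9.0]})
        out = predict_facility(cmap, cases, regions=regions)
        assert list(out["case_id"]) == ["in"]
        assert out.attrs["dropped"] == ["out"]

    def test_crossmapping_argmax_with_id_order_ties(self):
        mapping = pd.DataFrame({
            "coarse_id": ["C1", "C1", "C2", "C2"],
            "supply_id": ["A", "B", "B", "A"],
            "weight": [0.6, 0.4, 0.5, 0.5],
            "expected_cases": [60.0, 40.0, 10.0, 10.0]})
        cases = pd.DataFrame({"case_id": ["c1", "c2"],
                              "coarse_id": ["C1", "C2"]})
        out = predict_facility(mapping, cases)
        assert list(out["predicted"]) == ["A", "A"]  # C2 tie -> id order

    def test_icc_between_identical_mappings_is_one(self):
        mapping = pd.DataFrame({
            "coarse_id": ["C1", "C1", "C2"],
            "supply_id": ["A", "B", "A"],
            "weight": [0.6, 0.4, 1.0],
            "expected_cases": [60.0, 40.0, 25.0]})
        res = icc_from_crossmappings(mapping, mapping.copy())
        assert res.estimate == pytest.approx(1.0)
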
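import numpy as np
import pandas as pd
import pytest

from aquadom.microbiota import (
    alpha_metrics,
    assimilable_carbon,
    core_sets,
    detect_contaminant_otus,
    filter_min_total,
    growing_otus,
    rarefy,
)


def meta_for(columns, habitats):
    return pd.DataFrame({"habitat": habitats}, index=columns)


class TestContaminantDetection:
    def test_control_enriched_otu_flagged(self):
        counts = pd.DataFrame(
            {"ctrl": [100, 900], "s1": [1, 9999], "s2": [1, 9999]},
            index=["X", "Y"],
        )
        meta = meta_for(counts.columns, ["negctrl", "plankton", "plankton"])
        assert detect_contaminant_otus(counts, meta) == {"X"}

    def test_absent_from_controls_never_flagged(self):
        counts = pd.DataFrame(
            {"ctrl": [0, 1000], "s1": [50, 950]}, index=["X", "Y"]
        )
        meta = meta_for(counts.columns, ["negctrl", "plankton"])
        assert "X" not in detect_contaminant_otus(counts, meta)

    def test_no_controls_warns_empty(self):
        counts = pd.DataFrame({"s1": [5, 5]}, index=["X", "Y"])
        meta = meta_for(counts.columns, ["plankton"])
        with pytest.warns(UserWarning):
            assert detect_contaminant_otus(counts, meta) == set()

    def test_planted_contaminants_recovered(self, community):
        _, counts, meta, _, truth = community
        assert detect_contaminant_otus(counts, meta) == truth.contaminants


class TestFilterMinTotal:
    def test_boundary(self):
        counts = pd.DataFrame(
            {"s1": [1, 2, 0], "s2": [1, 1, 0]}, index=["two", "three", "zero"]
        )
        out = filter_min_total(counts, min_total=3)
        assert set(out.index) == {"three"}

    def test_two_total_dropped_three_kept(self):
        counts = pd.DataFrame({"s1": [2, 3]}, index=["two", "three"])
        out = filter_min_total(counts)
        assert list(out.index) == ["three"]

    def test_empty_table(self):
        counts = pd.DataFrame(index=pd.Index([], name="otu"), columns=["s1"], dtype=int)
        assert filter_min_total(counts).empty


class TestRarefy:
    def _counts(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            rng.integers(0, 100, size=(20, 4)),
            index=[f"o{i}" for i in range(20)],
            columns=list("abcd"),
        )

    def test_column_sums_equal_depth(self):
        out = rarefy(self._counts(), depth=500, seed=1)
        kept = self._counts().sum(0) >= 500
        assert (out.sum(0) == 500).all()
        assert list(out.columns) == list(self._counts().columns[kept])

    def test_shallow_sample_dropped(self):
        counts = pd.DataFrame({"deep": [600], "shallow": [499]}, index=["o1"])
        out = rarefy(counts, depth=500, seed=0)
        assert list(out.columns) == ["deep"]

    def test_seeded_draw_reproducible(self):
        a = rarefy(self._counts(), depth=300, seed=7)
        b = rarefy(self._counts(), depth=300, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            rarefy(self._counts(), depth=0)


class TestAlphaMetrics:
    def test_goods_coverage_fixture(self):
        # 100 reads, 2 singletons
        col = [1, 1] + [49, 49]
        assert alpha_metrics(col).goods_coverage == pytest.approx(0.98)

    def test_uniform_community(self):
        m = alpha_metrics([10] * 10)
        assert m.shannon == pytest.approx(np.log(10))
        assert m.simpson == pytest.approx(0.9)

    def test_chao1_closed_form(self):
        # S_obs=10, F1=4, F2=2 -> chao1 = 10 + 4*3/(2*3) = 12
        col = [1, 1, 1, 1, 2, 2, 5, 5, 5, 5]
        assert alpha_metrics(col).chao1 == pytest.approx(12.0)

    def test_row_order_invariance(self):
        col = [5, 1, 0, 7, 2, 1]
        a = alpha_metrics(col)
        b = alpha_metrics(sorted(col, reverse=True))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            alpha_metrics([0, 0])


class TestGrowingOtus:
    def _community(self, growing=True, seed=0):
        from aquadom.simulate import CommunityDesign, simulate_community

        d = CommunityDesign(
            n_otus=30,
            n_brands=1,
            growth_otus={"OTU_g": (1e3, 1e5)} if growing else {},
            negctrl_otus={},
            n_negctrl=0,
            include_wells=False,
            seed=seed,
        )
        counts, meta, cells, truth = simulate_community(d)
        return counts, meta.loc[counts.columns, "day"], cells, truth

    def test_planted_grower_detected(self):
        counts, days, cells, truth = self._community()
        res = growing_otus(counts, days, cells, seed=3)
        assert res.growing == {"OTU_g"}

    def test_null_community_mostly_clean(self):
        counts, days, cells, _ = self._community(growing=False, seed=2)
        res = growing_otus(counts, days, cells, seed=3)
        assert len(res.growing) <= max(1, int(0.05 * counts.shape[0]))

    def test_deterministic_with_fixed_seed(self):
        counts, days, cells, _ = self._community()
        a = growing_otus(counts, days, cells, iters=5, seed=9)
        b = growing_otus(counts, days, cells, iters=5, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_missing_cell_counts_named(self):
        counts, days, cells, _ = self._community()
        bad = cells.drop(index=cells.index[0])
        with pytest.raises(ValueError, match=cells.index[0]):
            growing_otus(counts, days, bad, seed=0)

    def test_growing_flag_implies_positive_r_and_small_p(self):
        counts, days, cells, _ = self._community()
        res = growing_otus(counts, days, cells, seed=3)
        t = res.table
        flagged = t[t["growing"]]
        assert (flagged["adjusted_p"] < 0.05).all()
        assert (flagged["median_r"] > 0).all()


class TestCoreSets:
    def test_hand_enumerated_fixture(self, toy_core_table):
        counts, meta = toy_core_table
        cs = core_sets(counts, meta, n_brands=12)
        assert cs.well_core == {"OTU_a", "OTU_b", "OTU_fill"}
        assert cs.early_core == {"OTU_a", "OTU_b", "OTU_fill"}
        assert cs.late_core == {"OTU_a", "OTU_c", "OTU_fill"}
        assert cs.ubiquitous == {"OTU_a", "OTU_fill"}

    def test_below_abundance_floor_excluded(self, toy_core_table):
        counts, meta = toy_core_table
        cs = core_sets(counts, meta, n_brands=12)
        for s in (cs.well_core, cs.early_core, cs.late_core):
            assert "OTU_d" not in s

    def test_monotone_under_threshold_relaxation(self, toy_core_table):
        counts, meta = toy_core_table
        tight = core_sets(counts, meta, abund=0.005, occupancy=0.5, n_brands=12)
        looser_abund = core_sets(counts, meta, abund=0.003, occupancy=0.5, n_brands=12)
        looser_occ = core_sets(counts, meta, abund=0.005, occupancy=0.3, n_brands=12)
        for a, b in (
            (tight.well_core, looser_abund.well_core),
            (tight.early_core, looser_abund.early_core),
            (tight.late_core, looser_abund.late_core),
            (tight.well_core, looser_occ.well_core),
            (tight.late_core, looser_occ.late_core),
        ):
            assert a <= b

    def test_empty_category_rejected(self, toy_core_table):
        counts, meta = toy_core_table
        no_wells = meta[meta["water_type"] != "well"]
        with pytest.raises(ValueError):
            core_sets(counts[no_wells.index], no_wells, n_brands=12)


class TestAssimilableCarbon:
    def test_default_yield(self):
        assert assimilable_carbon(0, 1e5) == pytest.approx(10.0)

    def test_zero_growth(self):
        assert assimilable_carbon(5e4, 5e4) == 0.0

    def test_inverse_proportional_to_yield(self):
        a = assimilable_carbon(0, 1e5, yield_cells_per_ug=1e7)
        b = assimilable_carbon(0, 1e5, yield_cells_per_ug=2e7)
        assert a == pytest.approx(2 * b)

    def test_negative_growth_rejected(self):
        with pytest.raises(ValueError):
            assimilable_carbon(2e5, 1e5)
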
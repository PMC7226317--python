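import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import surprisalx as sx
from surprisalx.barcodes import TernaryBarcoder


class TestMakeBarcode:
    def test_threshold_crossings(self):
        np.testing.assert_array_equal(
            sx.make_barcode([28.0, 0.0, 39.0], threshold=24.0), [1, 0, 1]
        )
        np.testing.assert_array_equal(
            sx.make_barcode([-30.0, 10.0, 25.0], threshold=24.0), [-1, 0, 1]
        )

    def test_boundary_maps_to_zero(self):
        np.testing.assert_array_equal(
            sx.make_barcode([24.0, -24.0], threshold=24.0), [0, 0]
        )

    def test_null_barcode(self):
        assert (sx.make_barcode([0.0] * 7) == 0).all()

    def test_per_process_thresholds(self):
        digits = sx.make_barcode([10.0, 10.0], threshold=[5.0, 20.0])
        np.testing.assert_array_equal(digits, [1, 0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            sx.make_barcode([np.nan, 1.0])

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1.001, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance_when_crossings_preserved(self, scale, seed):
        """Scaling amplitudes and thresholds together leaves digits unchanged."""
        rng = np.random.default_rng(seed)
        lam = rng.normal(0, 30, size=6)
        lam = lam[np.abs(np.abs(lam) - 24.0) > 1e-6]  # keep away from the boundary
        if len(lam) == 0:
            return
        d1 = sx.make_barcode(lam, 24.0)
        d2 = sx.make_barcode(lam * scale, 24.0 * scale)
        np.testing.assert_array_equal(d1, d2)


class TestBarcoderEstimator:
    def test_transform_matrix(self):
        X = np.array([[30.0, -30.0, 0.0], [10.0, 50.0, -25.0]])
        digits = TernaryBarcoder(24.0).fit(X).transform(X)
        np.testing.assert_array_equal(digits, [[1, -1, 0], [0, 1, -1]])

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            TernaryBarcoder(0.0).fit(np.ones((2, 2)))


class TestCatalog:
    def test_manual_tally(self, toy_barcodes, toy_meta):
        catalog = sx.build_catalog(toy_barcodes, toy_meta)
        # unique barcodes: (1,0)x2+e, (1,-1), (0,0)x2, (-1,1) -> 4 unique
        assert len(catalog.table) == 4
        # null barcode carried by c,d gets index 1
        assert catalog.digits[1] == (0, 0)
        assert catalog.assignment.loc["c"] == 1 and catalog.assignment.loc["d"] == 1
        # most common non-null barcode (1,0) carried by a,e gets index 2
        assert catalog.digits[2] == (1, 0)
        row = catalog.table.loc[2]
        assert row["n_total"] == 2
        assert row["n_definite"] == 1 and row["n_probable"] == 1

    def test_partition_invariant(self, toy_barcodes, toy_meta):
        catalog = sx.build_catalog(toy_barcodes, toy_meta)
        assert catalog.table["n_total"].sum() == len(toy_barcodes)
        assert set(catalog.assignment.index) == set(toy_barcodes.index)
        assert catalog.assignment.notna().all()

    def test_single_shared_barcode(self, toy_meta):
        barcodes = pd.DataFrame(
            {"digit_1": [1, 1, 1, 1]}, index=pd.Index(list("abcd"), name="sample_id")
        )
        catalog = sx.build_catalog(barcodes, toy_meta)
        assert len(catalog.table) == 1
        assert catalog.table["n_total"].iloc[0] == 4

    def test_missing_metadata_sample_errors(self, toy_barcodes, toy_meta):
        with pytest.raises(KeyError):
            sx.build_catalog(toy_barcodes, toy_meta.drop("a"))


class TestSpecificity:
    def _catalog(self, digits, pathologies):
        barcodes = pd.DataFrame(
            {"digit_1": digits},
            index=pd.Index([f"s{i}" for i in range(len(digits))], name="sample_id"),
        )
        meta = pd.DataFrame(
            {
                "sample_id": barcodes.index,
                "subject_id": "p",
                "region": "Hi",
                "pathology": pathologies,
            }
        ).set_index("sample_id", drop=False)
        return sx.build_catalog(barcodes, meta)

    def test_ad_only_and_rare(self):
        catalog = self._catalog([1, 1, 0], ["possible", "definite", "non-demented"])
        row = catalog.table[catalog.table["digits"] == "1"].iloc[0]
        assert row["specificity"] == "AD-only"
        assert row["rare"]  # 2 AD carriers

    def test_mixed(self):
        catalog = self._catalog([1, 1], ["non-demented", "probable"])
        assert catalog.table["specificity"].iloc[0] == "mixed"

    def test_normal_only(self):
        catalog = self._catalog([1, 0], ["non-demented", "definite"])
        row = catalog.table[catalog.table["digits"] == "1"].iloc[0]
        assert row["specificity"] == "normal-only"
        assert not row["rare"]

    def test_null_class_regardless_of_carriers(self):
        catalog = self._catalog([0, 0], ["non-demented", "definite"])
        assert catalog.table["specificity"].iloc[0] == "null"

    def test_order_invariance(self, toy_barcodes, toy_meta):
        c1 = sx.build_catalog(toy_barcodes, toy_meta)
        shuffled = toy_barcodes.iloc[[3, 0, 5, 2, 4, 1]]
        c2 = sx.build_catalog(shuffled, toy_meta)
        pd.testing.assert_frame_equal(c1.table, c2.table)


class TestRegionEnrichment:
    def test_hand_computed_ratios(self):
        # region Hi: 10 AD carriers + 5 ND carriers of barcode (1,); all carry it
        n = 15
        barcodes = pd.DataFrame(
            {"digit_1": [1] * n},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
        meta = pd.DataFrame(
            {
                "sample_id": barcodes.index,
                "subject_id": "p",
                "region": "Hi",
                "pathology": ["definite"] * 10 + ["non-demented"] * 5,
            }
        ).set_index("sample_id", drop=False)
        catalog = sx.build_catalog(barcodes, meta)
        table = sx.region_enrichment(catalog, meta)
        row = table.iloc[0]
        assert (row["n_AD"], row["n_ND"], row["ratio"]) == (10, 5, 2.0)

    def test_min_frac_exclusion(self):
        # barcode carried by 1 of 20 AD and 1 of 20 ND (5% each) -> excluded at 10%
        barcodes = pd.DataFrame(
            {"digit_1": [1, 1] + [0] * 38},
            index=pd.Index([f"s{i}" for i in range(40)], name="sample_id"),
        )
        meta = pd.DataFrame(
            {
                "sample_id": barcodes.index,
                "subject_id": "p",
                "region": "Hi",
                "pathology": ["definite", "non-demented"] * 20,
            }
        ).set_index("sample_id", drop=False)
        catalog = sx.build_catalog(barcodes, meta)
        table = sx.region_enrichment(catalog, meta, min_frac=0.10)
        idx = catalog.assignment.loc["s0"]
        assert idx not in set(table["barcode_index"])

    def test_ad_exclusive_reported(self, toy_barcodes, toy_meta):
        catalog = sx.build_catalog(toy_barcodes, toy_meta)
        table = sx.region_enrichment(catalog, toy_meta, min_frac=0.10)
        excl = table[table["note"] == "AD-exclusive in region"]
        assert (np.isinf(excl["ratio"])).all() and len(excl) > 0

    def test_absent_region_warns_and_skips(self, toy_barcodes, toy_meta):
        catalog = sx.build_catalog(toy_barcodes, toy_meta)
        with pytest.warns(UserWarning, match="FP"):
            table = sx.region_enrichment(catalog, toy_meta, regions=["FP", "Hi"])
        assert set(table["region"]) == {"Hi"}


class TestSubjectSummary:
    def test_manual_tabulation(self, toy_barcodes, toy_meta):
        catalog = sx.build_catalog(toy_barcodes, toy_meta)
        summary = sx.subject_summary(catalog, toy_meta)
        # p1: barcodes (1,0) and (1,-1) -> 2 distinct, union {1,2}
        assert summary.loc["p1", "n_distinct_barcodes"] == 2
        assert summary.loc["p1", "active_process_union"] == "1,2"
        # p2: both samples null -> 1 distinct barcode, empty union
        assert summary.loc["p2", "n_distinct_barcodes"] == 1
        assert summary.loc["p2", "active_process_union"] == ""
        # p3: (1,0) and (-1,1) -> 2 distinct, union {1,2}
        assert summary.loc["p3", "n_distinct_barcodes"] == 2


class TestFrequencyMap:
    def test_frequencies_sum_to_one_per_group(self, toy_barcodes, toy_meta):
        catalog = sx.build_catalog(toy_barcodes, toy_meta)
        freq = sx.frequency_map(catalog)
        for g in ("definite", "non-demented", "probable", "possible"):
            assert freq[g].sum() == pytest.approx(1.0)

    def test_empty_group_is_nan_not_zero(self, toy_barcodes, toy_meta):
        meta = toy_meta.copy()
        meta.loc[meta["pathology"] == "possible", "pathology"] = "probable"
        catalog = sx.build_catalog(toy_barcodes, meta)
        freq = sx.frequency_map(catalog)
        assert freq["possible"].isna().all()

    def test_exclusive_barcode_nonzero_only_in_its_group(self):
        barcodes = pd.DataFrame(
            {"digit_1": [1, 0]}, index=pd.Index(["s0", "s1"], name="sample_id")
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["s0", "s1"],
                "subject_id": "p",
                "region": "Hi",
                "pathology": ["definite", "non-demented"],
            }
        ).set_index("sample_id", drop=False)
        catalog = sx.build_catalog(barcodes, meta)
        freq = sx.frequency_map(catalog)
        idx = catalog.assignment.loc["s0"]
        assert freq.loc[idx, "definite"] == 1.0
        assert freq.loc[idx, "non-demented"] == 0.0
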
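"""Container I/O and preprocessing filter behaviour."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from perturbmap.barcodes import default_design
from perturbmap.config import PipelineConfig
from perturbmap.data import (BarcodeDesign, CountMatrix, NoduleMap,
                             read_count_matrix, write_count_matrix)
from perturbmap.errors import (ConfigurationError, EmptyResultError,
                               FormatError)
from perturbmap.preprocess import (annotate_normal_spots, filter_spots,
                                   flag_low_signal_barcodes, split_features)

from conftest import make_counts, make_spots


class TestCountMatrixIO:
    def test_round_trip_identity(self, tmp_path):
        mat = np.array([[1, 0], [2, 3], [0, 5]])
        counts = make_counts(mat, spot_ids=[f"s1_s{i}" for i in range(3)])
        spots = make_spots(3, total_umi=mat.sum(axis=1))
        write_count_matrix(tmp_path / "d", counts, spots)
        counts2, spots2 = read_count_matrix(tmp_path / "d")
        np.testing.assert_array_equal(counts2.dense(), mat)
        assert list(counts2.feature_ids) == list(counts.feature_ids)
        assert list(spots2.spot_ids) == list(spots.spot_ids)
        np.testing.assert_array_equal(
            spots2.df["total_umi"], counts2.row_sums())

    def test_explicit_zero_entry_preserved(self, tmp_path):
        coo = sp.coo_matrix((np.array([4.0, 0.0]),
                             (np.array([0, 1]), np.array([0, 1]))),
                            shape=(2, 2))
        counts = CountMatrix(coo.tocsr(), pd.DataFrame({
            "feature_id": ["f0", "f1"], "feature_kind": "gene"}),
            np.array(["s1_s0", "s1_s1"]))
        spots = make_spots(2, total_umi=[4, 0])
        write_count_matrix(tmp_path / "d", counts, spots)
        counts2, _ = read_count_matrix(tmp_path / "d")
        np.testing.assert_array_equal(counts2.dense(), [[4, 0], [0, 0]])

    def test_row_sums_match_brute_force(self, tmp_path):
        rng = np.random.default_rng(0)
        mat = rng.integers(0, 5, (50, 20)) * (rng.random((50, 20)) < 0.3)
        counts = make_counts(mat, spot_ids=[f"s1_s{i}" for i in range(50)])
        spots = make_spots(50, total_umi=mat.sum(axis=1))
        write_count_matrix(tmp_path / "d", counts, spots)
        counts2, spots2 = read_count_matrix(tmp_path / "d")
        expected = [sum(int(mat[i, j]) for j in range(20)) for i in range(50)]
        np.testing.assert_array_equal(spots2.df["total_umi"], expected)

    def test_missing_file_named_in_error(self, tmp_path):
        (tmp_path / "d").mkdir()
        with pytest.raises(FormatError, match="matrix.mtx"):
            read_count_matrix(tmp_path / "d")

    def test_dimension_mismatch_rejected(self, tmp_path):
        counts = make_counts(np.eye(3, dtype=int),
                             spot_ids=[f"s1_s{i}" for i in range(3)])
        spots = make_spots(3, total_umi=[1, 1, 1])
        write_count_matrix(tmp_path / "d", counts, spots)
        # drop one feature row from the sidecar table
        feats = pd.read_csv(tmp_path / "d" / "features.tsv", sep="\t")
        feats.iloc[:2].to_csv(tmp_path / "d" / "features.tsv", sep="\t", index=False)
        with pytest.raises(FormatError, match="features"):
            read_count_matrix(tmp_path / "d")

    def test_non_integer_entries_rejected(self):
        with pytest.raises(FormatError, match="integer"):
            make_counts(np.array([[0.5]]))


class TestBarcodeDesign:
    def test_default_design_has_38_barcodes_over_8_plasmids(self):
        design = default_design()
        assert design.n_barcodes == 38
        assert design.n_plasmids == 8
        assert all(len(s) == 50 for s in design.sequences.values())

    def test_barcode_in_two_plasmids_rejected(self):
        tab = pd.DataFrame({
            "plasmid_id": ["p1", "p2"], "barcode_id": ["b1", "b1"]})
        with pytest.raises(FormatError):
            BarcodeDesign.from_table(tab)

    def test_csv_round_trip(self, tmp_path):
        design = default_design()
        design.to_csv(tmp_path / "design.csv")
        back = BarcodeDesign.from_csv(tmp_path / "design.csv")
        assert back.barcodes == design.barcodes
        assert back.plasmids == design.plasmids
        assert back.sequences == design.sequences


class TestSplitFeatures:
    def test_barcode_block_width_38(self):
        design = default_design()
        mat = np.ones((3, 40), dtype=int)
        features = pd.DataFrame({
            "feature_id": design.barcodes + ["geneA", "geneB"],
            "feature_kind": "gene"})
        counts = CountMatrix(sp.csr_matrix(mat), features)
        bc, genes = split_features(counts, design)
        assert bc.matrix.shape[1] == 38
        assert list(bc.feature_ids) == design.barcodes
        assert list(genes.feature_ids) == ["geneA", "geneB"]

    def test_no_genes_left_is_fine(self):
        design = default_design()
        counts = CountMatrix(
            sp.csr_matrix(np.ones((2, 38), dtype=int)),
            pd.DataFrame({"feature_id": design.barcodes}))
        bc, genes = split_features(counts, design)
        assert genes.matrix.shape[1] == 0

    def test_shuffled_feature_order_same_partition(self):
        design = default_design()
        rng = np.random.default_rng(1)
        all_feats = design.barcodes + ["geneA", "geneB"]
        order = rng.permutation(len(all_feats))
        mat = rng.integers(0, 4, (5, len(all_feats)))
        counts = CountMatrix(
            sp.csr_matrix(mat[:, order]),
            pd.DataFrame({"feature_id": [all_feats[i] for i in order]}))
        bc, genes = split_features(counts, design)
        assert list(bc.feature_ids) == design.barcodes  # design order restored
        assert set(genes.feature_ids) == {"geneA", "geneB"}

    def test_missing_barcode_lists_ids(self):
        design = default_design()
        counts = make_counts(np.ones((2, 3), dtype=int))
        with pytest.raises(ConfigurationError, match="Olfr103"):
            split_features(counts, design)


class TestFilterSpots:
    def test_umi_threshold_is_strict(self):
        spots = make_spots(2, total_umi=[5000, 5001])
        counts = make_counts(np.ones((2, 1), dtype=int))
        c2, s2 = filter_spots(counts, spots, PipelineConfig())
        assert list(s2.spot_ids) == ["s1_s1"]

    def test_manual_platform_keeps_ring(self):
        spots = make_spots(100, platform="manual")
        counts = make_counts(np.ones((100, 1), dtype=int))
        _, s2 = filter_spots(counts, spots)
        assert len(s2) == 100

    def test_cytassist_ring_removes_36_of_100(self):
        spots = make_spots(100, platform="cytassist")
        counts = make_counts(np.ones((100, 1), dtype=int))
        _, s2 = filter_spots(counts, spots)
        # 10x10 grid: perimeter has 4*10 - 4 = 36 spots
        assert len(s2) == 64
        assert s2.df["row"].min() == 1 and s2.df["row"].max() == 8
        assert s2.df["col"].min() == 1 and s2.df["col"].max() == 8

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        spots = make_spots(100, platform="cytassist",
                           total_umi=rng.integers(0, 12000, 100))
        counts = make_counts(np.ones((100, 1), dtype=int))
        c1, s1 = filter_spots(counts, spots)
        c2, s2 = filter_spots(c1, s1)
        assert list(s1.spot_ids) == list(s2.spot_ids)
        np.testing.assert_array_equal(c1.dense(), c2.dense())

    def test_all_removed_reports_counts(self):
        spots = make_spots(4, total_umi=[1, 2, 3, 4])
        counts = make_counts(np.ones((4, 1), dtype=int))
        with pytest.raises(EmptyResultError, match="4"):
            filter_spots(counts, spots)


class TestLowSignalBarcodes:
    def test_all_zero_barcode_flagged(self):
        spots = make_spots(10, total_umi=np.full(10, 10_000))
        counts = make_counts(np.zeros((10, 1), dtype=int), "barcode")
        flags = flag_low_signal_barcodes(counts, spots)
        assert not flags["keep"].iloc[0]

    def test_threshold_side(self):
        # 87/1000 spots with one count at total 1e4: mean log1p = 0.0603 >= 0.05
        n = 1000
        mat = np.zeros((n, 2), dtype=int)
        mat[:87, 0] = 1
        mat[:60, 1] = 1  # 0.0416 < 0.05 -> flagged
        spots = make_spots(n, total_umi=np.full(n, 10_000))
        flags = flag_low_signal_barcodes(make_counts(mat, "barcode"), spots)
        assert flags["keep"].tolist() == [True, False]

    def test_matches_direct_loop(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 6, (100, 5))
        totals = rng.integers(1000, 20_000, 100)
        spots = make_spots(100, total_umi=totals)
        flags = flag_low_signal_barcodes(make_counts(mat, "barcode"), spots)
        for b in range(5):
            vals = [np.log1p(mat[s, b] * 1e4 / totals[s]) for s in range(100)]
            expected = np.mean(vals)
            assert flags["mean_log1p_per_1e4"].iloc[b] == pytest.approx(expected)
            assert flags["keep"].iloc[b] == (expected >= 0.05)

    def test_zero_total_spot_excluded_with_warning(self):
        mat = np.zeros((3, 1), dtype=int)
        mat[0, 0] = 100
        spots = make_spots(3, total_umi=[1000, 0, 1000])
        with pytest.warns(UserWarning, match="zero-total"):
            flags = flag_low_signal_barcodes(make_counts(mat, "barcode"), spots)
        expected = np.mean([np.log1p(100 * 1e4 / 1000), 0.0])
        assert flags["mean_log1p_per_1e4"].iloc[0] == pytest.approx(expected)

    def test_spot_order_invariance(self):
        rng = np.random.default_rng(4)
        mat = rng.integers(0, 5, (60, 4))
        totals = rng.integers(1000, 9000, 60)
        spots = make_spots(60, total_umi=totals)
        f1 = flag_low_signal_barcodes(make_counts(mat, "barcode"), spots)
        order = rng.permutation(60)
        spots2 = make_spots(60, total_umi=totals[order])
        f2 = flag_low_signal_barcodes(make_counts(mat[order], "barcode"), spots2)
        np.testing.assert_allclose(f1["mean_log1p_per_1e4"], f2["mean_log1p_per_1e4"])


class TestAnnotateNormal:
    def _nodule_map_one_spot(self):
        return NoduleMap(pd.DataFrame({
            "spot_id": ["s1_s0"], "region_id": ["nod1"],
            "region_class": ["nodule"]}))

    def test_far_spot_becomes_normal(self):
        spots = make_spots(2, spacing=800.0, side=2)
        out = annotate_normal_spots(spots, self._nodule_map_one_spot(), 700.0)
        normal = out.df[out.df["region_class"] == "normal"]
        assert list(normal["spot_id"]) == ["s1_s1"]

    def test_near_spot_not_normal(self):
        spots = make_spots(2, spacing=100.0, side=2)
        with pytest.warns(UserWarning):
            out = annotate_normal_spots(spots, self._nodule_map_one_spot(), 250.0)
        assert "normal" not in set(out.df["region_class"])

    def test_matches_exhaustive_distance_check(self):
        rng = np.random.default_rng(5)
        n = 200
        xy = rng.uniform(0, 3000, (n, 2))
        spots = make_spots(n)
        spots.df["x"], spots.df["y"] = xy[:, 0], xy[:, 1]
        nodule_spots = list(range(20))
        nm = NoduleMap(pd.DataFrame({
            "spot_id": [f"s1_s{i}" for i in nodule_spots],
            "region_id": "nod1", "region_class": "nodule"}))
        out = annotate_normal_spots(spots, nm, 500.0)
        got = set(out.df.loc[out.df["region_class"] == "normal", "spot_id"])
        expected = set()
        for i in range(20, n):
            d = min(np.hypot(*(xy[i] - xy[j])) for j in nodule_spots)
            if d >= 500.0:
                expected.add(f"s1_s{i}")
        assert got == expected

    def test_min_distance_range_enforced(self):
        spots = make_spots(4)
        with pytest.raises(ConfigurationError):
            annotate_normal_spots(spots, self._nodule_map_one_spot(), 100.0)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_filter_spots_idempotent_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(9, 60))
    platform = "cytassist" if rng.random() < 0.5 else "manual"
    spots = make_spots(n, platform=platform,
                       total_umi=rng.integers(0, 12_000, n))
    counts = make_counts(np.ones((n, 1), dtype=int))
    try:
        c1, s1 = filter_spots(counts, spots)
    except EmptyResultError:
        return
    c2, s2 = filter_spots(c1, s1)
    assert list(s1.spot_ids) == list(s2.spot_ids)
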
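"""Dice, global matching, confusion matrices and region statistics."""
import numpy as np
import pytest

from popatlas.evalseg import (
    confusion_matrix,
    dice,
    evaluate,
    global_index,
    merge_bilateral,
    merge_bilateral_table,
    region_statistics,
)
from popatlas.synthpop import (
    REGION_STATS,
    SynthParams,
    default_region_table,
    make_phantom,
)
from popatlas.volio import LabelMap, RegionTable, Volume


class TestDice:
    def test_identical_region_is_one(self, random_labelmap_factory):
        lm = random_labelmap_factory(0)
        assert dice(lm, lm, 1) == 1.0

    def test_disjoint_regions_zero(self, tiny_regions):
        a = np.zeros((4, 4, 4), np.int32)
        b = np.zeros((4, 4, 4), np.int32)
        a[:2] = 1
        b[2:] = 1
        assert dice(LabelMap(a, tiny_regions), LabelMap(b, tiny_regions), 1) == 0.0

    def test_partial_overlap_case(self, tiny_regions):
        # |A| = 4, |B| = 6, overlap 3 -> 2*3 / 10 = 0.6
        a = np.zeros((10, 1, 1), np.int32)
        b = np.zeros((10, 1, 1), np.int32)
        a[0:4] = 1
        b[1:7] = 1
        assert dice(LabelMap(a, tiny_regions), LabelMap(b, tiny_regions), 1) == 0.6

    def test_empty_in_both_is_one_empty_in_one_is_zero(self, tiny_regions):
        a = LabelMap(np.zeros((3, 3, 3), np.int32), tiny_regions)
        b = LabelMap(np.ones((3, 3, 3), np.int32), tiny_regions)
        assert dice(a, a, 5) == 1.0
        assert dice(a, b, 1) == 0.0

    def test_symmetric(self, random_labelmap_factory):
        a = random_labelmap_factory(1)
        b = random_labelmap_factory(2)
        for r in (1, 2, 3):
            assert dice(a, b, r) == dice(b, a, r)


class TestGlobalIndex:
    def test_identical_maps(self, random_labelmap_factory):
        lm = random_labelmap_factory(0)
        assert global_index(lm, lm) == 1.0

    def test_no_overlap_anywhere(self, tiny_regions):
        a = np.zeros((4, 4, 4), np.int32)
        b = np.zeros((4, 4, 4), np.int32)
        a[:2] = 1
        b[2:] = 2
        assert global_index(LabelMap(a, tiny_regions), LabelMap(b, tiny_regions)) == 0.0

    def test_matches_bruteforce_voxel_loop(self, random_labelmap_factory):
        a = random_labelmap_factory(4)
        b = random_labelmap_factory(5)
        inter = total = 0
        for x in np.ndindex(*a.shape):
            for r in a.regions.ids:
                ia = a.labels[x] == r
                ib = b.labels[x] == r
                inter += ia and ib
                total += int(ia) + int(ib)
        assert global_index(a, b) == pytest.approx(2 * inter / total)
        assert global_index(a, b) == global_index(b, a)

    def test_mean_variant_bounds_aggregated(self, random_labelmap_factory):
        a = random_labelmap_factory(6)
        b = random_labelmap_factory(7)
        per_region = [dice(a, b, int(r)) for r in a.regions.ids]
        agg = global_index(a, b)
        assert min(per_region) <= agg <= max(per_region)


class TestConfusion:
    def test_identity_is_diagonal(self, random_labelmap_factory):
        lm = random_labelmap_factory(0)
        C = confusion_matrix(lm, lm)
        present = [r for r in C.index if (lm.labels == r).sum() > 0]
        sub = C.loc[present, present].to_numpy()
        np.testing.assert_allclose(np.diag(sub), 100.0)
        np.testing.assert_allclose(sub - np.diag(np.diag(sub)), 0.0)

    def test_rows_sum_to_100(self, random_labelmap_factory):
        a = random_labelmap_factory(1)
        b = random_labelmap_factory(2)
        C = confusion_matrix(a, b)
        for r in C.index:
            n = (a.labels == r).sum()
            if n > 0:
                assert C.loc[r].sum() == pytest.approx(100.0, abs=1e-9)
            else:
                assert C.loc[r].sum() == 0.0

    def test_matches_naive_double_loop(self, random_labelmap_factory):
        a = random_labelmap_factory(3, shape=(8, 8, 8))
        b = random_labelmap_factory(4, shape=(8, 8, 8))
        C = confusion_matrix(a, b)
        for r in C.index:
            n_r = int((a.labels == r).sum())
            for s in C.columns:
                n_rs = int(((a.labels == r) & (b.labels == s)).sum())
                expected = 100.0 * n_rs / n_r if n_r else 0.0
                assert C.loc[r, s] == pytest.approx(expected)


class TestMergeBilateral:
    def test_full_catalogue_merges_60_to_35(self):
        rt = default_region_table()
        assert len(rt) == 60
        merged, mapping = merge_bilateral_table(rt)
        assert len(merged) == 35
        assert set(mapping) == set(int(i) for i in rt.ids)

    def test_midline_only_map_unchanged(self, tiny_regions):
        lm = LabelMap(np.ones((4, 4, 4), np.int32), tiny_regions)
        out = merge_bilateral(lm)
        np.testing.assert_array_equal(out.labels, lm.labels)
        assert len(out.regions) == len(tiny_regions)

    def test_voxels_conserved_and_sides_united(self):
        rt = default_region_table()
        rng = np.random.default_rng(0)
        labels = rng.choice(np.concatenate([[0], rt.ids]), size=(12, 12, 12)).astype(
            np.int32
        )
        lm = LabelMap(labels, rt)
        out = merge_bilateral(lm)
        assert (out.labels > 0).sum() == (lm.labels > 0).sum()
        # left and right of the same structure now share one id
        df = rt.table
        pair = df[df["name"] == "Thalamus"]["region_id"].tolist()
        assert len(pair) == 2
        merged_count = (out.labels == min(pair)).sum()
        assert merged_count == sum((lm.labels == p).sum() for p in pair)

    def test_unpaired_entry_warns(self):
        rt = RegionTable.from_rows(
            [(1, "lonely", "cortical", "left"), (2, "mid", "other", "midline")]
        )
        lm = LabelMap(np.zeros((3, 3, 3), np.int32), rt)
        with pytest.warns(UserWarning):
            out = merge_bilateral(lm)
        assert len(out.regions) == 2


class TestRegionStatistics:
    def test_constant_image_relative_intensity_one(self, phantom32):
        _, lab = phantom32
        vol = Volume(np.full(lab.shape, 5.0))
        stats = region_statistics(vol, lab, normalize=True)
        np.testing.assert_allclose(stats["mean_intensity"], 1.0)

    def test_volume_percentages(self, tiny_regions):
        labels = np.zeros((10, 10, 10), np.int32)
        labels.ravel()[:100] = 1
        labels.ravel()[100:1000] = 2
        lm = LabelMap(labels, tiny_regions)
        stats = region_statistics(Volume(np.ones((10, 10, 10))), lm)
        by_id = stats.set_index("region_id")
        assert by_id.loc[1, "volume_pct"] == pytest.approx(10.0)
        assert by_id.loc[2, "volume_pct"] == pytest.approx(90.0)

    def test_phantom_recovers_internal_capsule_contrast(self):
        # the generator encodes the white-matter internal capsule at a
        # relative T1 of 1.28; the statistics table should read it back
        p = SynthParams(seed=3)
        vol, lab = make_phantom(p)
        stats = region_statistics(vol, lab, normalize=True).set_index("name")
        got = stats.loc["Internal capsule", "mean_intensity"]
        expected = REGION_STATS["Internal capsule"][4]
        assert got == pytest.approx(expected, abs=0.02)
        got_th = stats.loc["Thalamus", "mean_intensity"]
        assert got_th == pytest.approx(REGION_STATS["Thalamus"][4], abs=0.02)

    def test_no_labeled_voxels_raises(self, tiny_regions):
        lm = LabelMap(np.zeros((3, 3, 3), np.int32), tiny_regions)
        with pytest.raises(ValueError):
            region_statistics(Volume(np.ones((3, 3, 3))), lm)


def test_report_round_trip(tmp_path, random_labelmap_factory):
    a = random_labelmap_factory(0)
    b = random_labelmap_factory(1)
    report = evaluate(a, b)
    report.save(tmp_path / "report.json", tmp_path / "confusion.tsv")
    import json

    obj = json.loads((tmp_path / "report.json").read_text())
    assert obj["global_index"] == pytest.approx(report.global_index)
    assert set(obj["per_region_dice"]) == {str(r) for r in a.regions.ids}
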
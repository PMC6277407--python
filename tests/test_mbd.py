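import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylstage.genome import GenomicInterval
from methylstage.mbd import (
    BinTrack,
    assemble_dmrs,
    classify_timing,
    cnv_correct,
    count_bins,
    coverage_depth_summary,
    mbd_dmps,
    mes_transform,
    read_bin_counts,
    tile_test,
    write_bin_counts,
)
from methylstage.records import DMRecord, EARLY_ONSET, GT_SPECIFIC, HYPER, HYPO

SIZES = {"chr1": 10_000}


def track_from_mes(mes, chrom_len=None, bin_size=200):
    """Build a BinTrack whose MES values are exactly `mes` (covered bins)."""
    mes = np.asarray(mes, dtype=float)
    chrom_len = chrom_len or len(mes) * bin_size
    t = BinTrack("t", bin_size, {"chr1": chrom_len}, {"chr1": np.ones(len(mes), dtype=np.int64)})
    t.mes = {"chr1": mes}
    return t


class TestCountBins:
    def test_plus_read_straddles_two_bins(self):
        t = count_bins([("chr1", 150, "+")], SIZES)
        assert t.raw["chr1"][0] == 1 and t.raw["chr1"][1] == 1
        assert t.raw["chr1"][2:].sum() == 0

    def test_footprint_within_one_bin(self):
        t = count_bins([("chr1", 200, "+")], SIZES)
        assert t.raw["chr1"][1] == 1
        assert t.raw["chr1"].sum() == 1

    def test_minus_read_extends_leftward(self):
        # 3'-most base at 350: footprint [151, 351) -> bins 0 and 1
        t = count_bins([("chr1", 350, "-")], SIZES)
        assert t.raw["chr1"][0] == 1 and t.raw["chr1"][1] == 1

    def test_empty_input_gives_zero_track(self):
        t = count_bins([], SIZES)
        assert t.total_n == 0
        assert t.raw["chr1"].sum() == 0

    def test_clipping_counted(self):
        t = count_bins([("chr1", 9_950, "+")], SIZES)
        assert t.n_clipped == 1
        assert t.raw["chr1"][-1] == 1


class TestMES:
    def test_worked_value(self):
        # n=20, bin 200 bp, total 1e6 reads, L=2e8 bp -> log2(20)
        t = BinTrack(
            "s", 200, {"chr1": 200_000_000},
            {"chr1": np.zeros(1_000_000, dtype=np.int64)},
        )
        t.raw["chr1"][0] = 20
        t.raw["chr1"][1:50_000] = 20  # 49,999 bins x 20 -> total exactly 1e6
        t.corrected = {"chr1": t.raw["chr1"].astype(float)}
        assert t.total_n == 1_000_000
        out = mes_transform(t)
        assert out.mes["chr1"][0] == pytest.approx(np.log2(20.0), abs=1e-9)

    def test_genome_average_density_is_zero(self):
        t = BinTrack("s", 200, {"chr1": 2_000}, {"chr1": np.full(10, 7, dtype=np.int64)})
        out = mes_transform(t)
        assert np.allclose(out.mes["chr1"], 0.0)

    def test_uncovered_bins_get_nan_not_minus_inf(self):
        t = BinTrack("s", 200, {"chr1": 2_000}, {"chr1": np.array([0, 4] * 5)})
        out = mes_transform(t)
        assert np.isnan(out.mes["chr1"][0])
        assert np.isfinite(out.mes["chr1"][1])

    def test_empty_track_errors(self):
        t = BinTrack("s", 200, {"chr1": 2_000}, {})
        with pytest.raises(ValueError):
            mes_transform(t)

    @given(
        counts=st.lists(st.integers(0, 1000), min_size=5, max_size=50),
        factor=st.integers(2, 9),
    )
    @settings(deadline=None, max_examples=100)
    def test_invariant_under_uniform_scaling(self, counts, factor):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.sum() == 0:
            counts[0] = 1
        t1 = BinTrack("a", 200, {"chr1": len(counts) * 200}, {"chr1": counts})
        t2 = BinTrack("b", 200, {"chr1": len(counts) * 200}, {"chr1": counts * factor})
        m1, m2 = mes_transform(t1), mes_transform(t2)
        np.testing.assert_allclose(m1.mes["chr1"], m2.mes["chr1"], equal_nan=True)

    def test_monotone_in_count(self):
        counts = np.array([1, 2, 5, 10, 100], dtype=np.int64)
        t = mes_transform(BinTrack("a", 200, {"chr1": 1_000}, {"chr1": counts}))
        assert np.all(np.diff(t.mes["chr1"]) > 0)

    def test_pseudocount_mode_covers_everything(self):
        t = BinTrack("s", 200, {"chr1": 2_000}, {"chr1": np.array([0, 4] * 5)})
        out = mes_transform(t, pseudocount=1.0)
        assert np.isfinite(out.mes["chr1"]).all()


class TestCNVCorrect:
    def seg(self, start, end, cn):
        return (GenomicInterval("chr1", start, end), cn)

    def test_cn4_halves_counts(self):
        t = BinTrack("s", 200, SIZES, {"chr1": np.full(50, 40, dtype=np.int64)})
        out = cnv_correct(t, [self.seg(0, 2_000, 4)])
        assert np.allclose(out.corrected["chr1"][:10], 20.0)
        assert np.allclose(out.corrected["chr1"][10:], 40.0)

    def test_cn2_is_identity(self):
        t = BinTrack("s", 200, SIZES, {"chr1": np.arange(50, dtype=np.int64)})
        out = cnv_correct(t, [self.seg(0, 10_000, 2)])
        np.testing.assert_allclose(out.corrected["chr1"], t.raw["chr1"].astype(float))

    def test_cn1_doubles_counts(self):
        t = BinTrack("s", 200, SIZES, {"chr1": np.full(50, 15, dtype=np.int64)})
        out = cnv_correct(t, [self.seg(2_000, 4_000, 1)])
        assert np.allclose(out.corrected["chr1"][10:20], 30.0)

    def test_cn0_marks_uncovered(self):
        t = BinTrack("s", 200, SIZES, {"chr1": np.full(50, 15, dtype=np.int64)})
        out = cnv_correct(t, [self.seg(0, 1_000, 0)])
        assert np.isnan(out.corrected["chr1"][:5]).all()

    def test_overlapping_segments_error(self):
        t = BinTrack("s", 200, SIZES, {"chr1": np.ones(50, dtype=np.int64)})
        with pytest.raises(ValueError):
            cnv_correct(t, [self.seg(0, 2_000, 3), self.seg(1_000, 3_000, 1)])


class TestTileTest:
    def test_hand_computed_paired_t(self):
        # A and B differ by exactly 2.0 MES on average, sd of diffs 0.1
        a = track_from_mes([1.0, 1.2, 0.8, 1.1, 0.9])
        b = track_from_mes([3.0, 3.1, 2.9, 3.2, 2.8])
        res = tile_test(a, b)
        assert len(res) == 1
        row = res.iloc[0]
        diffs = np.array([2.0, 1.9, 2.1, 2.1, 1.9])
        t_hand = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert row["mean_mes_diff"] == pytest.approx(2.0)
        assert row["fold_change"] == pytest.approx(4.0)
        assert row["p_value"] < 0.01
        assert row["direction"] == HYPER
        assert t_hand > 40  # hand-checked scale of the statistic

    def test_identical_tracks_fold_one_no_direction(self):
        a = track_from_mes([1.0, 1.5, 0.5, 1.2, 0.9, 1.1])
        res = tile_test(a, a)
        assert (res["fold_change"] == 1.0).all()
        assert (res["direction"] == "none").all()

    def test_zero_variance_nonzero_mean_is_significant(self):
        a = track_from_mes([1.0] * 5)
        b = track_from_mes([2.5] * 5)
        res = tile_test(a, b)
        assert res.iloc[0]["p_value"] == 0.0
        assert res.iloc[0]["direction"] == HYPER

    def test_insufficient_covered_bins_skipped(self):
        a = track_from_mes([1.0, np.nan, np.nan, np.nan, 1.0])
        b = track_from_mes([2.0, np.nan, np.nan, np.nan, 2.0])
        res = tile_test(a, b)
        assert len(res) == 0

    def test_hypo_direction(self):
        a = track_from_mes([2.0, 2.1, 1.9, 2.0, 2.0])
        b = track_from_mes([0.5, 0.6, 0.4, 0.5, 0.5])
        res = tile_test(a, b)
        assert res.iloc[0]["direction"] == HYPO
        assert res.iloc[0]["fold_change"] < 0.5


def rec(start, end, direction=HYPER, comparison="GT", p=1e-4, fold=4.0):
    return DMRecord(
        region=GenomicInterval("chr1", start, end),
        platform="MBD",
        direction=direction,
        comparison=comparison,
        fold_change=fold,
        p_value=p,
    )


class TestAssembleDMRs:
    def tiles(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "start", "end", "k", "mean_mes_diff", "fold_change",
                     "p_value", "direction"],
        )

    def test_three_stepping_tiles_merge_to_one(self):
        rows = [("chr1", s, s + 1000, 5, 2.0, 4.0, 1e-4, HYPER) for s in (0, 200, 400)]
        dmrs = assemble_dmrs(self.tiles(rows))
        assert len(dmrs) == 1
        assert (dmrs[0].region.start, dmrs[0].region.end) == (0, 1400)

    def test_isolated_tile_is_one_dmr(self):
        dmrs = assemble_dmrs(self.tiles([("chr1", 0, 1000, 5, 2.0, 4.0, 1e-4, HYPER)]))
        assert len(dmrs) == 1
        assert dmrs[0].region.width == 1000

    def test_opposite_directions_never_merge(self):
        rows = [
            ("chr1", 0, 1000, 5, 2.0, 4.0, 1e-4, HYPER),
            ("chr1", 1000, 2000, 5, -2.0, 0.25, 1e-4, HYPO),
        ]
        dmrs = assemble_dmrs(self.tiles(rows))
        assert len(dmrs) == 2
        assert {d.direction for d in dmrs} == {HYPER, HYPO}

    def test_best_p_propagates(self):
        rows = [
            ("chr1", 0, 1000, 5, 2.0, 4.0, 1e-3, HYPER),
            ("chr1", 200, 1200, 5, 2.5, 5.7, 1e-6, HYPER),
        ]
        dmrs = assemble_dmrs(self.tiles(rows))
        assert dmrs[0].p_value == 1e-6
        assert dmrs[0].fold_change == 5.7

    def test_output_nonoverlapping_per_direction(self, default_results):
        by_key = {}
        for d in default_results["mbd"].gt_dmrs:
            by_key.setdefault((d.region.chrom, d.direction), []).append(d.region)
        for regions in by_key.values():
            regions.sort(key=lambda r: r.start)
            for a, b in zip(regions, regions[1:]):
                assert a.end < b.start  # merged: strictly separated


class TestTiming:
    def test_overlap_same_direction_is_early_onset(self):
        gt = [rec(0, 1000)]
        classify_timing(gt, [rec(500, 1500, comparison="IM")])
        assert gt[0].timing == EARLY_ONSET

    def test_opposite_direction_overlap_is_gt_specific(self):
        gt = [rec(0, 1000)]
        classify_timing(gt, [rec(500, 1500, direction=HYPO, comparison="IM")])
        assert gt[0].timing == GT_SPECIFIC

    def test_no_overlap_is_gt_specific(self):
        gt = [rec(0, 1000)]
        classify_timing(gt, [rec(5000, 6000, comparison="IM")])
        assert gt[0].timing == GT_SPECIFIC


class TestMbdDmps:
    def test_promoter_overlap_yields_dmp(self, tiny_annotation):
        dmrs = [rec(49_500, 50_500)]
        dmrs[0].timing = GT_SPECIFIC
        dmps = mbd_dmps(dmrs, tiny_annotation)
        assert len(dmps) == 1
        assert dmps[0].gene_id == "geneA"
        assert dmps[0].direction == HYPER

    def test_no_overlap_no_dmp(self, tiny_annotation):
        assert mbd_dmps([rec(0, 1000)], tiny_annotation) == []

    def test_largest_overlap_wins_direction(self, tiny_annotation):
        big = rec(49_000, 50_800)  # 1.8 kb of the promoter
        small = rec(50_900, 51_100, direction=HYPO)  # 0.1 kb
        dmps = mbd_dmps([big, small], tiny_annotation)
        assert dmps[0].direction == HYPER


class TestCoverageSummary:
    def test_fraction_arithmetic(self, tiny_annotation):
        counts = np.zeros(500, dtype=np.int64)
        counts[:350] = 3
        t = BinTrack("s", 200, {"chr1": 100_000}, {"chr1": counts})
        summary = coverage_depth_summary(t, tiny_annotation)
        whole = summary[summary["region_class"] == "whole_genome"].iloc[0]
        assert whole["covered_fraction"] == pytest.approx(0.7)
        assert whole["depth_1_5"] == 350

    def test_all_zero_track(self, tiny_annotation):
        t = BinTrack("s", 200, {"chr1": 100_000}, {})
        summary = coverage_depth_summary(t, tiny_annotation)
        assert (summary["covered_fraction"] == 0).all()

    def test_simulated_cgi_coverage_exceeds_intergenic(self, default_dataset):
        from methylstage.mbd import coverage_depth_summary as cds

        summary = cds(default_dataset.mbd_tracks["gm"], default_dataset.annotation)
        cgi = summary.set_index("region_class").loc["CGIs", "covered_fraction"]
        inter = summary.set_index("region_class").loc["intergenic", "covered_fraction"]
        assert cgi > inter


class TestBinCountIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        t = BinTrack(
            "s", 200, {"chr1": 10_000, "chr2": 4_000},
            {"chr1": rng.integers(0, 50, 50), "chr2": rng.integers(0, 50, 20)},
        )
        path = tmp_path / "bins.tsv"
        write_bin_counts(t, path)
        back = read_bin_counts(path, t.chrom_sizes)
        for chrom in t.chrom_sizes:
            np.testing.assert_array_equal(back.raw[chrom], t.raw[chrom])
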
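"""Focal-point placement: anchoring, bridging, terminal enrichment, assignment."""

import numpy as np
import pytest

import arraysmith as ars
from arraysmith.focal import number_focal_points
from helpers import SMALL_PANEL, make_record


def _map(chrom, pairs):
    return [ars.GeneticMapPoint(f"m{i}", chrom, cm, bp) for i, (cm, bp) in enumerate(pairs)]


PARAMS = ars.FocalPointParams()


class TestAnchoring:
    def test_linear_interpolation_between_map_ends(self):
        # 10 cM over 4.4 Mb -> one FP per cM, 440 kb apart
        points = _map("chr1", [(0, 10_000), (10, 4_410_000)])
        fps = ars.anchor_focal_points(points, PARAMS, {"chr1": 5_000_000})
        assert len(fps) == 11
        assert [fp.center for fp in fps] == [10_000 + i * 440_000 for i in range(11)]
        assert all(fp.origin == "anchored" for fp in fps)

    def test_interior_map_points_bend_the_interpolation(self):
        points = _map("chr1", [(0, 0), (1, 100_000), (2, 1_000_000)])
        fps = ars.anchor_focal_points(points, PARAMS, {"chr1": 2_000_000})
        assert [fp.center for fp in fps] == [1, 100_000, 1_000_000]

    def test_duplicate_cm_collapsed(self, caplog):
        points = _map("chr1", [(0, 1000), (0, 2000), (1, 500_000)])
        with caplog.at_level("WARNING"):
            fps = ars.anchor_focal_points(points, PARAMS, {"chr1": 1_000_000})
        assert "duplicate cM" in caplog.text
        assert [fp.center for fp in fps] == [1000, 500_000]

    def test_extrapolation_beyond_map_uses_constant_ratio(self):
        points = _map("chr1", [(1, 500_000), (2, 900_000)])
        fps = ars.anchor_focal_points(points, PARAMS, {"chr1": 3_000_000})
        # integer cM targets 0, 1, 2; cM 0 extrapolates 440 kb left of cM 1
        assert [fp.center for fp in fps] == [60_000, 500_000, 900_000]


class TestBridging:
    def test_gap_subdivided_at_thirds(self):
        fps = number_focal_points([
            ars.focal._make_fp("chr1", 100_000, "anchored", PARAMS, 2_000_000),
            ars.focal._make_fp("chr1", 1_100_000, "anchored", PARAMS, 2_000_000),
        ])
        out = ars.bridge_focal_points(fps, {"chr1": 1_200_000}, PARAMS)
        bridges = sorted(fp.center for fp in out if fp.origin == "bridge")
        # ceil(1,000,000 / 440,000) - 1 = 2 inserted, at thirds of the gap
        assert bridges == [433_333, 766_667]

    def test_exact_threshold_gap_not_bridged(self):
        fps = number_focal_points([
            ars.focal._make_fp("chr1", 50_000, "anchored", PARAMS, 500_000),
            ars.focal._make_fp("chr1", 450_000, "anchored", PARAMS, 500_000),
        ])
        out = ars.bridge_focal_points(fps, {"chr1": 500_000}, PARAMS)
        assert all(fp.origin == "anchored" for fp in out if fp.chrom == "chr1" and 50_000 <= fp.center <= 450_000)
        # start/end gaps are 50 kb, also below threshold
        assert len(out) == 2

    def test_unmapped_chromosome_tiled(self):
        out = ars.bridge_focal_points([], {"chrX": 2_000_000}, PARAMS)
        centers = [fp.center for fp in out]
        assert centers == list(range(5_000, 1_995_001, 440_000))

    def test_no_gap_exceeds_the_tiling_interval_after_bridging(self):
        rng = np.random.default_rng(13)
        for trial in range(10):
            length = int(rng.integers(200_000, 4_000_000))
            n_anchor = int(rng.integers(0, 5))
            anchors = number_focal_points([
                ars.focal._make_fp("c", int(p), "anchored", PARAMS, length)
                for p in rng.integers(5_000, max(6_000, length - 5_000), size=n_anchor)
            ])
            out = ars.bridge_focal_points(anchors, {"c": length}, PARAMS)
            centers = sorted(fp.center for fp in out)
            bound = max(PARAMS.bridge_gap, PARAMS.kb_per_cm)
            gaps = np.diff([0] + centers + [length])
            assert gaps.max() <= bound, f"trial {trial}: max gap {gaps.max()}"


class TestTerminalEnrichment:
    def test_ends_enriched_with_spaced_fps(self):
        out = ars.terminal_focal_points([], {"chr1": 1_000_000}, PARAMS)
        left = sorted(fp.center for fp in out if fp.center < 500_000)
        right = sorted(fp.center for fp in out if fp.center >= 500_000)
        assert left == [5_000, 15_000, 25_000, 35_000]
        assert right == [965_000, 975_000, 985_000, 995_000]

    def test_dense_end_gets_nothing_new(self):
        existing = number_focal_points([
            ars.focal._make_fp("chr1", c, "anchored", PARAMS, 1_000_000)
            for c in (5_000, 15_000, 25_000, 35_000)
        ])
        out = ars.terminal_focal_points(existing, {"chr1": 1_000_000}, PARAMS)
        left_new = [fp for fp in out if fp.origin == "terminal" and fp.center <= 40_000]
        assert left_new == []

    def test_short_chromosome_has_no_duplicate_centers(self):
        out = ars.terminal_focal_points([], {"mini": 30_000}, PARAMS)
        centers = [fp.center for fp in out]
        assert len(centers) == len(set(centers))
        assert all(1 <= fp.win_start <= fp.win_end <= 30_000 for fp in out)

    def test_fp_count_monotone_through_stages(self, dataset):
        lengths = dataset.chrom_lengths
        a = ars.anchor_focal_points(dataset.map_points, PARAMS, lengths)
        b = ars.bridge_focal_points(a, lengths, PARAMS)
        c = ars.terminal_focal_points(b, lengths, PARAMS)
        assert len(a) <= len(b) <= len(c)


class TestAssignment:
    def _fps(self):
        return number_focal_points([
            ars.focal._make_fp("chr01", 20_000, "anchored", PARAMS, 1_000_000),
            ars.focal._make_fp("chr01", 30_000, "anchored", PARAMS, 1_000_000),
        ])

    @pytest.mark.parametrize("pos,assigned", [(25_000, True), (15_000, True), (14_999, False)])
    def test_window_is_closed(self, pos, assigned):
        fps, outside = ars.assign_candidates(self._fps(), [make_record(SMALL_PANEL, chrom="chr01", pos=pos)])
        n = sum(len(fp.candidates) for fp in fps)
        assert (n == 1) == assigned
        assert (len(outside) == 0) == assigned

    def test_overlap_resolved_to_nearest_center_then_lower_id(self):
        fps = self._fps()
        # 24,000 is closer to 20,000's center
        got, _ = ars.assign_candidates(fps, [make_record(SMALL_PANEL, chrom="chr01", pos=24_000)])
        assert got[0].candidates and not got[1].candidates
        # 25,000 is equidistant: lower fp_id (the first) wins
        got, _ = ars.assign_candidates(fps, [make_record(SMALL_PANEL, chrom="chr01", pos=25_000)])
        assert got[0].candidates == ["chr01_25000"]

    def test_each_candidate_lands_in_at_most_one_fp(self, pipeline_result):
        seen = [sid for fp in pipeline_result.fps for sid in fp.candidates]
        assert len(seen) == len(set(seen))

    def test_windows_stay_inside_chromosomes(self, pipeline_result, dataset):
        for fp in pipeline_result.fps:
            assert 1 <= fp.win_start <= fp.win_end <= dataset.chrom_lengths[fp.chrom]


class TestSpacingStats:
    def test_even_tiling_reports_even_mean(self):
        fps = number_focal_points([
            ars.focal._make_fp("c", 5_000 + i * 440_000, "bridge", PARAMS, 2_000_000)
            for i in range(5)
        ])
        stats = ars.fp_spacing_stats(fps, {"c": 2_000_000})
        assert stats["mean_distance"] == 440_000
        assert stats["large_gaps"] == []

    def test_planted_large_gap_reported_once(self):
        fps = number_focal_points([
            ars.focal._make_fp("c", p, "bridge", PARAMS, 3_000_000)
            for p in (100_000, 300_000, 1_500_000)
        ])
        stats = ars.fp_spacing_stats(fps, {"c": 3_000_000})
        assert len(stats["large_gaps"]) == 1
        assert stats["large_gaps"][0]["length"] == 1_200_000

    def test_single_fp_chromosome_noted_and_excluded(self):
        fps = number_focal_points([
            ars.focal._make_fp("a", 100_000, "bridge", PARAMS, 500_000),
            ars.focal._make_fp("b", 100_000, "bridge", PARAMS, 500_000),
            ars.focal._make_fp("b", 200_000, "bridge", PARAMS, 500_000),
        ])
        stats = ars.fp_spacing_stats(fps, {"a": 500_000, "b": 500_000})
        assert stats["single_fp_chroms"] == ["a"]
        assert stats["mean_distance"] == 100_000
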
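"""AvaI clusters, low-GC centromere regions and distance-binned profiles."""

import numpy as np
import pytest

from chromofeat import (
    Assembly, AvaICluster, LowGCRegion, TandemArray, delineate_low_gc,
    distance_binned_profile, find_avai_clusters, gc_track,
    region_overlap_share,
)
from chromofeat.genomeio import WindowTrack
from conftest import random_dna


def _track(name, values, size=100_000):
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * size
    return WindowTrack(name, size, size, starts, starts + size, values)


class TestClusters:
    def test_single_array_single_cluster(self):
        arr = TandemArray("chr1", 100, 14_322, "AvaI", 26, 6.6, 0)
        (c,) = find_avai_clusters([arr])
        assert c.repeat_count == 26

    def test_isolated_singles_dropped(self):
        arrs = [TandemArray("chr1", 0, 547, "AvaI", 1, 0, 0),
                TandemArray("chr1", 500_000, 500_547, "AvaI", 1, 0, 0)]
        assert find_avai_clusters(arrs, min_repeats=3) == []

    def test_nearby_arrays_merge(self):
        arrs = [TandemArray("chr1", 0, 1094, "AvaI", 2, 0, 0),
                TandemArray("chr1", 50_000, 51_094, "AvaI", 2, 0, 0)]
        (c,) = find_avai_clusters(arrs, min_repeats=3, merge_gap=100_000)
        assert c.repeat_count == 4

    def test_planted_clusters_recovered(self, desk_genome):
        _, _, truth = desk_genome
        arrays = [
            TandemArray(n, int(g.start.min()), int(g.end.max()), "AvaI", len(g), 6.6, 0)
            for n, g in truth.repeats.query("family == 'AvaI'").groupby("name")
        ]
        clusters = find_avai_clusters(arrays)
        assert {(c.name, c.repeat_count) for c in clusters} == \
               {("chr1", 26), ("chr2", 11), ("chr3", 5)}


class TestLowGC:
    def test_uniform_genome_no_regions(self):
        tr = {"c": _track("c", [0.35] * 50)}
        assert delineate_low_gc(tr, 0.327) == []

    def test_two_blocks_split_by_high_window(self):
        vals = [0.35] * 5 + [0.25] * 3 + [0.35] + [0.25] * 2 + [0.35] * 5
        regions = delineate_low_gc({"c": _track("c", vals)}, 0.327)
        assert [(r.start, r.end) for r in regions] == \
               [(5 * 100_000, 8 * 100_000), (9 * 100_000, 11 * 100_000)]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            delineate_low_gc({"c": _track("c", [0.3])}, 1.5)

    def test_cluster_seeding_filters_unanchored_runs(self):
        vals = [0.35] * 5 + [0.25] * 3 + [0.35] * 5 + [0.25] * 2 + [0.35]
        clusters = [AvaICluster("c", 600_000, 620_000, 5)]
        seeded = delineate_low_gc({"c": _track("c", vals)}, 0.327, clusters)
        assert len(seeded) == 1 and seeded[0].cluster_ids == [0]
        unseeded = delineate_low_gc({"c": _track("c", vals)}, 0.327, clusters,
                                    seed_with_clusters=False)
        assert len(unseeded) == 2

    def test_planted_block_boundaries_within_one_window(self, desk_genome):
        asm, _, truth = desk_genome
        from chromofeat import assembly_gc
        regions = delineate_low_gc(gc_track(asm, 100_000), assembly_gc(asm))
        regions = [r for r in regions if r.name.startswith("chr")]
        assert len(regions) == len(truth.centromeres)
        for row in truth.centromeres.itertuples():
            (r,) = [x for x in regions if x.name == row.name]
            assert abs(r.start - row.start) <= 100_000
            assert abs(r.end - row.end) <= 100_000
            assert r.mean_gc < 0.25


class TestDistanceProfile:
    def test_constant_track_degenerate(self):
        anchors = [AvaICluster("c", 500_000, 520_000, 5)]
        tr = {"c": _track("c", [0.3] * 2000, size=1000)}
        prof = distance_binned_profile(anchors, tr, n_boot=200, seed=1)
        ok = ~np.isnan(prof.means)
        assert np.allclose(prof.means[ok], 0.3)
        assert np.allclose(prof.ci_lo[ok], 0.3) and np.allclose(prof.ci_hi[ok], 0.3)

    def test_gradient_monotone_in_bins(self):
        anchors = [AvaICluster("c", 0, 1000, 5)]
        n = 5000
        vals = 0.22 + 0.12 * np.arange(n) / n  # GC rising with distance
        prof = distance_binned_profile(anchors, {"c": _track("c", vals, size=1000)},
                                       n_boot=100, seed=1)
        m = prof.means[~np.isnan(prof.means)]
        assert np.all(np.diff(m) >= -1e-12)

    def test_bin_partition(self):
        anchors = [AvaICluster("c", 0, 1000, 5)]
        tr = {"c": _track("c", np.ones(3000), size=1000)}
        prof = distance_binned_profile(anchors, tr, n_boot=50, seed=0)
        assert prof.counts.sum() <= 3000
        assert prof.ci_lo[0] <= prof.means[0] <= prof.ci_hi[0]

    def test_reproducible_with_seed(self):
        anchors = [AvaICluster("c", 0, 1000, 5)]
        rng = np.random.default_rng(5)
        tr = {"c": _track("c", rng.random(2000), size=1000)}
        a = distance_binned_profile(anchors, tr, n_boot=300, seed=9)
        b = distance_binned_profile(anchors, tr, n_boot=300, seed=9)
        assert np.array_equal(a.ci_lo, b.ci_lo, equal_nan=True)
        assert np.array_equal(a.ci_hi, b.ci_hi, equal_nan=True)


class TestOverlapShare:
    def test_half_genome_full_overlap(self):
        regions = [LowGCRegion("c", 0, 500, 0.2, 5, [])]
        share = region_overlap_share(regions, [("c", 100, 200)], genome_bp=1000)
        assert share == (0.5, 1.0)

    def test_disjoint(self):
        regions = [LowGCRegion("c", 0, 100, 0.2, 1, [])]
        assert region_overlap_share(regions, [("c", 500, 600)], 1000)[1] == 0.0

    def test_matches_base_level_oracle(self, rng):
        genome = 10_000
        regions = []
        for _ in range(5):
            s = int(rng.integers(0, genome - 500))
            regions.append(LowGCRegion("c", s, s + int(rng.integers(50, 500)), 0.2, 1, []))
        ivs = []
        for _ in range(8):
            s = int(rng.integers(0, genome - 300))
            ivs.append(("c", s, s + int(rng.integers(20, 300))))
        got = region_overlap_share(regions, ivs, genome)
        in_region = np.zeros(genome, dtype=bool)
        for r in regions:
            in_region[r.start:r.end] = True
        in_iv = np.zeros(genome, dtype=bool)
        for _, s, e in ivs:
            in_iv[s:e] = True
        assert got[0] == pytest.approx(in_region.sum() / genome)
        assert got[1] == pytest.approx((in_region & in_iv).sum() / in_iv.sum())
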
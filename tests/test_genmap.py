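"""Marker placement, congruence classification and recombination-rate estimation."""

import itertools

import numpy as np
import pytest

from chromofeat import (
    Assembly, Marker, MarkerPlacement, classify_congruence,
    drop_zero_distance, locate_primers, mapping_percentages, place_markers,
    recombination_rate,
)
from chromofeat._seq import revcomp
from chromofeat.genmap import _lnds_indices
from conftest import random_dna


def _marker(i, lg, cm, pa, pb):
    return Marker(f"m{i}", lg, cm, pa, pb)


def _embed(rng, pieces):
    """Concatenate 1 kbp random spacers with the given sequence pieces."""
    out = []
    pos = {}
    cursor = 0
    for label, piece in pieces:
        spacer = random_dna(rng, 1000)
        out.append(spacer)
        cursor += 1000
        pos[label] = cursor
        out.append(piece)
        cursor += len(piece)
    out.append(random_dna(rng, 1000))
    return "".join(out), pos


class TestLocateAndPlace:
    def test_convergent_pair_placed(self, rng):
        pa, pb = random_dna(rng, 20), random_dna(rng, 20)
        seq = random_dna(rng, 1000) + pa + random_dna(rng, 110) + revcomp(pb) \
            + random_dna(rng, 1000)
        m = _marker(1, "chr", 0.0, pa, pb)
        placements, _ = place_markers(locate_primers(Assembly({"chr": seq}), [m]))
        (p,) = placements
        assert p.status == "placed"
        assert p.span == 150
        assert p.position == 1000 + 150 // 2

    def test_distant_pair_ambiguous(self, rng):
        pa, pb = random_dna(rng, 20), random_dna(rng, 20)
        seq, _ = _embed(rng, [("a", pa), ("gap", random_dna(rng, 1500)), ("b", revcomp(pb))])
        placements, _ = place_markers(
            locate_primers(Assembly({"chr": seq}), [_marker(1, "chr", 0.0, pa, pb)]))
        assert placements[0].status == "ambiguous_distant"

    def test_absent_primers_unmapped(self, rng):
        seq = random_dna(rng, 5000)
        m = _marker(1, "chr", 0.0, "ACGT" * 5, "TGCA" * 5)
        hits = locate_primers(Assembly({"chr": seq}), [m])
        if not hits[0].hits_a and not hits[0].hits_b:
            placements, summary = place_markers(hits)
            assert placements[0].status == "unmapped"
            assert summary["pct_markers_positioned"] == 0.0

    def test_single_primer_still_positions(self, rng):
        pa = random_dna(rng, 20)
        seq, pos = _embed(rng, [("a", pa)])
        m = _marker(1, "chr", 0.0, pa, "GGGGCCCCAAAATTTTGGCC")
        placements, summary = place_markers(locate_primers(Assembly({"chr": seq}), [m]))
        assert placements[0].status == "placed"
        assert summary["pct_markers_unmapped"] == 100.0  # one primer missing

    def test_planted_markers_recovered_at_truth(self, desk_genome):
        asm, markers, truth = desk_genome
        sub = [m for m in markers if m.linkage_group == "chr1"][:40]
        placements, _ = place_markers(locate_primers(asm, sub))
        tm = truth.markers.set_index("id")
        for p in placements:
            assert p.status == "placed"
            assert p.position == tm.loc[p.marker_id, "position"]


class TestMappingPercentages:
    def test_reported_counts(self):
        # 4016 primers / 301 unmapped; 2008 markers / 268 affected; 1975 positioned
        pct = mapping_percentages(4016, 301, 2008, 268, 1975)
        assert round(pct["pct_primers_unmapped"], 1) == 7.5
        assert round(pct["pct_markers_unmapped"], 1) == 13.3
        assert round(pct["pct_markers_positioned"], 1) == 98.4


def brute_force_max_collinear(cms):
    """Largest subset of physically ordered markers with non-decreasing cM."""
    best = 0
    for r in range(len(cms), 0, -1):
        for combo in itertools.combinations(range(len(cms)), r):
            vals = [cms[i] for i in combo]
            if all(a <= b for a, b in zip(vals, vals[1:])):
                return r
    return best


class TestCongruence:
    def _setup(self, cms):
        markers = [_marker(i, "chr", cm, "A" * 20, "C" * 20) for i, cm in enumerate(cms)]
        placements = [
            MarkerPlacement(f"m{i}", "chr", 1000 * (i + 1), 60, "placed")
            for i in range(len(cms))
        ]
        return placements, markers

    def test_collinear_all_congruent(self):
        placements, markers = self._setup([0, 1, 2, 3, 4])
        rep = classify_congruence(placements, markers)
        assert len(rep.congruent_ids) == 5 and not rep.incongruent_ids

    def test_adjacent_swap_one_incongruent(self):
        placements, markers = self._setup([0, 2, 1, 3, 4])
        rep = classify_congruence(placements, markers)
        assert len(rep.congruent_ids) == 4 and len(rep.incongruent_ids) == 1

    def test_counts_partition(self):
        placements, markers = self._setup([3, 0, 2, 5, 1, 4])
        rep = classify_congruence(placements, markers)
        row = rep.per_chromosome.iloc[0]
        assert row.congruent + row.incongruent == row.positioned == 6

    def test_wrong_linkage_group_incongruent(self):
        markers = [_marker(0, "chr2", 0.0, "A" * 20, "C" * 20)]
        placements = [MarkerPlacement("m0", "chr1", 100, 60, "placed")]
        rep = classify_congruence(placements, markers)
        assert rep.incongruent_ids == {"m0"}

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 10))
            cms = [float(x) for x in rng.choice(np.arange(0, 20, 0.5), size=n)]
            placements, markers = self._setup(cms)
            rep = classify_congruence(placements, markers)
            assert len(rep.congruent_ids) == brute_force_max_collinear(cms)

    def test_lnds_helper_matches_oracle(self, rng):
        for _ in range(50):
            seq = [float(x) for x in rng.integers(0, 8, size=int(rng.integers(1, 10)))]
            assert len(_lnds_indices(seq)) == brute_force_max_collinear(seq)


class TestDropZeroDistance:
    def test_example(self):
        ms = [_marker(i, "lg1", cm, "A" * 20, "C" * 20)
              for i, cm in enumerate([0.0, 1.2, 1.2, 3.0])]
        kept = drop_zero_distance(ms)
        assert [m.cm for m in kept] == [0.0, 1.2, 3.0]
        assert kept[1].id == "m1"  # first of the run is kept

    def test_strictly_increasing_unchanged(self):
        ms = [_marker(i, "lg1", float(i), "A" * 20, "C" * 20) for i in range(5)]
        assert drop_zero_distance(ms) == ms

    def test_planted_duplicates_removed(self):
        from chromofeat.synth import SimulationConfig, simulate_genome
        cfg = SimulationConfig(n_chromosomes=1, chromosome_length=1_500_000,
                               centromere_length=500_000, avai_copies=(5,),
                               alui_copies=(0,), telomere_mean_copies=300,
                               n_unplaced=0, n_zero_distance=7)
        _, markers, _ = simulate_genome(cfg, seed=3)
        assert len(markers) - len(drop_zero_distance(markers)) == 7


class TestRecombinationRate:
    def _uniform(self, n=11, spacing=100_000, d_cm=1.0):
        markers = [_marker(i, "chr", i * d_cm, "A" * 20, "C" * 20) for i in range(n)]
        placements = [MarkerPlacement(f"m{i}", "chr", i * spacing, 60, "placed")
                      for i in range(n)]
        return placements, markers

    def test_exact_uniform_rate(self):
        placements, markers = self._uniform()
        est = recombination_rate(placements, markers, n_boot=200, seed=1)
        assert est.rate == pytest.approx(10.0)
        assert est.ci_lo == pytest.approx(10.0) and est.ci_hi == pytest.approx(10.0)

    def test_zero_cm_gives_zero(self):
        placements, markers = self._uniform(d_cm=0.0)
        est = recombination_rate(placements, markers, n_boot=100, seed=1)
        assert est.rate == 0.0

    def test_empty_scope_raises(self):
        placements, markers = self._uniform()
        with pytest.raises(ValueError, match="empty scope"):
            recombination_rate(placements, markers,
                               regions=[("nowhere", 0, 10)], n_boot=50, seed=1)

    def test_region_scope_uses_inside_pairs_only(self):
        placements, markers = self._uniform()
        est = recombination_rate(placements, markers,
                                 regions=[("chr", 0, 350_000)], n_boot=100, seed=1)
        assert est.n_pairs == 3

    def test_relabeling_invariance(self):
        placements, markers = self._uniform()
        relabeled_m = [Marker("x" + m.id, m.linkage_group, m.cm, m.primer_a, m.primer_b)
                       for m in markers]
        relabeled_p = [MarkerPlacement("x" + p.marker_id, p.chromosome, p.position,
                                       p.span, p.status) for p in placements]
        a = recombination_rate(placements, markers, n_boot=100, seed=2)
        b = recombination_rate(relabeled_p, relabeled_m, n_boot=100, seed=2)
        assert a.rate == b.rate
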
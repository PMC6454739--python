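"""RepeatMasker IO, canonical-repeat annotation, overlap resolution and arrays."""

import itertools

import numpy as np
import pytest

from chromofeat import (
    ALUI_CONSENSUS, AVAI_CONSENSUS, Assembly, RepeatHit, annotate_canonical,
    array_membership_quantile, compare_summaries, find_tandem_arrays,
    read_repeatmasker_out, resolve_overlaps, summarize_repeats,
    write_repeatmasker_out,
)
from conftest import random_dna


class TestRepeatMaskerIO:
    def test_single_line_fixture(self, tmp_path):
        p = tmp_path / "x.out"
        p.write_text("h1\nh2\n\n  239 10.5  0.0  0.0  chr1 101 647 (0) C AvaI AvaI 1 547 (0) 1\n")
        (hit,) = read_repeatmasker_out(p)
        assert (hit.name, hit.start, hit.end, hit.strand) == ("chr1", 100, 647, "-")
        assert hit.divergence == 10.5
        assert hit.family == "AvaI"

    def test_round_trip(self, tmp_path, rng):
        hits = [
            RepeatHit(f"chr{rng.integers(1, 4)}", int(s), int(s) + int(rng.integers(60, 600)),
                      "+" if rng.random() < 0.5 else "-", "AluI",
                      float(np.round(rng.uniform(0, 30), 1)))
            for s in rng.integers(0, 100_000, size=50)
        ]
        p = tmp_path / "x.out"
        write_repeatmasker_out(hits, p)
        back = read_repeatmasker_out(p)
        assert [(h.name, h.start, h.end, h.strand, h.divergence) for h in back] == \
               [(h.name, h.start, h.end, h.strand, h.divergence) for h in hits]

    def test_ori_dialect_headerless(self, tmp_path):
        p = tmp_path / "x.ori.out"
        p.write_text("100 5.0 0.0 0.0 chr2 1 176 (0) + AluI AluI 1 176 (0) 1\n")
        (hit,) = read_repeatmasker_out(p, dialect="ori")
        assert (hit.start, hit.end, hit.strand) == (0, 176, "+")

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "x.out"
        p.write_text("h\nh\n\nnot a valid line\n")
        with pytest.raises(ValueError, match="line 4"):
            read_repeatmasker_out(p)


class TestAnnotateCanonical:
    def test_exact_copy_found_with_exact_boundaries(self, rng):
        seq = random_dna(rng, 3000) + AVAI_CONSENSUS + random_dna(rng, 3000)
        hits = annotate_canonical(Assembly({"c": seq}), AVAI_CONSENSUS, "AvaI")
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.divergence) == (3000, 3547, 0.0)

    def test_divergence_estimate_tracks_planted_rate(self, rng):
        copy = list(ALUI_CONSENSUS)
        planted = rng.choice(len(copy), size=int(0.05 * len(copy)), replace=False)
        for i in planted:
            copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
        seq = random_dna(rng, 2000) + "".join(copy) + random_dna(rng, 2000)
        (h,) = annotate_canonical(Assembly({"c": seq}), ALUI_CONSENSUS, "AluI")
        assert h.divergence == pytest.approx(100 * planted.size / len(copy), abs=1.5)

    def test_reverse_strand_copy(self, rng):
        from chromofeat._seq import revcomp
        seq = random_dna(rng, 1000) + revcomp(ALUI_CONSENSUS) + random_dna(rng, 1000)
        (h,) = annotate_canonical(Assembly({"c": seq}), ALUI_CONSENSUS, "AluI")
        assert (h.start, h.end, h.strand) == (1000, 1176, "-")

    def test_planted_tandem_copies_all_recovered(self, desk_genome):
        asm, _, truth = desk_genome
        sub = Assembly({"chr3": asm.records["chr3"]})
        hits = resolve_overlaps(annotate_canonical(sub, AVAI_CONSENSUS, "AvaI"))
        want = truth.repeats.query("name == 'chr3' and family == 'AvaI'")
        assert len(hits) == len(want)
        assert {h.start for h in hits} == set(want.start)


def max_weight_disjoint(hits):
    """Exhaustive maximum-weight disjoint subset (oracle, n <= 12)."""
    best = 0.0
    for r in range(len(hits) + 1):
        for combo in itertools.combinations(hits, r):
            ok = all(a.end <= b.start or b.end <= a.start
                     for a, b in itertools.combinations(combo, 2))
            if ok:
                best = max(best, sum(h.score for h in combo))
    return best


class TestResolveOverlaps:
    def test_higher_score_kept(self):
        a = RepeatHit("c", 0, 100, "+", "AvaI", 0.0)
        b = RepeatHit("c", 50, 130, "+", "AvaI", 20.0)
        assert resolve_overlaps([a, b]) == [a]

    def test_disjoint_unchanged(self):
        hits = [RepeatHit("c", i * 200, i * 200 + 100, "+", "AvaI", 0.0) for i in range(5)]
        assert resolve_overlaps(hits) == hits

    def test_disjointness_and_near_optimality(self, rng):
        # greedy-by-score is near-optimal on average but has no uniform
        # guarantee on dense random overlap structures; cases below 80% of
        # the exhaustive optimum are flagged and must stay rare
        ratios = []
        for _ in range(25):
            n = int(rng.integers(2, 12))
            hits = []
            for _ in range(n):
                s = int(rng.integers(0, 500))
                hits.append(RepeatHit("c", s, s + int(rng.integers(20, 200)), "+",
                                      "AvaI", float(rng.uniform(0, 30))))
            kept = resolve_overlaps(hits)
            for a, b in itertools.combinations(kept, 2):
                assert a.end <= b.start or b.end <= a.start
            greedy = sum(h.score for h in kept)
            ratios.append(greedy / max_weight_disjoint(hits))
        ratios = np.array(ratios)
        assert ratios.min() >= 0.5
        assert ratios.mean() >= 0.9
        assert (ratios < 0.8).mean() <= 0.2



class TestTandemArrays:
    def test_adjacent_copies_form_one_array(self):
        hits = [RepeatHit("c", i * 176, (i + 1) * 176, "+", "AluI", 0.0) for i in range(80)]
        (arr,) = find_tandem_arrays(hits)
        assert (arr.copy_count, arr.span) == (80, 14_080)

    def test_distant_copies_split(self):
        hits = [RepeatHit("c", 0, 176, "+", "AluI", 0.0),
                RepeatHit("c", 1176, 1352, "+", "AluI", 0.0)]
        assert len(find_tandem_arrays(hits, max_gap=50)) == 2

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(20):
            n_hits = int(rng.integers(1, 40))
            hits = []
            pos = 0
            for _ in range(n_hits):
                pos += int(rng.integers(0, 200))  # gap to previous hit
                hits.append(RepeatHit("c", pos, pos + 30, "+", "AluI", 0.0))
                pos += 30
            arrays = find_tandem_arrays(hits, max_gap=50)
            # O(n^2) oracle: two hits share an array iff chained by gaps <= 50
            n = len(hits)
            parent = list(range(n))
            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i
            for i in range(n):
                for j in range(n):
                    if i < j and hits[j].start - hits[i].end <= 50 and hits[j].start >= hits[i].end:
                        pi, pj = find(i), find(j)
                        parent[pj] = pi
            groups = len({find(i) for i in range(n)})
            assert len(arrays) == groups
            assert sum(a.copy_count for a in arrays) == n
            for a, b in zip(arrays, arrays[1:]):
                assert a.end <= b.start


class TestArrayQuantile:
    def test_single_array(self):
        from chromofeat import TandemArray
        arr = [TandemArray("c", 0, 100, "AluI", 10, 0.0, 0)]
        assert array_membership_quantile(arr, 0.5) == 10

    def test_mixed_sizes(self):
        from chromofeat import TandemArray
        arrs = [TandemArray("c", i, i + 1, "AluI", n, 0.0, 0)
                for i, n in enumerate([1, 1, 8])]
        assert array_membership_quantile(arrs, 0.5) == 8

    def test_q_one_gives_smallest(self):
        from chromofeat import TandemArray
        arrs = [TandemArray("c", i, i + 1, "AluI", n, 0.0, 0)
                for i, n in enumerate([3, 7, 21])]
        assert array_membership_quantile(arrs, 1.0) == 3

    def test_non_increasing_in_q(self, rng):
        from chromofeat import TandemArray
        arrs = [TandemArray("c", i, i + 1, "AluI", int(n), 0.0, 0)
                for i, n in enumerate(rng.integers(1, 50, size=30))]
        qs = [0.1, 0.3, 0.5, 0.7, 0.9, 1.0]
        vals = [array_membership_quantile(arrs, q) for q in qs]
        assert vals == sorted(vals, reverse=True)


class TestSummaries:
    def test_identical_sets_ratio_one(self, rng):
        asm = Assembly({"c": random_dna(rng, 10_000)})
        hits = [RepeatHit("c", 0, 100, "+", "AluI", 0.0),
                RepeatHit("c", 500, 700, "+", "DNA/mariner", 0.0)]
        s = summarize_repeats(hits, asm)
        assert compare_summaries(s, s) == {"AluI": (1.0, 1.0), "DNA/mariner": (1.0, 1.0)}

    def test_planted_bp_inflation(self, rng):
        asm = Assembly({"c": random_dna(rng, 10_000)})
        a = summarize_repeats([RepeatHit("c", 0, 100, "+", "AluI", 0.0)], asm)
        b = summarize_repeats([RepeatHit("c", 0, 200, "+", "AluI", 0.0)], asm)
        assert compare_summaries(a, b)["AluI"] == (1.0, 2.0)

    def test_overlaps_not_double_counted(self, rng):
        asm = Assembly({"c": random_dna(rng, 1000)})
        hits = [RepeatHit("c", 0, 100, "+", "AluI", 0.0),
                RepeatHit("c", 50, 150, "+", "AluI", 0.0)]
        s = summarize_repeats(hits, asm)
        assert s.families["AluI"][1] == 150
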
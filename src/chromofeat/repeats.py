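"""RepeatMasker parsing, internal tandem-repeat annotation and array statistics.

The centromeric AvaI (547 bp) and short-arm-telomeric AluI (176 bp)
repeats cluster into long tandem arrays; because the AvaI consensus is
internally sub-repetitive, masking tools emit overlapping annotations in
tandem context, so hits are reduced to a non-overlapping set before
arrays are built.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from ._seq import encode, kmer_hashes, revcomp
from .genomeio import Assembly


@dataclass
class RepeatHit:
    name: str          # sequence the hit lies on
    start: int         # 0-based half-open genome coordinates
    end: int
    strand: str        # "+" | "-"
    family: str        # AvaI, AluI, Simple_repeat, DNA/mariner, ...
    divergence: float  # percent divergence from the canonical element

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        return self.length * (1 - self.divergence / 100)


@dataclass
class TandemArray:
    name: str
    start: int
    end: int
    family: str
    copy_count: int
    mean_divergence: float
    max_gap: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class RepeatSummary:
    """Per-family hit counts and non-overlapping masked bp."""
    families: dict[str, tuple[int, int, float]]  # family -> (count, bp, pct)
    assembly_bp: int


def read_repeatmasker_out(path: str | Path, dialect: str = "standard") -> list[RepeatHit]:
    """Parse RepeatMasker .out output into repeat hits.

    ``dialect="standard"`` expects the usual 3-line header; ``"ori"``
    parses the headerless pre-ProcessRepeats ori.out layout (same column
    order).  1-based closed input coordinates become 0-based half-open;
    the complement flag "C" becomes strand "-".
    """
    if dialect not in ("standard", "ori"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[RepeatHit] = []
    skip = 3 if dialect == "standard" else 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= skip or not line.strip():
                continue
            f = line.split()
            try:
                div = float(f[1])
                name = f[4]
                start = int(f[5]) - 1
                end = int(f[6])
                strand = "-" if f[8] in ("C", "-") else "+"
                repname = f[9]
                family = f[10] if len(f) > 10 else repname
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed RepeatMasker line {lineno}: {line!r}") from exc
            fam = repname if repname in ("AvaI", "AluI") else family
            hits.append(RepeatHit(name, start, end, strand, fam, div))
    return hits


def write_repeatmasker_out(hits: list[RepeatHit], path: str | Path,
                           dialect: str = "standard") -> None:
    """Write hits in RepeatMasker .out column layout (round-trips with the reader)."""
    with open(path, "w") as fh:
        if dialect == "standard":
            fh.write("   SW   perc perc perc  queryphylum    position in query"
                     "     matching  repeat       position in repeat\n")
            fh.write("score   div. del. ins.  sequence       begin  end    (left)"
                     "   repeat    class/family   begin end (left)  ID\n\n")
        for i, h in enumerate(hits, 1):
            strand = "C" if h.strand == "-" else "+"
            fh.write(
                f"{int(h.score):6d} {h.divergence:5.1f}  0.0  0.0  {h.name} "
                f"{h.start + 1} {h.end} (0) {strand} {h.family} {h.family} "
                f"1 {h.length} (0) {i}\n"
            )


def annotate_canonical(
    assembly: Assembly,
    canonical: str,
    family: str,
    max_divergence: float = 0.30,
    min_length: int = 50,
    seed_len: int = 16,
) -> list[RepeatHit]:
    """Annotate copies of a canonical repeat by exact-seed + semi-global extension.

    Exact ``seed_len``-mers of the canonical (both strands) anchor candidate
    copy starts; each candidate is refined by a semi-global (infix) unit-cost
    alignment of the canonical against a padded genome window, and kept when
    divergence (edits / alignment columns) and matched length pass the
    thresholds.
    """
    if len(canonical) < 20:
        raise ValueError("canonical repeat must be at least 20 bp")
    hits: list[RepeatHit] = []
    L = len(canonical)
    tol = max(10, L // 4)
    pad = max(30, int(0.35 * L))
    for strand, query in (("+", canonical), ("-", revcomp(canonical))):
        seed_offsets: dict[int, list[int]] = {}
        qcodes = encode(query)
        qh, qv = kmer_hashes(qcodes, seed_len)
        for off in range(qh.size):
            if qv[off]:
                seed_offsets.setdefault(int(qh[off]), []).append(off)
        keys = np.fromiter(seed_offsets.keys(), dtype=np.uint64)
        for name, seq in assembly.records.items():
            codes = encode(seq)
            gh, gv = kmer_hashes(codes, seed_len)
            if gh.size == 0:
                continue
            cand = np.flatnonzero(np.isin(gh, keys) & gv)
            proj: list[int] = []
            for p in cand:
                for off in seed_offsets.get(int(gh[p]), ()):
                    if seq[p : p + seed_len] == query[off : off + seed_len]:
                        proj.append(int(p) - off)
            if not proj:
                continue
            proj.sort()
            # cluster projected starts within tol, one alignment per cluster
            clusters: list[list[int]] = [[proj[0]]]
            for p in proj[1:]:
                if p - clusters[-1][-1] <= tol:
                    clusters[-1].append(p)
                else:
                    clusters.append([p])
            seen: set[tuple[int, int]] = set()
            for cl in clusters:
                anchor = int(np.median(cl))
                w0 = max(0, anchor - pad)
                w1 = min(len(seq), anchor + L + pad)
                res = edlib.align(query, seq[w0:w1], mode="HW", task="locations")
                if res["editDistance"] < 0 or not res["locations"]:
                    continue
                # several co-optimal end positions may be reported; prefer the
                # span closest to the canonical length (stable copy boundaries
                # in tandem context)
                loc = min(res["locations"],
                          key=lambda lc: abs((lc[1] + 1 - lc[0]) - L))
                s, e = w0 + loc[0], w0 + loc[1] + 1
                cols = max(L, e - s)
                div = 100.0 * res["editDistance"] / cols
                if div <= 100 * max_divergence and (e - s) >= min_length and (s, e) not in seen:
                    seen.add((s, e))
                    hits.append(RepeatHit(name, s, e, strand, family, div))
    hits.sort(key=lambda h: (h.name, h.start, h.end))
    # trim residual micro-overlaps between adjacent copies (alignment end
    # ambiguity in tandem context); genuine overlapping annotations are the
    # business of resolve_overlaps
    for a, b in zip(hits, hits[1:]):
        if a.name == b.name and 0 < a.end - b.start <= 8:
            a.end = b.start
    return hits


def resolve_overlaps(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Greedy non-overlapping subset by descending score (length x identity).

    Ties break toward the leftmost start; retained hits are pairwise
    disjoint per sequence.
    """
    kept: list[RepeatHit] = []
    by_seq: dict[str, list[tuple[int, int]]] = {}
    order = sorted(hits, key=lambda h: (-h.score, h.start, h.end))
    for h in order:
        ivs = by_seq.setdefault(h.name, [])
        if all(h.end <= s or h.start >= e for s, e in ivs):
            ivs.append((h.start, h.end))
            kept.append(h)
    return sorted(kept, key=lambda h: (h.name, h.start))


def find_tandem_arrays(hits: list[RepeatHit], max_gap: int = 50) -> list[TandemArray]:
    """Group non-overlapping same-family hits into tandem arrays.

    Hits on one sequence belong to the same array when consecutive copies
    are separated by at most ``max_gap`` bp; honeybee AvaI/AluI arrays are
    typically gap-free between copies.
    """
    arrays: list[TandemArray] = []
    groups: dict[tuple[str, str], list[RepeatHit]] = {}
    for h in hits:
        groups.setdefault((h.name, h.family), []).append(h)
    for (name, family), hs in groups.items():
        hs = sorted(hs, key=lambda h: h.start)
        run: list[RepeatHit] = []
        for h in hs + [None]:  # type: ignore[list-item]
            if run and (h is None or h.start - run[-1].end > max_gap):
                gaps = [b.start - a.end for a, b in zip(run, run[1:])]
                arrays.append(TandemArray(
                    name, run[0].start, run[-1].end, family, len(run),
                    float(np.mean([x.divergence for x in run])),
                    max(gaps) if gaps else 0,
                ))
                run = []
            if h is not None:
                run.append(h)
    return sorted(arrays, key=lambda a: (a.name, a.start))


def array_membership_quantile(arrays: list[TandemArray], q: float = 0.5) -> int:
    """Largest c such that >= q of all copies sit in arrays of >= c copies.

    The "half of all copies occur in arrays of at least c copies"
    statistic; non-increasing in q.
    """
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    if not arrays:
        raise ValueError("no arrays")
    sizes = np.sort(np.array([a.copy_count for a in arrays]))[::-1]
    total = sizes.sum()
    cum = np.cumsum(sizes)
    # scanning thresholds c downward over distinct sizes
    best = sizes.min()
    for c in np.unique(sizes)[::-1]:
        copies_in = sizes[sizes >= c].sum()
        if copies_in >= q * total:
            best = int(c)
            break
    return int(best)


def _merged_bp(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


def summarize_repeats(hits: list[RepeatHit], assembly: Assembly) -> RepeatSummary:
    """Per-family hit count, non-overlapping masked bp and % of assembly."""
    total_bp = assembly.total_length
    fams: dict[str, tuple[int, int, float]] = {}
    by_family: dict[str, dict[str, list[tuple[int, int]]]] = {}
    counts: dict[str, int] = {}
    for h in hits:
        by_family.setdefault(h.family, {}).setdefault(h.name, []).append((h.start, h.end))
        counts[h.family] = counts.get(h.family, 0) + 1
    for family, per_seq in by_family.items():
        bp = sum(_merged_bp(ivs) for ivs in per_seq.values())
        fams[family] = (counts[family], bp, 100.0 * bp / total_bp)
    return RepeatSummary(fams, total_bp)


def compare_summaries(a: RepeatSummary, b: RepeatSummary) -> dict[str, tuple[float, float]]:
    """Per-family (count ratio, bp ratio) of b relative to a."""
    out: dict[str, tuple[float, float]] = {}
    for family in sorted(set(a.families) | set(b.families)):
        ca, bpa, _ = a.families.get(family, (0, 0, 0.0))
        cb, bpb, _ = b.families.get(family, (0, 0, 0.0))
        out[family] = (
            cb / ca if ca else float("inf"),
            bpb / bpa if bpa else float("inf"),
        )
    return out
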
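"""Classification of whole-genome alignment blocks between two assemblies.

Alignment blocks (e.g. Satsuma output) between a query (older) and target
(newer) assembly are categorized by the placement status of the sequences
on both sides — same chromosome, newly anchored, switched chromosome,
anchor lost, unplaced in both — and the unaligned remainder of the target
is split by its placement status.  Per-category feature statistics
(mappability, GC, repeat densities) are computed over 1 kbp windows with
percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import percentile_ci
from .genomeio import WindowTrack

#: Fixed category order; ties in window assignment resolve to the earlier one.
CATEGORIES = (
    "same_chromosome",
    "new_anchor",
    "switched",
    "lost_anchor",
    "both_unplaced",
    "unaligned_anchored",
    "unaligned_unplaced",
)


@dataclass
class AlignmentBlock:
    query: str
    q_start: int
    q_end: int
    target: str
    t_start: int
    t_end: int
    orientation: str = "+"

    def __post_init__(self):
        if self.q_end <= self.q_start or self.t_end <= self.t_start:
            raise ValueError("block spans must be >= 1 bp")


@dataclass
class CategoryTotals:
    bp: dict[str, int]
    pct: dict[str, float]
    target_bp: int
    intervals: dict[str, dict[str, list[tuple[int, int]]]]  # category -> seq -> merged ivs


def read_blocks_tsv(path: str | Path) -> list[AlignmentBlock]:
    """Generic blocks TSV: query, q_start, q_end, target, t_start, t_end, orientation."""
    df = pd.read_csv(path, sep="\t")
    return [AlignmentBlock(r.query, int(r.q_start), int(r.q_end),
                           r.target, int(r.t_start), int(r.t_end),
                           getattr(r, "orientation", "+"))
            for r in df.itertuples()]


def read_satsuma_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Satsuma summary layout: target, t_start, t_end, query, q_start, q_end, score, orientation."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if len(f) < 8:
                continue
            blocks.append(AlignmentBlock(f[3], int(f[4]), int(f[5]),
                                         f[0], int(f[1]), int(f[2]), f[7]))
    return blocks


def write_blocks_tsv(blocks: list[AlignmentBlock], path: str | Path) -> None:
    pd.DataFrame(
        [(b.query, b.q_start, b.q_end, b.target, b.t_start, b.t_end, b.orientation)
         for b in blocks],
        columns=["query", "q_start", "q_end", "target", "t_start", "t_end", "orientation"],
    ).to_csv(path, sep="\t", index=False)


def read_placements_tsv(path: str | Path) -> dict[str, str | None]:
    df = pd.read_csv(path, sep="\t", names=["name", "chromosome"], header=0)
    out: dict[str, str | None] = {}
    for r in df.itertuples():
        chrom = None if str(r.chromosome).lower() in ("unplaced", "-", "nan", "none") else str(r.chromosome)
        out[str(r.name)] = chrom
    return out


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s > out[-1][1]:
            out.append([s, e])
        else:
            out[-1][1] = max(out[-1][1], e)
    return [(s, e) for s, e in out]


def _block_category(block: AlignmentBlock,
                    qp: dict[str, str | None],
                    tp: dict[str, str | None]) -> str:
    if block.query not in qp or block.target not in tp:
        missing = [s for s, m in ((block.query, qp), (block.target, tp)) if s not in m]
        raise ValueError(f"blocks reference sequences missing from placements: {missing}")
    qc, tc = qp[block.query], tp[block.target]
    if tc is not None and qc is not None:
        return "same_chromosome" if qc == tc else "switched"
    if tc is not None and qc is None:
        return "new_anchor"
    if tc is None and qc is not None:
        return "lost_anchor"
    return "both_unplaced"


def classify_blocks(
    blocks: list[AlignmentBlock],
    query_placements: dict[str, str | None],
    target_placements: dict[str, str | None],
    target_lengths: dict[str, int],
) -> tuple[list[str], CategoryTotals]:
    """Categorize blocks and account target bp per category, exactly once.

    Target coverage is merged per category before counting; overlaps
    between categories resolve to the earlier category in the fixed order.
    The unaligned remainder of the target is split by placement status, so
    category bp (including unaligned) sums exactly to the target size.
    """
    per_block = [_block_category(b, query_placements, target_placements) for b in blocks]
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {c: {} for c in CATEGORIES}
    for b, cat in zip(blocks, per_block):
        raw[cat].setdefault(b.target, []).append((b.t_start, b.t_end))
    # disjoint per-category coverage, priority = category order
    taken: dict[str, list[tuple[int, int]]] = {}
    intervals: dict[str, dict[str, list[tuple[int, int]]]] = {c: {} for c in CATEGORIES}
    bp = {c: 0 for c in CATEGORIES}
    for cat in CATEGORIES[:5]:
        for seq, ivs in raw[cat].items():
            merged = _merge(ivs)
            free = _subtract(merged, taken.get(seq, []))
            if free:
                intervals[cat][seq] = free
                bp[cat] += sum(e - s for s, e in free)
                taken[seq] = _merge(taken.get(seq, []) + free)
    for seq, length in target_lengths.items():
        gaps = _subtract([(0, length)], taken.get(seq, []))
        if not gaps:
            continue
        cat = "unaligned_anchored" if target_placements.get(seq) is not None else "unaligned_unplaced"
        intervals[cat].setdefault(seq, [])
        intervals[cat][seq] = _merge(intervals[cat][seq] + gaps)
        bp[cat] += sum(e - s for s, e in gaps)
    total = sum(target_lengths.values())
    pct = {c: 100.0 * bp[c] / total for c in CATEGORIES}
    return per_block, CategoryTotals(bp, pct, total, intervals)


def _subtract(ivs: list[tuple[int, int]], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Set difference of merged, sorted interval lists."""
    out = []
    for s, e in ivs:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def region_feature_stats(
    totals: CategoryTotals,
    tracks: dict[str, dict[str, WindowTrack]],
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-category means and bootstrap CIs of window tracks.

    ``tracks`` maps feature name -> per-sequence 1 kbp WindowTrack.  Each
    window goes to the category covering the majority of it (ties to the
    earlier category in the fixed order); per-category means get 95%
    percentile bootstrap CIs over windows.  Empty categories report NaN.
    """
    rng = np.random.default_rng(seed)
    rows = []
    # precompute per-sequence category interval lists
    for feature, per_seq in tracks.items():
        values: dict[str, list[np.ndarray]] = {c: [] for c in CATEGORIES}
        for seq, tr in per_seq.items():
            if len(tr) == 0:
                continue
            overlap = np.zeros((len(CATEGORIES), len(tr)))
            for ci, cat in enumerate(CATEGORIES):
                for s, e in totals.intervals[cat].get(seq, ()):  # merged
                    o = np.minimum(tr.ends, e) - np.maximum(tr.starts, s)
                    overlap[ci] += np.maximum(o, 0)
            best = np.argmax(overlap, axis=0)  # argmax takes first max: category order
            covered = overlap.max(axis=0) > 0
            ok = covered & ~np.isnan(tr.values)
            for ci, cat in enumerate(CATEGORIES):
                sel = ok & (best == ci)
                if sel.any():
                    values[cat].append(tr.values[sel])
        for cat in CATEGORIES:
            if values[cat]:
                vals = np.concatenate(values[cat])
                mean, lo, hi = percentile_ci(vals, n_boot=n_boot, rng=rng)
                rows.append((feature, cat, mean, lo, hi, vals.size))
            else:
                rows.append((feature, cat, np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["feature", "category", "mean", "ci_lo", "ci_hi", "n_windows"])
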
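"""Centromere delineation from AvaI clusters and low-GC windows.

Honeybee centromeres are operationally megabase-scale blocks of reduced
GC content containing clusters of the 547 bp AvaI tandem repeat.  The
delineation rule: maximal runs of consecutive 100 kbp windows whose GC
falls below a threshold (the assembly's own genome-wide GC by default),
seeded at windows containing an AvaI cluster when cluster seeding is on.
Feature profiles as a function of distance from clusters use percentile
bootstrap CIs over 1 kbp windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bootstrap import percentile_ci
from .genomeio import WindowTrack
from .repeats import TandemArray

#: Distance bins (bp) used for feature profiles around AvaI clusters.
DEFAULT_BINS: tuple[tuple[int, int], ...] = (
    (0, 20_000), (20_000, 40_000), (40_000, 80_000), (80_000, 160_000),
    (160_000, 320_000), (320_000, 640_000), (640_000, 1_280_000),
    (1_280_000, 2_560_000), (2_560_000, 5_120_000),
)


@dataclass
class AvaICluster:
    name: str
    start: int
    end: int
    repeat_count: int


@dataclass
class LowGCRegion:
    name: str
    start: int
    end: int
    mean_gc: float
    window_count: int
    cluster_ids: list[int]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DistanceBinProfile:
    bins: tuple[tuple[int, int], ...]
    means: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    counts: np.ndarray
    n_boot: int


def find_avai_clusters(
    arrays: list[TandemArray],
    min_repeats: int = 3,
    merge_gap: int = 100_000,
) -> list[AvaICluster]:
    """Merge tandem arrays within ``merge_gap`` into clusters; drop small ones.

    Cluster repeat count is the summed copy count of merged arrays; only
    clusters with at least ``min_repeats`` copies are reported.
    """
    clusters: list[AvaICluster] = []
    by_seq: dict[str, list[TandemArray]] = {}
    for a in arrays:
        by_seq.setdefault(a.name, []).append(a)
    for name, arrs in by_seq.items():
        arrs = sorted(arrs, key=lambda a: a.start)
        cur = [arrs[0]]
        for a in arrs[1:] + [None]:  # type: ignore[list-item]
            if a is None or a.start - cur[-1].end > merge_gap:
                count = sum(x.copy_count for x in cur)
                if count >= min_repeats:
                    clusters.append(AvaICluster(name, cur[0].start, cur[-1].end, count))
                cur = []
            if a is not None:
                cur.append(a)
    return sorted(clusters, key=lambda c: (c.name, c.start))


def delineate_low_gc(
    gc_tracks: dict[str, WindowTrack],
    threshold: float,
    clusters: list[AvaICluster] | None = None,
    seed_with_clusters: bool = True,
) -> list[LowGCRegion]:
    """Maximal runs of consecutive windows with GC below ``threshold``.

    With cluster seeding on (default), only runs overlapping an AvaI
    cluster are reported, so regions correspond to putative centromeres;
    without it all runs are reported (which also recovers low-GC blocks
    lacking a mapped cluster).
    """
    if not (0 < threshold < 1):
        raise ValueError("GC threshold must be in (0, 1)")
    regions: list[LowGCRegion] = []
    for name, tr in gc_tracks.items():
        below = np.asarray(tr.values < threshold) & ~np.isnan(tr.values)
        i = 0
        n = below.size
        while i < n:
            if not below[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            start, end = int(tr.starts[i]), int(tr.ends[j])
            ids = []
            if clusters is not None:
                ids = [k for k, c in enumerate(clusters)
                       if c.name == name and c.start < end and c.end > start]
            if not (seed_with_clusters and clusters is not None and not ids):
                vals = tr.values[i : j + 1]
                regions.append(LowGCRegion(name, start, end,
                                           float(np.nanmean(vals)), j - i + 1, ids))
            i = j + 1
    return regions


def distance_binned_profile(
    anchors: list[AvaICluster],
    tracks: dict[str, WindowTrack],
    bins: tuple[tuple[int, int], ...] = DEFAULT_BINS,
    n_boot: int = 2000,
    seed: int | None = None,
) -> DistanceBinProfile:
    """Mean track value per distance bin from the nearest anchor boundary.

    Each window (1 kbp in the published profiles) is assigned to the bin of
    the distance from its midpoint to the nearest anchor interval (0 inside
    an anchor); per-bin means get 95% percentile bootstrap CIs over
    windows.  Empty bins report NaN, not zero.
    """
    if not anchors:
        raise ValueError("no anchors")
    edges = [b[0] for b in bins] + [bins[-1][1]]
    if any(e1 >= e2 for e1, e2 in zip(edges, edges[1:])):
        raise ValueError("bins must be ascending and disjoint")
    rng = np.random.default_rng(seed)
    per_bin: list[list[np.ndarray]] = [[] for _ in bins]
    by_seq: dict[str, list[AvaICluster]] = {}
    for a in anchors:
        by_seq.setdefault(a.name, []).append(a)
    for name, tr in tracks.items():
        if name not in by_seq or len(tr) == 0:
            continue
        mid = (tr.starts + tr.ends) / 2
        dist = np.full(mid.size, np.inf)
        for a in by_seq[name]:
            d = np.maximum.reduce([a.start - mid, mid - a.end, np.zeros(mid.size)])
            dist = np.minimum(dist, d)
        ok = ~np.isnan(tr.values)
        for bi, (lo, hi) in enumerate(bins):
            sel = ok & (dist >= lo) & (dist < hi)
            if sel.any():
                per_bin[bi].append(tr.values[sel])
    means = np.full(len(bins), np.nan)
    los = np.full(len(bins), np.nan)
    his = np.full(len(bins), np.nan)
    counts = np.zeros(len(bins), dtype=int)
    for bi, parts in enumerate(per_bin):
        if not parts:
            continue
        vals = np.concatenate(parts)
        counts[bi] = vals.size
        means[bi], los[bi], his[bi] = percentile_ci(vals, n_boot=n_boot, rng=rng)
    return DistanceBinProfile(bins, means, los, his, counts, n_boot)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s > out[-1][1]:
            out.append([s, e])
        else:
            out[-1][1] = max(out[-1][1], e)
    return [(s, e) for s, e in out]


def region_overlap_share(
    regions: list[LowGCRegion],
    intervals: list[tuple[str, int, int]],
    genome_bp: int,
) -> tuple[float, float]:
    """(regions' share of the genome, share of ``intervals`` bp inside regions)."""
    reg_by_seq: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        reg_by_seq.setdefault(r.name, []).append((r.start, r.end))
    reg_by_seq = {k: _merge(v) for k, v in reg_by_seq.items()}
    reg_bp = sum(e - s for ivs in reg_by_seq.values() for s, e in ivs)
    iv_by_seq: dict[str, list[tuple[int, int]]] = {}
    for name, s, e in intervals:
        iv_by_seq.setdefault(name, []).append((s, e))
    iv_by_seq = {k: _merge(v) for k, v in iv_by_seq.items()}
    iv_bp = sum(e - s for ivs in iv_by_seq.values() for s, e in ivs)
    inter = 0
    for name, ivs in iv_by_seq.items():
        for s, e in ivs:
            for rs, re_ in reg_by_seq.get(name, ()):  # merged, sorted
                inter += max(0, min(e, re_) - max(s, rs))
    return (
        reg_bp / genome_bp if genome_bp else 0.0,
        inter / iv_bp if iv_bp else 0.0,
    )
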
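"""Genetic-map marker placement, congruence classification and recombination rates.

Microsatellite markers from a linkage map are located on the assembly by
exact search for their primer pairs; marker order along chromosomes is
compared with genetic (cM) order via a longest non-decreasing subsequence,
and recombination rates (cM/Mbp) are estimated from adjacent congruent
marker pairs with percentile-bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import find_patterns, revcomp
from .bootstrap import ratio_of_sums_ci
from .genomeio import Assembly


@dataclass
class Marker:
    id: str
    linkage_group: str
    cm: float
    primer_a: str
    primer_b: str

    def __post_init__(self):
        if self.cm < 0:
            raise ValueError(f"negative cM for marker {self.id}")
        for p in (self.primer_a, self.primer_b):
            if len(p) < 15 or any(c not in "ACGT" for c in p):
                raise ValueError(f"invalid primer for marker {self.id}: {p!r}")


@dataclass
class PrimerHit:
    name: str
    start: int
    strand: str
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class MarkerHits:
    marker: Marker
    hits_a: list[PrimerHit]
    hits_b: list[PrimerHit]


@dataclass
class MarkerPlacement:
    marker_id: str
    chromosome: str | None
    position: int | None       # midpoint of the primer-pair span
    span: int | None           # bp between outer primer ends
    status: str                # placed | unmapped | ambiguous_distant | ambiguous_overlap


@dataclass
class CongruenceReport:
    per_chromosome: pd.DataFrame      # positioned, congruent, incongruent columns
    congruent_ids: set[str]
    incongruent_ids: set[str]
    ambiguous_ids: set[str]
    interleaved_pairs: list[tuple[str, str]]

    @property
    def pct_congruent(self) -> float:
        pos = len(self.congruent_ids) + len(self.incongruent_ids)
        return 100.0 * len(self.congruent_ids) / pos if pos else float("nan")


@dataclass
class RecombinationEstimate:
    scope: str
    total_cm: float
    total_mbp: float
    rate: float
    n_pairs: int
    ci_lo: float
    ci_hi: float
    n_boot: int
    seed: int | None


def read_markers_tsv(path: str | Path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "linkage_group": str})
    return [Marker(r.id, r.linkage_group, float(r.cm), r.primer_a, r.primer_b)
            for r in df.itertuples()]


def write_markers_tsv(markers: list[Marker], path: str | Path) -> None:
    pd.DataFrame(
        [(m.id, m.linkage_group, m.cm, m.primer_a, m.primer_b) for m in markers],
        columns=["id", "linkage_group", "cm", "primer_a", "primer_b"],
    ).to_csv(path, sep="\t", index=False)


def locate_primers(assembly: Assembly, markers: list[Marker]) -> list[MarkerHits]:
    """Exact occurrences of every primer (both strands) across the assembly.

    A hit on the reverse strand is reported at its forward-strand start
    with strand "-"; a reverse-strand primer "points" leftward, so a
    convergent pair is (+ hit) upstream of (- hit).
    """
    patterns: set[str] = set()
    for m in markers:
        patterns |= {m.primer_a, m.primer_b, revcomp(m.primer_a), revcomp(m.primer_b)}
    pat_list = sorted(patterns)
    per_seq = {name: find_patterns(seq, pat_list) for name, seq in assembly.records.items()}

    def hits_for(primer: str) -> list[PrimerHit]:
        out = []
        for name in assembly.records:
            for p in per_seq[name][primer]:
                out.append(PrimerHit(name, int(p), "+", len(primer)))
            rc = revcomp(primer)
            if rc != primer:
                for p in per_seq[name][rc]:
                    out.append(PrimerHit(name, int(p), "-", len(primer)))
        return out

    return [MarkerHits(m, hits_for(m.primer_a), hits_for(m.primer_b)) for m in markers]


def _best_pair(hits_a: list[PrimerHit], hits_b: list[PrimerHit]) -> tuple[PrimerHit, PrimerHit] | None:
    """Minimal-span convergent pair on one chromosome, else None."""
    best = None
    for ha in hits_a:
        for hb in hits_b:
            if ha.name != hb.name or ha.strand == hb.strand:
                continue
            fwd, rev = (ha, hb) if ha.strand == "+" else (hb, ha)
            if fwd.start > rev.start:  # divergent orientation
                continue
            span = max(ha.end, hb.end) - min(ha.start, hb.start)
            if best is None or span < best[0]:
                best = (span, ha, hb)
    return (best[1], best[2]) if best else None


def place_markers(marker_hits: list[MarkerHits],
                  max_span: int = 1000) -> tuple[list[MarkerPlacement], dict[str, float]]:
    """Place markers from primer hits and summarize mapping percentages.

    A marker is placed at the midpoint of its minimal convergent primer-pair
    span; pairs separated by more than ``max_span`` are ``ambiguous_distant``
    and pairs whose primer intervals overlap are ``ambiguous_overlap``.  A
    marker with a single mapped primer is placed at that primer's midpoint;
    a marker with no mapped primer is ``unmapped``.
    """
    placements: list[MarkerPlacement] = []
    n_primers = n_primers_unmapped = 0
    n_markers_affected = 0
    for mh in marker_hits:
        n_primers += 2
        missing = (not mh.hits_a) + (not mh.hits_b)
        n_primers_unmapped += missing
        if missing:
            n_markers_affected += 1
        if missing == 2:
            placements.append(MarkerPlacement(mh.marker.id, None, None, None, "unmapped"))
            continue
        if missing == 1:
            h = (mh.hits_a or mh.hits_b)[0]
            placements.append(MarkerPlacement(mh.marker.id, h.name,
                                              (h.start + h.end) // 2, h.length, "placed"))
            continue
        pair = _best_pair(mh.hits_a, mh.hits_b)
        if pair is None:
            # hits exist but never convergent on one chromosome
            h = mh.hits_a[0]
            placements.append(MarkerPlacement(mh.marker.id, h.name,
                                              (h.start + h.end) // 2, h.length,
                                              "ambiguous_distant"))
            continue
        ha, hb = pair
        lo = min(ha.start, hb.start)
        hi = max(ha.end, hb.end)
        span = hi - lo
        pos = (lo + hi) // 2
        if ha.start < hb.end and hb.start < ha.end:
            status = "ambiguous_overlap"
        elif span > max_span:
            status = "ambiguous_distant"
        else:
            status = "placed"
        placements.append(MarkerPlacement(mh.marker.id, ha.name, pos, span, status))
    n = len(marker_hits)
    positioned = sum(p.status != "unmapped" for p in placements)
    summary = {
        "pct_primers_unmapped": 100.0 * n_primers_unmapped / n_primers if n_primers else 0.0,
        "pct_markers_unmapped": 100.0 * n_markers_affected / n if n else 0.0,
        "pct_markers_positioned": 100.0 * positioned / n if n else 0.0,
    }
    return placements, summary


def mapping_percentages(n_primers: int, n_primers_unmapped: int,
                        n_markers: int, n_markers_unmapped: int,
                        n_positioned: int) -> dict[str, float]:
    """Summary percentages straight from mapping counts (one-decimal scale)."""
    return {
        "pct_primers_unmapped": 100.0 * n_primers_unmapped / n_primers,
        "pct_markers_unmapped": 100.0 * n_markers_unmapped / n_markers,
        "pct_markers_positioned": 100.0 * n_positioned / n_markers,
    }


def _lnds_indices(ranks: list[float]) -> list[int]:
    """Indices of one longest non-decreasing subsequence (O(n^2) DP)."""
    n = len(ranks)
    if n == 0:
        return []
    best = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if ranks[j] <= ranks[i] and best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                prev[i] = j
    i = int(np.argmax(best))
    out = []
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def classify_congruence(
    placements: list[MarkerPlacement],
    markers: list[Marker],
    chromosome_of_group: dict[str, str] | None = None,
) -> CongruenceReport:
    """Classify positioned markers as congruent or incongruent with the map.

    Per chromosome, the congruent set is a longest subsequence of markers in
    physical order whose cM values are non-decreasing (ties either order);
    all other unambiguously positioned markers are incongruent.  A marker
    placed on a chromosome other than its linkage group is incongruent
    outright.  Ambiguous placements are excluded from both counts.
    Sequence pairs anchored to one chromosome whose marker cM intervals
    overlap are reported as interleaved/nested.
    """
    by_id = {m.id: m for m in markers}
    chrom_of = chromosome_of_group or {}
    ambiguous = {p.marker_id for p in placements if p.status.startswith("ambiguous")}
    placed = [p for p in placements if p.status == "placed"]
    congruent: set[str] = set()
    incongruent: set[str] = set()
    rows = []
    by_chrom: dict[str, list[MarkerPlacement]] = {}
    for p in placed:
        by_chrom.setdefault(p.chromosome, []).append(p)
    for chrom, ps in sorted(by_chrom.items()):
        ok, wrong = [], []
        for p in ps:
            lg = by_id[p.marker_id].linkage_group
            if chrom_of.get(lg, lg) == chrom:
                ok.append(p)
            else:
                wrong.append(p)
        incongruent |= {p.marker_id for p in wrong}
        ok.sort(key=lambda p: p.position)
        ranks = [by_id[p.marker_id].cm for p in ok]
        keep = set(_lnds_indices(ranks))
        for i, p in enumerate(ok):
            (congruent if i in keep else incongruent).add(p.marker_id)
        rows.append((chrom, len(ps), len(keep), len(ps) - len(keep)))
    per_chrom = pd.DataFrame(rows, columns=["chromosome", "positioned", "congruent", "incongruent"])
    # interleaved/nested sequence pairs: two records carrying markers of the
    # same linkage group whose marker cM intervals overlap
    interleaved: list[tuple[str, str]] = []
    spans: dict[tuple[str, str], tuple[float, float]] = {}
    for p in placed:
        m = by_id[p.marker_id]
        key = (m.linkage_group, p.chromosome)
        lo, hi = spans.get(key, (m.cm, m.cm))
        spans[key] = (min(lo, m.cm), max(hi, m.cm))
    by_lg: dict[str, list[tuple[str, float, float]]] = {}
    for (lg, rec), (lo, hi) in spans.items():
        by_lg.setdefault(lg, []).append((rec, lo, hi))
    for lg, recs in sorted(by_lg.items()):
        recs.sort(key=lambda t: t[1])
        for (ra, lo_a, hi_a), (rb, lo_b, hi_b) in zip(recs, recs[1:]):
            if ra != rb and lo_b < hi_a:
                interleaved.append((ra, rb))
    return CongruenceReport(per_chrom, congruent, incongruent, ambiguous, interleaved)


def drop_zero_distance(markers: list[Marker]) -> list[Marker]:
    """Remove markers at zero genetic distance to the previous marker.

    Markers must be sorted by (linkage group, cM); the first marker of each
    zero-distance run is kept.
    """
    out: list[Marker] = []
    for m in markers:
        if out and out[-1].linkage_group == m.linkage_group and out[-1].cm == m.cm:
            continue
        out.append(m)
    return out


def marker_pairs(
    placements: list[MarkerPlacement],
    markers: list[Marker],
    congruent_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Adjacent marker pairs (in cM order per chromosome) with cM and bp gaps."""
    by_id = {m.id: m for m in markers}
    rows = []
    by_chrom: dict[str, list[MarkerPlacement]] = {}
    for p in placements:
        if p.status != "placed":
            continue
        if congruent_ids is not None and p.marker_id not in congruent_ids:
            continue
        by_chrom.setdefault(p.chromosome, []).append(p)
    for chrom, ps in sorted(by_chrom.items()):
        ps.sort(key=lambda p: (by_id[p.marker_id].cm, p.position))
        for a, b in zip(ps, ps[1:]):
            rows.append((
                chrom, a.marker_id, b.marker_id,
                abs(by_id[b.marker_id].cm - by_id[a.marker_id].cm),
                abs(b.position - a.position),
                a.position, b.position,
            ))
    return pd.DataFrame(rows, columns=["chromosome", "id_a", "id_b",
                                       "d_cm", "d_bp", "pos_a", "pos_b"])


def recombination_rate(
    placements: list[MarkerPlacement],
    markers: list[Marker],
    regions: list[tuple[str, int, int]] | None = None,
    congruent_ids: set[str] | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
    method: str = "ratio_of_sums",
    scope_label: str | None = None,
) -> RecombinationEstimate:
    """Recombination rate (cM/Mbp) over adjacent congruent marker pairs.

    The rate is total cM / total Mbp over pairs (not the mean of per-pair
    ratios, which explodes for tiny physical gaps; ``method="mean_of_ratios"``
    exposes the alternative).  With ``regions`` given, a pair is in scope
    only when both markers lie inside a region.  The 95% CI comes from
    resampling pairs with replacement.
    """
    pairs = marker_pairs(placements, markers, congruent_ids)
    if regions is not None:
        def inside(chrom, pos):
            return any(c == chrom and s <= pos < e for c, s, e in regions)
        keep = [
            inside(r.chromosome, r.pos_a) and inside(r.chromosome, r.pos_b)
            for r in pairs.itertuples()
        ]
        pairs = pairs[np.array(keep, dtype=bool)] if len(pairs) else pairs
    if len(pairs) == 0:
        raise ValueError("empty scope: no marker pairs available")
    d_cm = pairs["d_cm"].to_numpy(dtype=float)
    d_mbp = pairs["d_bp"].to_numpy(dtype=float) / 1e6
    nz = d_mbp > 0
    d_cm, d_mbp = d_cm[nz], d_mbp[nz]
    if d_cm.size == 0:
        raise ValueError("empty scope: all pairs have zero physical distance")
    if method == "mean_of_ratios":
        ratios = d_cm / d_mbp
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, ratios.size, size=(n_boot, ratios.size))
        reps = ratios[idx].mean(axis=1)
        est = float(ratios.mean())
        lo, hi = (float(x) for x in np.quantile(reps, [0.025, 0.975]))
    else:
        est, lo, hi = ratio_of_sums_ci(d_cm, d_mbp, n_boot=n_boot,
                                       rng=np.random.default_rng(seed))
    return RecombinationEstimate(
        scope=scope_label or ("regions" if regions is not None else "genome"),
        total_cm=float(d_cm.sum()),
        total_mbp=float(d_mbp.sum()),
        rate=est,
        n_pairs=int(d_cm.size),
        ci_lo=lo,
        ci_hi=hi,
        n_boot=n_boot,
        seed=seed,
    )
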
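"""Short telomeric-motif scanning and distal telomere calling.

The honeybee telomeric repeat is the 5-mer TTAGG (CCTAA on the opposite
strand); inner telomeres are enriched for the variants TCAGG, CTGGG and
TTGGG, which largely co-occur in the higher-order repeat TCAGGCTGGG.
Densities are computed over non-overlapping windows (10 kbp by default)
and a distal telomere is called when terminal windows exceed a density
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, find_pattern, revcomp
from .genomeio import Assembly, WindowTrack, window_bounds


@dataclass(frozen=True)
class MotifSet:
    canonical: str = "TTAGG"
    variants: tuple[str, ...] = ("TCAGG", "CTGGG", "TTGGG")

    def __post_init__(self):
        for m in (self.canonical, *self.variants):
            if not m or any(c not in "ACGT" for c in m):
                raise ValueError(f"invalid motif {m!r}")


TELOMERIC = MotifSet()


@dataclass
class TelomereCall:
    name: str
    end: str  # "left" | "right"
    start: int
    stop: int
    count: int
    density: float
    enrichment: float


def count_motifs(sequence: str, motif: str, both_strands: bool = True) -> list[tuple[int, str]]:
    """Start offsets of exact motif occurrences, overlapping ones included.

    Reverse-complement occurrences are reported with strand "-" at their
    position on the forward sequence.
    """
    hits = [(int(p), "+") for p in find_pattern(sequence, motif)]
    rc = revcomp(motif)
    if both_strands and rc != motif:
        hits += [(int(p), "-") for p in find_pattern(sequence, rc)]
    return sorted(hits)


def motif_positions(sequence: str, motif: str, both_strands: bool = True,
                    codes: np.ndarray | None = None) -> np.ndarray:
    """Sorted start offsets of motif (and reverse complement) occurrences."""
    pos = find_pattern(sequence, motif, codes=codes)
    rc = revcomp(motif)
    if both_strands and rc != motif:
        pos = np.concatenate([pos, find_pattern(sequence, rc, codes=codes)])
    return np.sort(pos)


def motif_density_track(
    assembly: Assembly,
    motifset: MotifSet | str = TELOMERIC,
    window: int = 10_000,
    both_strands: bool = True,
) -> dict[str, WindowTrack]:
    """Per-window canonical-motif count and density tracks.

    Density is count * motif_length / actual window length; a motif
    spanning a window boundary is assigned to the window containing its
    start, which makes window counts additive.  The returned tracks carry
    counts in ``values`` and densities in ``densities``.
    """
    motif = motifset.canonical if isinstance(motifset, MotifSet) else motifset
    if window < len(motif):
        raise ValueError("window smaller than motif")
    tracks: dict[str, WindowTrack] = {}
    for name, seq in assembly.records.items():
        codes = encode(seq)
        pos = motif_positions(seq, motif, both_strands, codes=codes)
        starts, ends = window_bounds(len(seq), window)
        counts = np.zeros(starts.size, dtype=float)
        if pos.size:
            idx = np.minimum(pos // window, starts.size - 1)
            np.add.at(counts, idx, 1)
        tr = WindowTrack(name, window, window, starts, ends, counts)
        tr.densities = counts * len(motif) / (ends - starts)  # type: ignore[attr-defined]
        tracks[name] = tr
    return tracks


def call_telomeres(
    tracks: dict[str, WindowTrack],
    density_threshold: float = 0.10,
    terminal_windows: int = 2,
    motif_length: int = 5,
) -> list[TelomereCall]:
    """Call distal telomeres at sequence termini from a density track.

    A call is made at an end when any of the outermost ``terminal_windows``
    windows exceeds ``density_threshold``; the call interval extends inward
    over the maximal contiguous run of above-threshold windows.  Both ends
    are evaluated independently (metacentric chromosomes carry two distal
    telomeres).  Enrichment is the call's per-bp density over the mean
    density of all non-call windows across the track set.
    """
    if not (0 < density_threshold <= 1):
        raise ValueError("density threshold must be in (0, 1]")
    calls: list[TelomereCall] = []
    call_windows: dict[str, set[int]] = {}
    for name, tr in tracks.items():
        dens = getattr(tr, "densities", None)
        if dens is None:
            dens = tr.values * motif_length / np.maximum(tr.widths, 1)
        n = len(tr)
        if n == 0:
            continue
        used: set[int] = set()
        for end in ("left", "right"):
            order = range(n) if end == "left" else range(n - 1, -1, -1)
            order = list(order)
            trigger = None
            for i in order[:terminal_windows]:
                if dens[i] > density_threshold:
                    trigger = i
                    break
            if trigger is None:
                continue
            run = {trigger}
            j = trigger
            while j + 1 < n and dens[j + 1] > density_threshold:
                j += 1
                run.add(j)
            j = trigger
            while j - 1 >= 0 and dens[j - 1] > density_threshold:
                j -= 1
                run.add(j)
            if run & used:
                continue  # same run already claimed by the other end
            used |= run
            lo, hi = min(run), max(run)
            count = int(tr.values[lo : hi + 1].sum())
            span = int(tr.ends[hi] - tr.starts[lo])
            calls.append(TelomereCall(name, end, int(tr.starts[lo]), int(tr.ends[hi]),
                                      count, count * motif_length / span, 0.0))
        call_windows[name] = used
    # background density over non-call windows
    bg_count = bg_bp = 0.0
    for name, tr in tracks.items():
        mask = np.ones(len(tr), dtype=bool)
        for i in call_windows.get(name, ()):  # pragma: no branch
            mask[i] = False
        bg_count += float(tr.values[mask].sum())
        bg_bp += float(tr.widths[mask].sum())
    bg_density = bg_count * motif_length / bg_bp if bg_bp else 0.0
    for c in calls:
        c.enrichment = c.density / bg_density if bg_density > 0 else float("inf")
    return calls


def enrichment(call_density: float, background_density: float) -> float:
    """Fold enrichment of a call over the genomic background density."""
    if background_density <= 0:
        raise ValueError("undefined enrichment: background density is zero")
    return call_density / background_density


def screen_unplaced(
    tracks: dict[str, WindowTrack],
    placement: dict[str, str | None],
    min_count: int = 30,
) -> list[tuple[str, int]]:
    """Unplaced contigs with any window motif count above ``min_count``.

    Returns ``(contig, max window count)`` sorted by descending count.
    """
    out = []
    for name, tr in tracks.items():
        if placement.get(name) is not None or len(tr) == 0:
            continue
        mx = int(tr.values.max())
        if mx > min_count:
            out.append((name, mx))
    return sorted(out, key=lambda t: -t[1])


def hor_cooccurrence(
    sequence: str,
    variants: tuple[str, ...] = ("TCAGG", "CTGGG"),
    hor: str = "TCAGGCTGGG",
) -> float:
    """Fraction of variant-motif occurrences lying inside a higher-order repeat.

    Both strands are scanned; a variant occurrence counts as co-occurring
    when its span is contained in an occurrence of ``hor`` on the same
    strand.  NaN when no variant occurs at all.
    """
    for v in variants:
        if v not in hor:
            raise ValueError(f"variant {v!r} is not a substring of the HOR {hor!r}")
    total = inside = 0
    for strand_hor, strand_vars in ((hor, variants), (revcomp(hor), tuple(revcomp(v) for v in variants))):
        hor_pos = find_pattern(sequence, strand_hor)
        hstarts = np.asarray(hor_pos, dtype=np.int64)
        hends = hstarts + len(strand_hor)
        for v in strand_vars:
            for p in find_pattern(sequence, v):
                total += 1
                i = np.searchsorted(hstarts, p, side="right") - 1
                if i >= 0 and p + len(v) <= hends[i]:
                    inside += 1
    return inside / total if total else float("nan")
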
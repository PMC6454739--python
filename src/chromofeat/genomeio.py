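"""Sequence IO, window tiling, GC/mappability tracks and assembly statistics.

Coordinates are 0-based half-open throughout (BED semantics); 1-based
closed coordinates appear only in human-readable report strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._seq import encode, kmer_hashes

logger = logging.getLogger(__name__)

_NORMALIZE = str.maketrans(
    "acgtnRYSWKMBDHVryswkmbdhvU u", "ACGTNNNNNNNNNNNNNNNNNNNNNTNT"
)


@dataclass
class Assembly:
    """An ordered set of named DNA sequences with a placement table.

    ``placement`` maps each record name to the chromosome it is anchored
    to, or ``None`` for unplaced contigs.  By default every record is
    anchored to itself (chromosome-length records).
    """

    records: dict[str, str]
    placement: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self):
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for record {name!r}")
        if not self.placement:
            self.placement = {name: name for name in self.records}

    @property
    def names(self) -> list[str]:
        return list(self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.records.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def anchored_names(self) -> list[str]:
        return [n for n in self.records if self.placement.get(n) is not None]

    def unplaced_names(self) -> list[str]:
        return [n for n in self.records if self.placement.get(n) is None]


@dataclass
class WindowTrack:
    """Tiled per-window values on one sequence (0-based half-open)."""

    name: str
    size: int
    step: int
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return self.starts.size

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts


@dataclass
class IntervalRecord:
    name: str
    start: int
    end: int
    label: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    longest_bp: int
    mean_bp: float
    n50_bp: int
    l50: int


def read_fasta(path: str | Path, placement: dict[str, str | None] | None = None) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N (a warning with the substitution count is logged).  Duplicate
    record names and empty files are hard errors.
    """
    records: dict[str, str] = {}
    n_sub = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record name {rec.id!r} in {path}")
        raw = str(rec.seq)
        seq = raw.translate(_NORMALIZE)
        bad = sum(1 for a, b in zip(raw.upper(), seq) if a != b and a != "N")
        n_sub += bad
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_sub:
        logger.warning("%d ambiguous bases replaced by N while reading %s", n_sub, path)
    asm = Assembly(records, placement or {})
    asm.ambiguous_base_count = n_sub  # type: ignore[attr-defined]
    return asm


def write_fasta(assembly: Assembly, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gc_content(segment: str) -> float:
    """GC fraction of a segment; N excluded from numerator and denominator.

    Returns NaN when every base is N; raises on an empty segment.
    """
    if not segment:
        raise ValueError("empty segment")
    codes = encode(segment)
    acgt = int(np.count_nonzero(codes < 4))
    if acgt == 0:
        return float("nan")
    gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / acgt


def assembly_gc(assembly: Assembly) -> float:
    """Genome-wide GC fraction over all records (N-excluded)."""
    gc = acgt = 0
    for seq in assembly.records.values():
        codes = encode(seq)
        acgt += int(np.count_nonzero(codes < 4))
        gc += int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / acgt if acgt else float("nan")


def window_bounds(length: int, size: int, step: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Window start/end arrays tiling [0, length); the last window may be short."""
    if size < 1:
        raise ValueError("window size must be >= 1")
    step = size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > size:
        raise ValueError("step > size would leave gaps between windows")
    starts = np.arange(0, length, step, dtype=np.int64)
    # drop redundant trailing windows fully covered by the previous one
    starts = starts[starts < length]
    ends = np.minimum(starts + size, length)
    return starts, ends


def make_windows(assembly: Assembly, size: int, step: int | None = None,
                 stat=None) -> dict[str, WindowTrack]:
    """Tile every record into windows, optionally evaluating ``stat`` per window.

    ``stat`` is a callback ``f(segment: str) -> float`` evaluated on each
    window's sequence; when omitted, values are window widths.
    """
    tracks: dict[str, WindowTrack] = {}
    for name, seq in assembly.records.items():
        starts, ends = window_bounds(len(seq), size, step)
        if stat is None:
            values = (ends - starts).astype(float)
        else:
            values = np.array([stat(seq[s:e]) for s, e in zip(starts, ends)], dtype=float)
        tracks[name] = WindowTrack(name, size, size if step is None else step,
                                   starts, ends, values)
    return tracks


def gc_track(assembly: Assembly, size: int, step: int | None = None) -> dict[str, WindowTrack]:
    """Windowed GC fraction per record (vectorized; N-excluded per window)."""
    tracks: dict[str, WindowTrack] = {}
    for name, seq in assembly.records.items():
        starts, ends = window_bounds(len(seq), size, step)
        codes = encode(seq)
        isgc = ((codes == 1) | (codes == 2)).astype(np.int64)
        isacgt = (codes < 4).astype(np.int64)
        cgc = np.concatenate([[0], np.cumsum(isgc)])
        cab = np.concatenate([[0], np.cumsum(isacgt)])
        gc = cgc[ends] - cgc[starts]
        ab = cab[ends] - cab[starts]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(ab > 0, gc / np.maximum(ab, 1), np.nan)
        tracks[name] = WindowTrack(name, size, size if step is None else step,
                                   starts, ends, vals)
    return tracks


def mappability(assembly: Assembly, k: int = 50) -> dict[str, np.ndarray]:
    """Per-base mappability from exact k-mer uniqueness.

    Each k-mer start position scores 1 / (number of exact occurrences of
    the k-mer or its reverse complement anywhere in the assembly); a base's
    score is the mean over all k-mers overlapping it.  K-mers containing N
    score 0.  Sequences shorter than k yield empty tracks with a warning.
    """
    fwd: dict[str, np.ndarray] = {}
    rev: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    canon_parts = []
    for name, seq in assembly.records.items():
        codes = encode(seq)
        if codes.size < k:
            logger.warning("sequence %s shorter than k=%d; empty mappability track", name, k)
            continue
        hf, vf = kmer_hashes(codes, k)
        # reverse complement: complement codes (A<->T, C<->G), reverse, hash,
        # then re-reverse so index i corresponds to the k-mer starting at i
        comp = np.where(codes < 4, 3 - codes, codes)
        hr, _ = kmer_hashes(comp[::-1].copy(), k)
        hr = hr[::-1]
        fwd[name], rev[name], valid[name] = hf, hr, vf
        canon = np.minimum(hf, hr)[vf]
        canon_parts.append(canon)
    if not canon_parts:
        return {}
    allc = np.concatenate(canon_parts)
    uniq, counts = np.unique(allc, return_counts=True)
    out: dict[str, np.ndarray] = {}
    for name, seq in assembly.records.items():
        if name not in fwd:
            out[name] = np.empty(0, dtype=float)
            continue
        canon = np.minimum(fwd[name], rev[name])
        idx = np.searchsorted(uniq, canon)
        idx = np.clip(idx, 0, uniq.size - 1)
        cnt = counts[idx]
        scores = np.where(valid[name], 1.0 / cnt, 0.0)
        # mean over k-mers overlapping each base
        kernel = np.ones(k)
        num = np.convolve(scores, kernel)
        den = np.convolve(np.ones(scores.size), kernel)
        out[name] = num / den
    return out


def windowed_means(per_base: dict[str, np.ndarray], size: int) -> dict[str, WindowTrack]:
    """Windowed means of a per-base score track."""
    tracks = {}
    for name, vals in per_base.items():
        starts, ends = window_bounds(max(vals.size, 1), size)
        if vals.size == 0:
            tracks[name] = WindowTrack(name, size, size, np.empty(0, np.int64),
                                       np.empty(0, np.int64), np.empty(0))
            continue
        c = np.concatenate([[0.0], np.cumsum(vals)])
        means = (c[ends] - c[starts]) / (ends - starts)
        tracks[name] = WindowTrack(name, size, size, starts, ends, means)
    return tracks


def assembly_stats(lengths_or_assembly) -> AssemblyStats:
    """N50/L50 and basic size statistics.

    N50 is the length of the sequence at which the cumulative length of
    descending-sorted sequences first reaches half the total; L50 is its
    1-based rank.
    """
    if isinstance(lengths_or_assembly, Assembly):
        lengths = list(lengths_or_assembly.lengths.values())
    else:
        lengths = list(lengths_or_assembly)
    if not lengths:
        raise ValueError("need at least one sequence")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    # first index where cumulative length reaches >= total/2
    i = int(np.argmax(cum * 2 >= total))
    return AssemblyStats(
        n_sequences=arr.size,
        total_bp=total,
        longest_bp=int(arr[0]),
        mean_bp=total / arr.size,
        n50_bp=int(arr[i]),
        l50=i + 1,
    )


def write_bedgraph(tracks: dict[str, WindowTrack], path: str | Path) -> None:
    """4-column bedGraph (0-based half-open) of a window track set."""
    with open(path, "w") as fh:
        for name, tr in tracks.items():
            for s, e, v in zip(tr.starts, tr.ends, tr.values):
                fh.write(f"{name}\t{s}\t{e}\t{v:.6g}\n")


def write_bed(intervals: list[IntervalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.name}\t{iv.start}\t{iv.end}\t{iv.label}\t{iv.score:.6g}\t{iv.strand}\n")
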
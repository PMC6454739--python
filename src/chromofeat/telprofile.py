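"""Windowed profiling of aligned chromosome-end (subtelomere/telomere) sequences.

Given a multiple sequence alignment of distal chromosome ends, columns
where the chosen backbone row has a gap are removed, and divergence, GC,
motif densities and coverage depth are profiled across 100 bp backbone
windows with sequence-bootstrap confidence intervals.  The
subtelomere-telomere junction is detected from the combined density of
the canonical repeat and its variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import encode
from .motifscan import MotifSet, TELOMERIC, motif_positions

GAP_CODE = 250


class TelomereNotFoundError(ValueError):
    """Raised when no window run qualifies as a telomere."""


@dataclass
class Msa:
    names: list[str]
    rows: list[str]
    backbone: str

    def __post_init__(self):
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.backbone not in self.names:
            raise ValueError(f"backbone {self.backbone!r} not among rows")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)


def read_msa(path: str | Path, backbone: str) -> Msa:
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Msa(names, rows, backbone)


def write_msa(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(msa.names, msa.rows):
            fh.write(f">{name}\n{row}\n")


def mask_to_backbone(msa: Msa) -> Msa:
    """Remove every column where the backbone row has a gap.

    The result's width equals the backbone's ungapped length; idempotent.
    """
    bb = msa.rows[msa.names.index(msa.backbone)]
    keep = [i for i, c in enumerate(bb) if c != "-"]
    rows = ["".join(r[i] for i in keep) for r in msa.rows]
    return Msa(list(msa.names), rows, msa.backbone)


def _codes_matrix(msa: Msa) -> np.ndarray:
    mat = np.empty((msa.n_rows, msa.width), dtype=np.uint8)
    for i, row in enumerate(msa.rows):
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        c = encode(row)
        c = np.where(arr == ord("-"), np.uint8(GAP_CODE), c)
        mat[i] = c
    return mat


def _pair_divergence(mat: np.ndarray, min_frac: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(mismatches, comparable) per row pair for one window's code matrix.

    Columns where either row is a gap are skipped; a pair with fewer than
    ``min_frac`` of the window comparable is marked NaN.
    """
    n, w = mat.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    div = np.full(len(pairs), np.nan)
    for k, (i, j) in enumerate(pairs):
        a, b = mat[i], mat[j]
        comp = (a != GAP_CODE) & (b != GAP_CODE) & (a != 4) & (b != 4)
        nc = int(comp.sum())
        if nc >= min_frac * w and nc > 0:
            div[k] = float(((a != b) & comp).sum()) / nc
    return div, np.array([p for p in pairs], dtype=int)


def window_profile(
    msa: Msa,
    window: int = 100,
    n_boot: int = 2000,
    seed: int | None = None,
    motifs: MotifSet = TELOMERIC,
    depth_mode: str = "coverage",
) -> pd.DataFrame:
    """Per-window divergence, GC, motif densities and depth with bootstrap CIs.

    Mean pairwise divergence is mismatches / comparable columns over all
    row pairs (pair-gap columns excluded; a pair contributes only when at
    least half the window is comparable).  Motif densities are computed on
    gap-stripped per-row window text and averaged over rows.  Depth counts
    rows with >= 50% non-gap in the window (``depth_mode="span"`` instead
    counts rows whose first/last non-gap flanks the window).  95% CIs per
    window come from resampling rows with replacement.
    """
    if msa.width == 0:
        raise ValueError("empty alignment")
    rng = np.random.default_rng(seed)
    mat = _codes_matrix(msa)
    n = msa.n_rows
    starts = np.arange(0, msa.width, window)
    motif_names = (motifs.canonical, *motifs.variants)
    first_nz = np.array([min((i for i, c in enumerate(r) if c != "-"), default=len(r))
                         for r in msa.rows])
    last_nz = np.array([max((i for i, c in enumerate(r) if c != "-"), default=-1)
                        for r in msa.rows])
    rows_out = []
    for s in starts:
        e = min(s + window, msa.width)
        sub = mat[:, s:e]
        w = e - s
        nongap = (sub != GAP_CODE).sum(axis=1)
        if depth_mode == "span":
            depth = int(((first_nz <= s) & (last_nz >= e - 1)).sum())
        else:
            depth = int((nongap >= 0.5 * w).sum())
        # per-row GC and motif densities on gap-stripped text
        gc_row = np.full(n, np.nan)
        dens_row = {m: np.full(n, np.nan) for m in motif_names}
        for i in range(n):
            txt = msa.rows[i][s:e].replace("-", "")
            if not txt:
                continue
            codes = encode(txt)
            acgt = int((codes < 4).sum())
            if acgt:
                gc_row[i] = int(((codes == 1) | (codes == 2)).sum()) / acgt
            for m in motif_names:
                if len(txt) >= len(m):
                    cnt = motif_positions(txt, m, both_strands=True, codes=codes).size
                    dens_row[m][i] = cnt * len(m) / len(txt)
                else:
                    dens_row[m][i] = 0.0
        div_pair, pair_idx = _pair_divergence(sub)
        divergence = float(np.nanmean(div_pair)) if np.any(~np.isnan(div_pair)) else float("nan")
        # divergence matrix for vectorized row-bootstrap (NaN on the diagonal:
        # a pair of identical resampled rows is not an independent comparison)
        dmat = np.full((n, n), np.nan)
        for k, (i, j) in enumerate(pair_idx):
            dmat[i, j] = dmat[j, i] = div_pair[k]
        sel = rng.integers(0, n, size=(n_boot, n))
        xs, ys = np.triu_indices(n, 1)
        a, b_ = sel[:, xs], sel[:, ys]
        pvals = dmat[a, b_]
        pvals[a == b_] = np.nan
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN replicates
            boot_div = np.nanmean(pvals, axis=1)
            boot_gc = np.nanmean(gc_row[sel], axis=1)
            boot_dens = {m: np.nanmean(dens_row[m][sel], axis=1) for m in motif_names}
        def ci(a):
            ok = a[~np.isnan(a)]
            if ok.size == 0:
                return float("nan"), float("nan")
            return (float(np.quantile(ok, 0.025)), float(np.quantile(ok, 0.975)))
        row = {
            "start": int(s), "end": int(e), "depth": depth,
            "divergence": divergence,
        }
        row["div_lo"], row["div_hi"] = ci(boot_div)
        row["gc"] = float(np.nanmean(gc_row)) if np.any(~np.isnan(gc_row)) else float("nan")
        row["gc_lo"], row["gc_hi"] = ci(boot_gc)
        for m in motif_names:
            row[f"dens_{m}"] = (float(np.nanmean(dens_row[m]))
                                if np.any(~np.isnan(dens_row[m])) else float("nan"))
            row[f"dens_{m}_lo"], row[f"dens_{m}_hi"] = ci(boot_dens[m])
        rows_out.append(row)
    return pd.DataFrame(rows_out)


def detect_junction(
    profile_or_sequence,
    window: int = 100,
    density_threshold: float = 0.5,
    min_run: int = 5,
    motifs: MotifSet = TELOMERIC,
) -> int:
    """Subtelomere-telomere junction: start of the first sustained motif-dense run.

    The junction is the start of the first window whose combined
    canonical+variant motif density exceeds ``density_threshold`` and that
    begins a run of at least ``min_run`` such windows.  Accepts either a
    profile DataFrame from :func:`window_profile` or a plain sequence
    string.  Raises :class:`TelomereNotFoundError` when no run qualifies.
    """
    names = (motifs.canonical, *motifs.variants)
    if isinstance(profile_or_sequence, str):
        seq = profile_or_sequence
        starts = np.arange(0, len(seq), window)
        dens = np.zeros(starts.size)
        for m in names:
            for p in motif_positions(seq, m, both_strands=True):
                dens[min(p // window, starts.size - 1)] += len(m)
        widths = np.minimum(starts + window, len(seq)) - starts
        dens = dens / widths
        start_coords = starts
    else:
        df = profile_or_sequence
        dens = sum(df[f"dens_{m}"].to_numpy() for m in names)
        start_coords = df["start"].to_numpy()
    above = dens > density_threshold
    n = above.size
    run_len = np.zeros(n, dtype=int)
    for i in range(n - 1, -1, -1):
        if above[i]:
            run_len[i] = (run_len[i + 1] if i + 1 < n else 0) + 1
    hits = np.flatnonzero(run_len >= min_run)
    if hits.size == 0:
        raise TelomereNotFoundError("no telomere detected")
    return int(start_coords[hits[0]])
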
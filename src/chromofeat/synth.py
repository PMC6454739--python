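"""Synthetic assemblies with planted chromosome features and machine-readable truth.

The generator emulates the architecture of a chromosome-scale honeybee
assembly at desk scale: a few megabase chromosomes carrying distal TTAGG
telomere arrays with an inner variant-motif gradient, conserved
subtelomeres, megabase low-GC centromeric blocks with AvaI tandem
arrays, short-arm AluI arrays, cM-positioned microsatellite markers
whose genetic density drops inside centromeres, and a set of unplaced
contigs.  Every planted feature is recorded in truth tables so that each
analysis module can be scored against ground truth without external
data.  All randomness flows from a single integer seed; reruns are
byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .canonical import ALUI_CONSENSUS, AVAI_CONSENSUS
from .genomeio import Assembly
from .genmap import Marker
from .telprofile import Msa

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Desk-scale genome layout and feature parameters.

    Rates and sizes default to the honeybee values the analyses are
    designed around: 2.3 Mbp centromeres at 22.7% GC in a 34.6% GC
    background, AvaI copies at 6.6% divergence, AluI at 3.9%, distal
    telomeres of ~1177 TTAGG copies with inner-telomere divergence of 12%
    falling to 2.4% distally, a conserved 3 kbp subtelomere (400 bp
    GC-rich element at 5.5% divergence, ~350 bp junction element ending
    100 bp before the junction), and marker maps at 21.6 cM/Mbp outside /
    7.9 cM/Mbp inside centromere regions.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 5_000_000
    background_gc: float = 0.346

    centromere_length: int = 2_300_000
    centromere_gc: float = 0.227
    avai_copies: tuple[int, ...] = (26, 11, 5)
    avai_divergence: float = 0.066

    alui_copies: tuple[int, ...] = (0, 80, 21)  # per chromosome; chr1's left end is telomeric
    alui_divergence: float = 0.039

    telomere_mean_copies: int = 1177
    telomere_copy_divergence: float = 0.003
    variant_fraction_at_junction: float = 0.5
    ttggg_share: float = 0.25             # share of variant events that are lone TTGGG
    hor_cooccurrence: float = 0.90        # target share of TCAGG/CTGGG inside the HOR
    telomere_inner_divergence: float = 0.12   # pairwise, < 2 kbp from junction
    telomere_outer_divergence: float = 0.024  # pairwise, 2-4 kbp from junction
    telomere_tip_divergence: float = 0.02     # pairwise, > 4 kbp

    subtelomere_length: int = 3000
    subtelomere_divergence: float = 0.14
    conserved_element_length: int = 400
    conserved_element_divergence: float = 0.055
    conserved_element_gc: float = 0.55
    junction_element_length: int = 350
    junction_element_offset: int = 100

    marker_spacing: int = 30_000
    rate_background: float = 21.6
    rate_centromere: float = 7.9
    marker_noise_shape: float = 25.0
    primer_length: int = 20
    n_zero_distance: int = 0

    n_unplaced: int = 10
    unplaced_length: int = 20_000
    unplaced_cctaa_copies: int = 900
    unplaced_alui_copies: int = 30

    n_ends: int = 14
    end_deletion_rate: float = 0.005

    block_total_bp: int = 10_000_000
    block_proportions: dict[str, float] = field(default_factory=lambda: {
        "same_chromosome": 0.86, "new_anchor": 0.075, "switched": 0.006,
        "lost_anchor": 0.001, "both_unplaced": 0.009,
        "unaligned_anchored": 0.038, "unaligned_unplaced": 0.011,
    })

    def validate(self) -> None:
        L = self.chromosome_length
        need = (self.subtelomere_length + 8 * self.telomere_mean_copies
                + self.centromere_length + 50_000)
        if need > L:
            raise ValueError("features exceed chromosome length")
        for frac in (self.background_gc, self.centromere_gc, self.hor_cooccurrence):
            if not (0 < frac < 1):
                raise ValueError("fractions must be in (0, 1)")
        if len(self.avai_copies) < self.n_chromosomes or len(self.alui_copies) < self.n_chromosomes:
            raise ValueError("per-chromosome copy tuples shorter than n_chromosomes")


@dataclass
class SyntheticTruth:
    telomeres: pd.DataFrame    # name, end, start, stop, copies
    centromeres: pd.DataFrame  # name, start, end, gc
    repeats: pd.DataFrame      # name, family, start, end, edits
    markers: pd.DataFrame      # id, linkage_group, cm, chromosome, position
    rates: dict[str, float]    # realized cM/Mbp per scope
    unplaced_counts: pd.DataFrame  # name, motif, copies
    junction: int | None = None
    hor_cooccurrence: float | None = None


def _rand_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitute each base with probability ``rate`` (to a different base)."""
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out, int(hit.size)


def _solve_row_rate(pairwise: float) -> float:
    """Per-row substitution rate m with pairwise mismatch 2m - (4/3)m**2."""
    return (2 - math.sqrt(4 - 16 * pairwise / 3)) / (8 / 3)


def _encode_str(seq: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _telomere_array(rng: np.random.Generator, n_copies: int,
                    cfg: SimulationConfig) -> tuple[str, int, int]:
    """A TTAGG array with a linear variant gradient from junction to tip.

    Returns (sequence, variants inside the HOR, lone TCAGG/CTGGG variants).
    The probability that a copy slot emits a variant declines linearly from
    ``variant_fraction_at_junction`` to zero at the tip; TCAGG/CTGGG events
    are planted as the higher-order repeat TCAGGCTGGG with probability
    h = c / (2 - c), which realizes a co-occurrence fraction c.
    """
    h = cfg.hor_cooccurrence / (2 - cfg.hor_cooccurrence)
    parts: list[str] = []
    made = 0
    n_in_hor = n_lone = 0
    acc = 0.0
    while made < n_copies:
        x = made / n_copies
        f = cfg.variant_fraction_at_junction * max(0.0, 1.0 - x)
        # error-diffusion thinning realizes the declining variant density
        # with low local noise, so the gradient is monotone at kbp scale
        acc += f
        if acc >= 1.0:
            acc -= 1.0
            if rng.random() < cfg.ttggg_share:
                parts.append("TTGGG")
                made += 1
            elif rng.random() < h:
                parts.append("TCAGGCTGGG")
                made += 2
                n_in_hor += 2
            else:
                parts.append("TCAGG" if rng.random() < 0.5 else "CTGGG")
                made += 1
                n_lone += 1
        else:
            unit, _ = _mutate(_encode_str("TTAGG"), cfg.telomere_copy_divergence, rng)
            parts.append(_to_str(unit))
            made += 1
    return "".join(parts), n_in_hor, n_lone


def _master_subtelomere(rng: np.random.Generator, cfg: SimulationConfig
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral subtelomere codes and per-position row substitution rates."""
    n = cfg.subtelomere_length
    codes = _rand_bases(rng, n, cfg.background_gc)
    rates = np.full(n, _solve_row_rate(cfg.subtelomere_divergence))
    el_len = cfg.conserved_element_length
    j_len = cfg.junction_element_length
    j_end = n - cfg.junction_element_offset
    j_start = j_end - j_len
    el_end = j_start - 150
    el_start = el_end - el_len
    codes[el_start:el_end] = _rand_bases(rng, el_len, cfg.conserved_element_gc)
    rates[el_start:el_end] = _solve_row_rate(cfg.conserved_element_divergence)
    return codes, rates


def simulate_genome(config: SimulationConfig | None = None, seed: int = 0
                    ) -> tuple[Assembly, list[Marker], SyntheticTruth]:
    """Generate a synthetic assembly, a marker table and truth tables."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    records: dict[str, str] = {}
    placement: dict[str, str | None] = {}
    telo_rows, cen_rows, rep_rows, marker_rows = [], [], [], []
    markers: list[Marker] = []
    hor_in = hor_lone = 0
    sub_codes, sub_rates = _master_subtelomere(rng, cfg)
    L = cfg.chromosome_length

    pair_d_cm: list[float] = []
    pair_d_bp: list[float] = []
    pair_in_cen: list[bool] = []

    for ci in range(cfg.n_chromosomes):
        name = f"chr{ci + 1}"
        genome = _rand_bases(rng, L, cfg.background_gc)
        blocked: list[tuple[int, int]] = []

        # centromere: low-GC block with an AvaI tandem array at its middle
        cen_s = (L - cfg.centromere_length) // 2
        cen_e = cen_s + cfg.centromere_length
        genome[cen_s:cen_e] = _rand_bases(rng, cfg.centromere_length, cfg.centromere_gc)
        cen_rows.append((name, cen_s, cen_e, cfg.centromere_gc))
        ava = _encode_str(AVAI_CONSENSUS)
        pos = cen_s + cfg.centromere_length // 2
        for _ in range(cfg.avai_copies[ci]):
            copy, edits = _mutate(ava, cfg.avai_divergence, rng)
            genome[pos:pos + ava.size] = copy
            rep_rows.append((name, "AvaI", pos, pos + ava.size, edits))
            pos += ava.size
        blocked.append((cen_s + cfg.centromere_length // 2 - 100, pos + 100))

        # short-arm AluI array (proximal telomere), except on the metacentric chr1
        alu = _encode_str(ALUI_CONSENSUS)
        if cfg.alui_copies[ci]:
            pos = 5000
            for _ in range(cfg.alui_copies[ci]):
                copy, edits = _mutate(alu, cfg.alui_divergence, rng)
                genome[pos:pos + alu.size] = copy
                rep_rows.append((name, "AluI", pos, pos + alu.size, edits))
                pos += alu.size
            blocked.append((4900, pos + 100))

        # distal telomere + subtelomere on the right end
        n_copies = int(rng.poisson(cfg.telomere_mean_copies))
        telo, nin, nlone = _telomere_array(rng, n_copies, cfg)
        hor_in += nin
        hor_lone += nlone
        telo_codes = _encode_str(telo)
        sub_row, _ = _vector_mutate(sub_codes, sub_rates, rng)
        t_start = L - telo_codes.size
        s_start = t_start - sub_codes.size
        genome[s_start:t_start] = sub_row
        genome[t_start:] = telo_codes
        telo_rows.append((name, "right", t_start, L, n_copies))
        blocked.append((s_start - 100, L))

        # metacentric chr1: a second distal telomere on the left end (CCTAA-oriented)
        if ci == 0:
            n_left = int(rng.poisson(cfg.telomere_mean_copies))
            telo_l, nin, nlone = _telomere_array(rng, n_left, cfg)
            hor_in += nin
            hor_lone += nlone
            sub_row_l, _ = _vector_mutate(sub_codes, sub_rates, rng)
            # mirrored end: [telomere'][subtelomere'] with the array at coord 0
            left = _encode_str(revcomp(_to_str(sub_row_l) + telo_l))
            genome[: left.size] = left
            telo_rows.append((name, "left", 0, len(telo_l), n_left))
            blocked.append((0, left.size + 100))

        # microsatellite markers: primer pairs flanking a planted core
        plen = cfg.primer_length
        locus_len = 3 * plen
        pos = cfg.marker_spacing // 2
        cm = 0.0
        prev_mid: int | None = None
        prev_cm = 0.0
        while pos + locus_len < L - 1000:
            jitter = int(rng.integers(-cfg.marker_spacing // 6, cfg.marker_spacing // 6))
            p = pos + jitter
            if any(s - locus_len < p < e for s, e in blocked):
                pos += cfg.marker_spacing
                continue
            locus = rng.integers(0, 4, size=locus_len).astype(np.uint8)
            genome[p:p + locus_len] = locus
            primer_a = _to_str(locus[:plen])
            primer_b = revcomp(_to_str(locus[2 * plen:]))
            mid = p + locus_len // 2
            if prev_mid is not None:
                seg = _segment_cm(prev_mid, mid, cen_s, cen_e, cfg)
                noise = rng.gamma(cfg.marker_noise_shape, 1.0 / cfg.marker_noise_shape)
                d_cm = seg * noise
                cm = prev_cm + d_cm
                pair_d_cm.append(d_cm)
                pair_d_bp.append(mid - prev_mid)
                pair_in_cen.append(cen_s <= prev_mid < cen_e and cen_s <= mid < cen_e)
            mid_id = f"m{ci + 1}_{len(marker_rows):04d}"
            markers.append(Marker(mid_id, name, round(cm, 4), primer_a, primer_b))
            marker_rows.append((mid_id, name, round(cm, 4), name, mid))
            prev_mid, prev_cm = mid, cm
            pos += cfg.marker_spacing

        records[name] = _to_str(genome)
        placement[name] = name

    # planted zero-genetic-distance duplicates (off by default)
    if cfg.n_zero_distance:
        idx = [i for i in range(1, len(markers))
               if markers[i].linkage_group == markers[i - 1].linkage_group]
        pick = rng.choice(len(idx), size=min(cfg.n_zero_distance, len(idx)), replace=False)
        for k in sorted(pick):
            i = idx[int(k)]
            markers[i].cm = markers[i - 1].cm
            marker_rows[i] = marker_rows[i][:2] + (markers[i].cm,) + marker_rows[i][3:]

    # unplaced contigs
    un_rows = []
    for ui in range(cfg.n_unplaced):
        name = f"contig_un_{ui + 1}"
        contig = _rand_bases(rng, cfg.unplaced_length, cfg.background_gc)
        if ui == 0 and cfg.unplaced_cctaa_copies:
            arr = _encode_str("CCTAA" * cfg.unplaced_cctaa_copies)
            contig[5000:5000 + arr.size] = arr
            un_rows.append((name, "CCTAA", cfg.unplaced_cctaa_copies))
        elif ui == 1 and cfg.unplaced_alui_copies:
            alu = _encode_str(ALUI_CONSENSUS)
            pos = 5000
            for _ in range(cfg.unplaced_alui_copies):
                copy, edits = _mutate(alu, cfg.alui_divergence, rng)
                contig[pos:pos + alu.size] = copy
                rep_rows.append((name, "AluI", pos, pos + alu.size, edits))
                pos += alu.size
            un_rows.append((name, "AluI", cfg.unplaced_alui_copies))
        records[name] = _to_str(contig)
        placement[name] = None

    d_cm = np.array(pair_d_cm)
    d_bp = np.array(pair_d_bp, dtype=float)
    in_cen = np.array(pair_in_cen, dtype=bool)
    rates = {
        "genome": float(d_cm.sum() / (d_bp.sum() / 1e6)),
        "centromere": float(d_cm[in_cen].sum() / (d_bp[in_cen].sum() / 1e6))
        if in_cen.any() else float("nan"),
        "background": float(d_cm[~in_cen].sum() / (d_bp[~in_cen].sum() / 1e6))
        if (~in_cen).any() else float("nan"),
    }
    n_var = hor_in + hor_lone
    truth = SyntheticTruth(
        telomeres=pd.DataFrame(telo_rows, columns=["name", "end", "start", "stop", "copies"]),
        centromeres=pd.DataFrame(cen_rows, columns=["name", "start", "end", "gc"]),
        repeats=pd.DataFrame(rep_rows, columns=["name", "family", "start", "end", "edits"]),
        markers=pd.DataFrame(marker_rows, columns=["id", "linkage_group", "cm",
                                                   "chromosome", "position"]),
        rates=rates,
        unplaced_counts=pd.DataFrame(un_rows, columns=["name", "motif", "copies"]),
        hor_cooccurrence=hor_in / n_var if n_var else None,
    )
    return Assembly(records, placement), markers, truth


def _segment_cm(a: int, b: int, cen_s: int, cen_e: int, cfg: SimulationConfig) -> float:
    """Expected cM between physical positions a < b under the two-rate map."""
    cen_bp = max(0, min(b, cen_e) - max(a, cen_s))
    bg_bp = (b - a) - cen_bp
    return (bg_bp * cfg.rate_background + cen_bp * cfg.rate_centromere) / 1e6


def _vector_mutate(codes: np.ndarray, rates: np.ndarray,
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
    out = codes.copy()
    hit = np.flatnonzero(rng.random(codes.size) < rates)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out, int(hit.size)


def simulate_end_alignment(config: SimulationConfig | None = None, seed: int = 0
                           ) -> tuple[Msa, SyntheticTruth]:
    """Aligned chromosome-end sequences with a distance-dependent divergence plan.

    All rows derive from one ancestral end (3 kbp subtelomere + telomere
    array with the variant gradient); per-position substitution rates are
    chosen so realized pairwise divergence matches the configured values
    (subtelomere, conserved element, inner/outer telomere).  The backbone
    row is indel-free; other rows carry rare deletions shown as gaps.
    """
    cfg = config or SimulationConfig()
    if cfg.n_ends < 2:
        raise ValueError("need at least two chromosome ends")
    rng = np.random.default_rng(seed)
    sub_codes, sub_rates = _master_subtelomere(rng, cfg)
    telo, _, _ = _telomere_array(rng, cfg.telomere_mean_copies, cfg)
    telo_codes = _encode_str(telo)
    junction = sub_codes.size
    anc = np.concatenate([sub_codes, telo_codes])
    d = np.arange(telo_codes.size)
    telo_pair = np.where(d < 2000, cfg.telomere_inner_divergence,
                         np.where(d < 4000, cfg.telomere_outer_divergence,
                                  cfg.telomere_tip_divergence))
    rates = np.concatenate([sub_rates,
                            np.vectorize(_solve_row_rate)(telo_pair)])
    names, rows = [], []
    for i in range(cfg.n_ends):
        name = "chr8_distal" if i == 0 else f"end_{i:02d}"
        row, _ = _vector_mutate(anc, rates, rng)
        txt = _to_str(row)
        if i > 0 and cfg.end_deletion_rate > 0:
            gap = rng.random(anc.size) < cfg.end_deletion_rate
            txt = "".join("-" if g else c for g, c in zip(gap, txt))
        names.append(name)
        rows.append(txt)
    msa = Msa(names, rows, backbone="chr8_distal")
    truth = SyntheticTruth(
        telomeres=pd.DataFrame([("ancestral", "right", junction, anc.size,
                                 cfg.telomere_mean_copies)],
                               columns=["name", "end", "start", "stop", "copies"]),
        centromeres=pd.DataFrame(columns=["name", "start", "end", "gc"]),
        repeats=pd.DataFrame(columns=["name", "family", "start", "end", "edits"]),
        markers=pd.DataFrame(columns=["id", "linkage_group", "cm", "chromosome", "position"]),
        rates={},
        unplaced_counts=pd.DataFrame(columns=["name", "motif", "copies"]),
        junction=junction,
    )
    return msa, truth


def simulate_blocks(config: SimulationConfig | None = None, seed: int = 0):
    """Alignment blocks + placement maps realizing category bp exactly.

    Returns ``(blocks, query_placements, target_placements, target_lengths,
    truth_bp)`` where ``truth_bp`` is the planted bp per category (summing
    exactly to the target assembly size).
    """
    from .asmcompare import CATEGORIES, AlignmentBlock

    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    props = cfg.block_proportions
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ValueError("block proportions must sum to 1")
    total = cfg.block_total_bp
    bp = {c: int(round(props.get(c, 0.0) * total)) for c in CATEGORIES}
    bp["same_chromosome"] += total - sum(bp.values())  # absorb rounding

    anchored_cats = ("same_chromosome", "new_anchor", "switched", "unaligned_anchored")
    unplaced_cats = ("lost_anchor", "both_unplaced", "unaligned_unplaced")
    n_chrom = 3
    blocks: list[AlignmentBlock] = []
    qp: dict[str, str | None] = {}
    tp: dict[str, str | None] = {}
    target_lengths: dict[str, int] = {}

    def split(n_bp: int, k: int) -> list[int]:
        base = n_bp // k
        out = [base] * k
        out[0] += n_bp - base * k
        return out

    q_counter = [0]

    def new_query(chrom: str | None) -> str:
        q_counter[0] += 1
        q = f"q_{q_counter[0]:03d}"
        qp[q] = chrom
        return q

    for i in range(n_chrom):
        t = f"t_chr{i + 1}"
        tp[t] = t
        cursor = 0
        segs = []
        for cat in anchored_cats:
            share = split(bp[cat], n_chrom)[i]
            if share > 0:
                segs.append((cat, share))
        order = rng.permutation(len(segs))
        for k in order:
            cat, share = segs[int(k)]
            s, e = cursor, cursor + share
            cursor = e
            if cat == "unaligned_anchored":
                continue
            if cat == "same_chromosome":
                q = new_query(t)
            elif cat == "switched":
                q = new_query(f"t_chr{(i + 1) % n_chrom + 1}")
            else:  # new_anchor
                q = new_query(None)
            blocks.append(AlignmentBlock(q, 0, share, t, s, e, "+"))
        target_lengths[t] = cursor
    t = "t_un1"
    tp[t] = None
    cursor = 0
    for cat in unplaced_cats:
        share = bp[cat]
        s, e = cursor, cursor + share
        cursor = e
        if share == 0:
            continue
        if cat == "lost_anchor":
            blocks.append(AlignmentBlock(new_query("t_chr1"), 0, share, t, s, e, "+"))
        elif cat == "both_unplaced":
            blocks.append(AlignmentBlock(new_query(None), 0, share, t, s, e, "+"))
    target_lengths[t] = cursor
    return blocks, qp, tp, target_lengths, bp
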
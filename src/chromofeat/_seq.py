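"""Low-level sequence encoding and exact k-mer matching primitives.

All genome-scale scans in this package run on numpy uint8 codes
(A=0, C=1, G=2, T=3, N=4) and 64-bit polynomial rolling hashes computed
modulo 2**64 (native uint64 wrap-around).  Hash identity is verified by
string comparison wherever single-pattern positions are reported, so
collisions cannot produce false hits there; multiset counting
(mappability) relies on the hash alone.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANTGCAN")

# odd => invertible modulo 2**64
_BASE = np.uint64(0x9E3779B97F4A7C15)
_BASE_INV = np.uint64(pow(int(_BASE), -1, 2**64))


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A0 C1 G2 T3, anything else 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _wrap_mul(a: np.ndarray, b) -> np.ndarray:
    with np.errstate(over="ignore"):
        return a * b


def kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling hashes of every k-window of ``codes``.

    Returns ``(hashes, valid)`` of length ``len(codes) - k + 1``;
    ``valid[i]`` is False when the window contains an N.  Hash of window i
    is sum_j codes[i+j] * BASE**(k-1-j) mod 2**64, so equal windows hash
    equal across sequences and k's.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    c = codes.astype(np.uint64)
    # powers BASE**(n-1-t) for t = 0..n-1 via cumulative product
    pw = np.empty(n, dtype=np.uint64)
    pw[0] = 1
    if n > 1:
        pw[1:] = _BASE
        np.cumprod(pw, out=pw)
    pw = pw[::-1].copy()
    terms = _wrap_mul(c, pw)
    pref = np.zeros(n + 1, dtype=np.uint64)
    np.cumsum(terms, out=pref[1:])
    win = pref[k:] - pref[:-k]  # sum over t in [i, i+k): codes[t]*BASE**(n-1-t)
    # normalize: multiply by BASE**-(n-i-k) = BASE_INV**(n-i-k)
    inv_pw = np.empty(n - k + 1, dtype=np.uint64)
    inv_pw[0] = 1
    if inv_pw.size > 1:
        inv_pw[1:] = _BASE_INV
        np.cumprod(inv_pw, out=inv_pw)
    inv_pw = inv_pw[::-1].copy()  # BASE_INV**(n-k-i) for i=0..n-k
    hashes = _wrap_mul(win, inv_pw)
    isn = (codes == 4).astype(np.int32)
    cn = np.zeros(n + 1, dtype=np.int32)
    np.cumsum(isn, out=cn[1:])
    valid = (cn[k:] - cn[:-k]) == 0
    return hashes, valid


def hash_pattern(pattern: str) -> int:
    codes = encode(pattern)
    h, v = kmer_hashes(codes, codes.size)
    if not v[0]:
        raise ValueError(f"pattern contains non-ACGT characters: {pattern!r}")
    return int(h[0])


def find_pattern(seq: str, pattern: str, codes: np.ndarray | None = None) -> np.ndarray:
    """Start offsets of exact occurrences of ``pattern`` in ``seq`` (forward
    strand only), verified by string comparison."""
    if codes is None:
        codes = encode(seq)
    k = len(pattern)
    h, valid = kmer_hashes(codes, k)
    cand = np.flatnonzero((h == np.uint64(hash_pattern(pattern))) & valid)
    if cand.size == 0:
        return cand
    return np.array([p for p in cand if seq[p : p + k] == pattern], dtype=np.int64)


def find_patterns(seq: str, patterns: list[str]) -> dict[str, np.ndarray]:
    """Exact start offsets for many same-or-mixed-length patterns at once.

    Hashes the sequence once per distinct pattern length; candidate hits are
    verified by string comparison.
    """
    codes = encode(seq)
    out: dict[str, np.ndarray] = {}
    by_len: dict[int, list[str]] = {}
    for p in patterns:
        by_len.setdefault(len(p), []).append(p)
    for k, pats in by_len.items():
        h, valid = kmer_hashes(codes, k)
        want = {hash_pattern(p): [] for p in pats}
        for p in pats:
            want[hash_pattern(p)].append(p)
        keys = np.fromiter(want.keys(), dtype=np.uint64)
        mask = np.isin(h, keys) & valid
        for pos in np.flatnonzero(mask):
            sub = seq[pos : pos + k]
            for p in want.get(int(h[pos]), ()):
                if sub == p:
                    out.setdefault(p, []).append(int(pos))
    return {
        p: np.array(sorted(out.get(p, [])), dtype=np.int64) for p in patterns
    }
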
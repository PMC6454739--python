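"""Synthetic stand-in consensus sequences for the honeybee tandem repeats.

The centromeric AvaI repeat (547 bp) and the proximal-telomeric AluI
repeat (176 bp) are defined by GenBank consensus entries that are not
redistributed here; the package instead ships deterministic synthetic
consensus sequences of the correct lengths, generated once from a fixed
seed.  Every annotation and array statistic in this package is
sequence-agnostic, so substituting the real consensus FASTA for these
stand-ins changes nothing but the sequences searched for.
"""

from __future__ import annotations

import numpy as np


_TELOMERIC_5MERS = ("TTAGG", "CCTAA", "TCAGG", "CCTGA", "CTGGG", "CCCAG",
                    "TTGGG", "CCCAA")


def _synthetic_consensus(length: int, seed: int, gc: float = 0.38) -> str:
    """Deterministic random consensus free of telomeric 5-mers.

    The tandem-repeat consensus must not share the telomeric motifs, or
    repeat arrays would confound motif-density screens; the first seed
    whose draw is clean is used (deterministic)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    for s in range(seed, seed + 1000):
        rng = np.random.default_rng(s)
        cand = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
        if not any(m in cand for m in _TELOMERIC_5MERS):
            return cand
    raise RuntimeError("no clean consensus found")  # pragma: no cover


#: 547 bp synthetic stand-in for the centromeric AvaI consensus.
AVAI_CONSENSUS: str = _synthetic_consensus(547, seed=547)

#: 176 bp synthetic stand-in for the proximal-telomeric AluI consensus.
ALUI_CONSENSUS: str = _synthetic_consensus(176, seed=176)

CONSENSUS = {"AvaI": AVAI_CONSENSUS, "AluI": ALUI_CONSENSUS}
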
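"""Per-base composition summary for RRHP FASTQ files.

RRHP libraries show near-total C,C,G,G content in the first four sequencing
cycles — the reconstituted MspI junction — which standard QC flags as "low
complexity" but is the assay's signature.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

BASES = ("A", "C", "G", "T", "N")


def per_base_composition(fastq_path: str | Path) -> pd.DataFrame:
    """Fraction of each base per sequencing cycle (1-based index).

    Cycles are normalized by the number of reads long enough to reach them,
    so frequencies sum to 1 per cycle (reads containing other IUPAC codes
    are tallied under N).
    """
    tallies: list[np.ndarray] = []
    for record in SeqIO.parse(str(fastq_path), "fastq"):
        seq = str(record.seq).upper()
        if len(seq) > len(tallies):
            tallies.extend(np.zeros(5) for _ in range(len(seq) - len(tallies)))
        for i, base in enumerate(seq):
            j = BASES.index(base) if base in BASES else 4
            tallies[i][j] += 1
    if not tallies:
        return pd.DataFrame(columns=BASES, dtype=float)
    mat = np.vstack(tallies)
    totals = mat.sum(axis=1, keepdims=True)
    freq = mat / np.where(totals == 0, 1, totals)
    return pd.DataFrame(freq, columns=BASES, index=pd.RangeIndex(1, len(tallies) + 1, name="cycle"))
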
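"""Strand-aware junction-read quantification.

A mapped read is assigned to the plus-strand junction at site start ``s``
when it aligns forward, its leftmost coordinate equals ``s`` and its first
four aligned bases are CCGG; to the minus-strand junction when it aligns
reverse, its 5' end (rightmost genome coordinate) equals ``s + 3`` and its
biological first four bases are CCGG.  Duplicates are counted — RRHP signal
is read abundance at the junction — and every mapped record is counted at
most once.  Soft-clipped 5' ends disqualify a read: the junction base must
be aligned for the coordinate identity with the site to hold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .digest import JunctionCatalog

logger = logging.getLogger(__name__)

MOTIF = "CCGG"


@dataclass
class LibrarySummary:
    """Per-library audit counters (raw reads, assigned reads, covered sites)."""

    sample_id: str
    raw_reads: int = 0
    counted_5hmc: int = 0
    unique_sites: int = 0
    skipped_malformed: int = 0


@dataclass
class CountMatrix:
    """Junction sites x libraries count matrix plus the sample sheet.

    ``counts`` is indexed by (contig, site_start, strand); ``samples`` is
    indexed by sample_id with columns ``group`` and ``is_control`` and fixes
    the column order of ``counts``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts[list(self.samples.index)]

    @property
    def biological(self) -> pd.DataFrame:
        """Count columns for non-control libraries only."""
        keep = ~self.samples["is_control"].astype(bool)
        return self.counts[list(self.samples.index[keep])]

    @property
    def biological_samples(self) -> pd.DataFrame:
        return self.samples[~self.samples["is_control"].astype(bool)]

    def subset_sites(self, mask) -> "CountMatrix":
        return CountMatrix(self.counts[mask], self.samples)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, sheet_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=[0, 1, 2])
        samples = read_sample_sheet(sheet_path)
        return cls(counts, samples)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "is_control"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    sheet["is_control"] = sheet["is_control"].astype(bool)
    return sheet.set_index("sample_id")


def _first_aligned_ok(read: pysam.AlignedSegment) -> bool:
    """True when the read's 5' end is aligned (no clip at the 5' side)."""
    cigar = read.cigartuples
    if not cigar:
        return False
    op = cigar[-1][0] if read.is_reverse else cigar[0][0]
    return op == 0  # M


def count_junction_reads(
    alignments: str | Path | pysam.AlignmentFile,
    catalog: JunctionCatalog,
    sample_id: str = "sample",
) -> tuple[pd.Series, LibrarySummary]:
    """Count junction reads from a SAM/BAM stream against a catalog."""
    own = not isinstance(alignments, pysam.AlignmentFile)
    if own:
        path = str(alignments)
        mode = "rb" if path.endswith(".bam") else "r"
        alignments = pysam.AlignmentFile(path, mode, check_sq=False)

    counts = np.zeros(len(catalog), dtype=np.int64)
    summary = LibrarySummary(sample_id)
    known_contigs = set(catalog.contig_lengths) or {
        j.contig_id for j in catalog
    }
    try:
        for read in alignments:
            summary.raw_reads += 1
            if read.is_unmapped:
                continue
            if read.reference_name not in known_contigs:
                raise ValueError(
                    f"alignment contig {read.reference_name!r} absent from the "
                    "junction catalog's genome"
                )
            seq = read.query_sequence
            if seq is None or len(seq) < 4 or not _first_aligned_ok(read):
                summary.skipped_malformed += seq is None
                continue
            if read.is_reverse:
                # 5' end at reference_end - 1 must equal site_start + 3;
                # stored sequence is the reverse complement of the biological
                # read, and CCGG is its own reverse complement.
                if seq[-4:] != MOTIF:
                    continue
                key = (read.reference_name, read.reference_end - 4, "-")
            else:
                if seq[:4] != MOTIF:
                    continue
                key = (read.reference_name, read.reference_start, "+")
            if key in catalog:
                counts[catalog.index_of(key)] += 1
                summary.counted_5hmc += 1
    finally:
        if own:
            alignments.close()

    summary.unique_sites = int((counts > 0).sum())
    series = pd.Series(
        counts,
        index=pd.MultiIndex.from_tuples(
            catalog.keys(), names=["contig", "site_start", "strand"]
        ),
        name=sample_id,
    )
    return series, summary


def summarize_counts(counts: pd.Series, sample_id: str = "sample") -> LibrarySummary:
    """Audit counters from a count vector alone (no raw-read total)."""
    s = LibrarySummary(sample_id)
    s.counted_5hmc = int(counts.sum())
    s.unique_sites = int((counts > 0).sum())
    return s


def assemble_matrix(columns: dict[str, pd.Series], sheet: pd.DataFrame) -> CountMatrix:
    """Combine per-sample count vectors into a CountMatrix.

    Sites absent from a library get zero; rows are sorted genomically
    (contig, site_start, strand); column order follows the sample sheet.
    """
    missing = [s for s in sheet.index if s not in columns]
    if missing:
        raise ValueError(f"counts missing for samples: {missing}")
    frame = pd.DataFrame({s: columns[s] for s in sheet.index}).fillna(0).astype(np.int64)
    frame = frame.sort_index()
    frame.index.names = ["contig", "site_start", "strand"]
    return CountMatrix(frame, sheet)


def merged_strand_union(counts: pd.DataFrame) -> int:
    """Number of distinct recognition sites (strand-merged) with any count."""
    covered = counts.sum(axis=1) > 0
    sites = {(c, s) for (c, s, _strand), hit in covered.items() if hit}
    return len(sites)
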
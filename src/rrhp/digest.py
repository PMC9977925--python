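"""In-silico MspI digestion and RRHP junction cataloguing.

MspI recognizes CCGG and cuts between the first and second base (C^CGG),
regardless of CpG methylation but blocked by glucosylated 5hmC.  In an RRHP
library the P5 adapter reconstitutes the CCGG at a fragment end, so a
sequenced junction read starts with CCGG on either strand.  Because CCGG is
its own reverse complement, every recognition site carries exactly two
junctions: one read start per strand.

All coordinates are 0-based, half-open.  BED output follows the same
convention; SAM input (1-based) is converted on ingestion elsewhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

MOTIF = "CCGG"
CUT_OFFSET = 1  # C^CGG
VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class RecognitionSite:
    """A CCGG occurrence; ``start`` is the 0-based offset of the first C."""

    contig_id: str
    start: int


@dataclass(frozen=True)
class Junction:
    """A strand-resolved read start at a recognition site.

    ``read_start`` is the leftmost genome coordinate a junction read's
    alignment occupies: the site start for the plus strand; for the minus
    strand the read's 5' end sits at ``site_start + 3`` and the alignment
    extends leftward, so ``read_start`` depends on read length and is
    recorded as the site start here as well (the leftmost coordinate of the
    4-base motif interval both strands share).
    """

    contig_id: str
    site_start: int
    strand: str  # "+" or "-"

    @property
    def five_prime(self) -> int:
        """Genome coordinate of the read's first sequenced base."""
        return self.site_start if self.strand == "+" else self.site_start + 3


@dataclass(frozen=True)
class Fragment:
    contig_id: str
    start: int
    end: int
    sequence: str


@dataclass
class JunctionCatalog:
    """All junctions of a genome, with constant-time key lookup."""

    junctions: list[Junction]
    contig_lengths: dict[str, int] = field(default_factory=dict)
    _index: dict[tuple[str, int, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {
                (j.contig_id, j.site_start, j.strand): i
                for i, j in enumerate(self.junctions)
            }

    def __len__(self) -> int:
        return len(self.junctions)

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._index

    def __iter__(self):
        return iter(self.junctions)

    def index_of(self, key: tuple[str, int, str]) -> int:
        return self._index[key]

    def keys(self) -> list[tuple[str, int, str]]:
        return [(j.contig_id, j.site_start, j.strand) for j in self.junctions]

    @property
    def n_sites(self) -> int:
        return len(self.junctions) // 2


class InvalidSequenceError(ValueError):
    """A genome sequence contains a character outside {A,C,G,T,N}."""


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly line-wrapped, multi-contig) FASTA into a dict."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate contig id {record.id!r} in {path}")
        genome[record.id] = str(record.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _validate_sequence(contig_id: str, sequence: str) -> None:
    bad = set(sequence) - VALID_BASES
    if bad:
        pos = next(i for i, b in enumerate(sequence) if b in bad)
        raise InvalidSequenceError(
            f"contig {contig_id!r}: invalid base {sequence[pos]!r} at position {pos}"
        )


def scan_recognition_sites(genome: Mapping[str, str]) -> list[RecognitionSite]:
    """Enumerate every CCGG occurrence with a step-1 sliding window.

    N never matches (the enzyme is sequence-exact).  Returned sites are
    sorted by (contig, start) in the genome's contig order.
    """
    sites: list[RecognitionSite] = []
    for contig_id, sequence in genome.items():
        _validate_sequence(contig_id, sequence)
        if len(sequence) < 4:
            continue
        arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
        hit = (
            (arr[:-3] == ord("C"))
            & (arr[1:-2] == ord("C"))
            & (arr[2:-1] == ord("G"))
            & (arr[3:] == ord("G"))
        )
        sites.extend(RecognitionSite(contig_id, int(s)) for s in np.flatnonzero(hit))
    return sites


def enumerate_junctions(
    sites: Sequence[RecognitionSite],
    contig_lengths: Mapping[str, int] | None = None,
) -> JunctionCatalog:
    """Two junctions per recognition site, one per strand."""
    junctions: list[Junction] = []
    for site in sites:
        junctions.append(Junction(site.contig_id, site.start, "+"))
        junctions.append(Junction(site.contig_id, site.start, "-"))
    return JunctionCatalog(junctions, dict(contig_lengths or {}))


def digest_fragments(
    genome: Mapping[str, str], sites: Sequence[RecognitionSite]
) -> list[Fragment]:
    """Cut C^CGG at every site; fragments tile each contig exactly."""
    by_contig: dict[str, list[int]] = {}
    for site in sites:
        by_contig.setdefault(site.contig_id, []).append(site.start + CUT_OFFSET)
    fragments: list[Fragment] = []
    for contig_id, sequence in genome.items():
        cuts = [0] + sorted(by_contig.get(contig_id, [])) + [len(sequence)]
        for start, end in zip(cuts[:-1], cuts[1:]):
            if end > start:
                fragments.append(
                    Fragment(contig_id, start, end, sequence[start:end])
                )
    return fragments


def write_junction_bed(catalog: JunctionCatalog, destination: str | Path | io.TextIOBase) -> None:
    """BED6: the 4-base motif interval per junction, strand in column 6."""
    own = isinstance(destination, (str, Path))
    fh = open(destination, "w") if own else destination
    try:
        for j in catalog:
            fh.write(
                f"{j.contig_id}\t{j.site_start}\t{j.site_start + 4}\t.\t.\t{j.strand}\n"
            )
    finally:
        if own:
            fh.close()


def read_junction_bed(path: str | Path) -> JunctionCatalog:
    junctions: list[Junction] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, _name, _score, strand = line.rstrip("\n").split("\t")
            junctions.append(Junction(chrom, int(start), strand))
    return JunctionCatalog(junctions)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
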
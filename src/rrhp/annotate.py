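"""Assignment of DhmCs to genomic features.

Each differentially hydroxymethylated site is placed into exactly one of
promoter-TSS, TTS, exon, intron or intergenic, decided in that priority
order.  Promoter and TTS windows are strand-relative around the
transcription start / termination site; HOMER-style defaults of
(-1000, +100) around the TSS and (-100, +1000) around the TES are explicit,
configurable parameters.  Distances to the nearest TSS are signed and
strand-aware (negative = upstream of the gene).

The BED dialect used for DhmCs has six tab-separated columns — chrom, start,
end, unique peak id (1..N), a carried-through score slot (e.g. the adjusted
p-value), and strand — and accepts 0/1 strand codes (0 = "+", 1 = "-") on
input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

CATEGORIES = ("promoter-TSS", "TTS", "exon", "intron", "intergenic")

_STRAND_IN = {"+": "+", "-": "-", "0": "+", "1": "-"}


@dataclass
class GeneModel:
    """A gene with its span, exons and strand-aware TSS/TES (0-based)."""

    gene_id: str
    contig: str
    strand: str
    start: int                      # 0-based half-open span
    end: int
    exons: list[tuple[int, int]]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class AnnotationRecord:
    peak_id: str
    contig: str
    position: int
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None


def write_bed6(
    dhmcs: pd.DataFrame,
    path: str | Path,
    score_column: str = "q",
) -> None:
    """Write DhmC calls as BED6 with sequential peak ids 1..N.

    ``dhmcs`` is indexed by (contig, site_start, strand) as produced by the
    differential stage; the score slot carries ``score_column`` through the
    annotation.
    """
    with open(path, "w") as fh:
        for i, ((contig, start, strand), row) in enumerate(dhmcs.iterrows(), 1):
            score = row[score_column] if score_column in dhmcs.columns else "."
            if isinstance(score, float):
                score = f"{score:.6g}"
            fh.write(f"{contig}\t{start}\t{start + 1}\t{i}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> pd.DataFrame:
    """Read the DhmC BED dialect; strand accepted as +/- or 0/1."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ValueError(f"expected 6 BED columns, got {len(fields)}: {line!r}")
            chrom, start, end, peak_id, score, strand = fields
            if strand not in _STRAND_IN:
                raise ValueError(f"invalid strand code {strand!r}")
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "peak_id": peak_id,
                    "score": score,
                    "strand": _STRAND_IN[strand],
                }
            )
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "peak_id", "score", "strand"]
    )
    if frame["peak_id"].duplicated().any():
        raise ValueError("peak ids must be unique within a BED file")
    return frame


def parse_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Read gene/mRNA/exon features from GFF3 into 0-based gene models.

    GFF coordinates are 1-based inclusive and converted to 0-based
    half-open.  A transcript without exon children contributes its whole
    span as a single exon.
    """
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        for exon in db.children(gene, featuretype="exon"):
            exons.append((exon.start - 1, exon.end))
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        exons.sort()
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
            )
        )
    models.sort(key=lambda m: (m.contig, m.start, m.gene_id))
    return models


class _ContigIndex:
    """Interval trees per annotation layer for one contig."""

    def __init__(
        self,
        models: list[GeneModel],
        promoter_window: tuple[int, int],
        tts_window: tuple[int, int],
    ):
        self.promoter = IntervalTree()
        self.tts = IntervalTree()
        self.exon = IntervalTree()
        self.gene_body = IntervalTree()
        self.models = models
        for m in models:
            p_lo, p_hi = _strand_window(m.tss, m.strand, promoter_window)
            t_lo, t_hi = _strand_window(m.tes, m.strand, tts_window)
            self.promoter[p_lo:p_hi] = m
            self.tts[t_lo:t_hi] = m
            for lo, hi in m.exons:
                if hi > lo:
                    self.exon[lo:hi] = m
            if m.end > m.start:
                self.gene_body[m.start:m.end] = m


def _strand_window(anchor: int, strand: str, window: tuple[int, int]) -> tuple[int, int]:
    """Half-open interval of a strand-relative (upstream, downstream) window."""
    lo, hi = window
    if strand == "+":
        return anchor + lo, anchor + hi + 1
    return anchor - hi, anchor - lo + 1


def signed_tss_distance(position: int, model: GeneModel) -> int:
    """Signed distance to the TSS; negative = upstream of the gene."""
    if model.strand == "+":
        return position - model.tss
    return model.tss - position


def build_index(
    models: list[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (-100, 1000),
) -> dict[str, _ContigIndex]:
    by_contig: dict[str, list[GeneModel]] = {}
    for m in models:
        by_contig.setdefault(m.contig, []).append(m)
    return {
        contig: _ContigIndex(ms, promoter_window, tts_window)
        for contig, ms in by_contig.items()
    }


def _nearest_by_tss(position: int, candidates: list[GeneModel]) -> GeneModel | None:
    if not candidates:
        return None
    return min(
        candidates, key=lambda m: (abs(position - m.tss), m.gene_id)
    )


def annotate_site(
    contig: str,
    position: int,
    index: dict[str, _ContigIndex],
    peak_id: str = ".",
) -> AnnotationRecord:
    """Categorize one site with priority promoter-TSS > TTS > exon > intron."""
    cidx = index.get(contig)
    if cidx is None or not cidx.models:
        return AnnotationRecord(peak_id, contig, position, "intergenic", None, None)
    for category, tree in (
        ("promoter-TSS", cidx.promoter),
        ("TTS", cidx.tts),
        ("exon", cidx.exon),
        ("intron", cidx.gene_body),
    ):
        hits = [iv.data for iv in tree[position]]
        if hits:
            gene = _nearest_by_tss(position, hits)
            return AnnotationRecord(
                peak_id, contig, position, category,
                gene.gene_id, signed_tss_distance(position, gene),
            )
    gene = _nearest_by_tss(position, cidx.models)
    return AnnotationRecord(
        peak_id, contig, position, "intergenic",
        gene.gene_id, signed_tss_distance(position, gene),
    )


def batch_annotate(
    bed: pd.DataFrame,
    models: list[GeneModel],
    promoter_window: tuple[int, int] = (-1000, 100),
    tts_window: tuple[int, int] = (-100, 1000),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate every BED peak; returns (records, category tally)."""
    index = build_index(models, promoter_window, tts_window)
    records = []
    for _, row in bed.iterrows():
        rec = annotate_site(row["chrom"], int(row["start"]), index, str(row["peak_id"]))
        records.append(
            {
                "peak_id": rec.peak_id,
                "contig": rec.contig,
                "position": rec.position,
                "category": rec.category,
                "nearest_gene": rec.nearest_gene,
                "distance_to_tss": rec.distance_to_tss,
            }
        )
    frame = pd.DataFrame(
        records,
        columns=["peak_id", "contig", "position", "category", "nearest_gene", "distance_to_tss"],
    )
    tally = {cat: int((frame["category"] == cat).sum()) for cat in CATEGORIES}
    return frame, tally


def write_tally(tally: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(json.dumps(tally, indent=2) + "\n")
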
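"""Genome-browser track export: per-sample bedGraph and DhmC BED."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import write_bed6
from .quantify import CountMatrix


def write_bedgraph(counts: pd.Series, path: str | Path, name: str | None = None) -> int:
    """One bedGraph line per nonzero junction (4-base motif interval).

    Returns the number of data lines written.
    """
    name = name or counts.name or "sample"
    n = 0
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        nonzero = counts[counts > 0]
        for (contig, start, _strand), value in nonzero.items():
            fh.write(f"{contig}\t{start}\t{start + 4}\t{int(value)}\n")
            n += 1
    return n


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("track") or not line.strip():
                continue
            contig, start, end, value = line.rstrip("\n").split("\t")
            rows.append(
                {"contig": contig, "start": int(start), "end": int(end), "value": float(value)}
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "value"])


def write_igv_tracks(
    matrix: CountMatrix, dhmcs: pd.DataFrame, outdir: str | Path
) -> dict[str, Path]:
    """Per-sample count bedGraphs plus one BED6 of DhmC calls."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in matrix.samples.index:
        # one file per strand: both junctions of a site share the motif
        # interval, and bedGraph forbids overlapping lines within a track
        for strand, label in (("+", "plus"), ("-", "minus")):
            col = matrix.counts[sample]
            sel = col[col.index.get_level_values("strand") == strand]
            path = outdir / f"{sample}.{label}.bedGraph"
            write_bedgraph(sel, path, name=f"{sample} ({strand})")
            paths[f"{sample}.{label}"] = path
    bed_path = outdir / "dhmc.bed"
    write_bed6(dhmcs, bed_path)
    paths["dhmc_bed"] = bed_path
    return paths
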
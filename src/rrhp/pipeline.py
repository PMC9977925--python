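"""End-to-end orchestration: simulate/ingest -> quantify -> filter -> test -> annotate -> tracks.

Every stochastic stage draws from a named RNG stream fanned out from one run
seed, so a rerun with the same configuration is byte-identical and stages
can be rerun in isolation.  A JSON run report mirrors the per-library audit
columns (raw reads, junction-assigned reads, covered sites) and the filter
cascade.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import batch_annotate, parse_gene_models, read_bed6, write_bed6, write_tally
from .diffhmc import differential_analysis, mds_coordinates, voom_transform
from .digest import (
    enumerate_junctions,
    read_fasta,
    scan_recognition_sites,
    write_junction_bed,
)
from .filters import FilterParams, apply_filters
from .quantify import assemble_matrix, count_junction_reads, CountMatrix, read_sample_sheet
from .simulate import SimConfig, default_sample_sheet, simulate_gene_models, simulate_study
from .tracks import write_igv_tracks

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "rrhp_out"
    seed: int = 0
    # either simulate a study ...
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # ... or point at real inputs
    genome_fasta: str | None = None
    sample_sheet: str | None = None
    alignments: dict[str, str] = field(default_factory=dict)  # sample_id -> SAM/BAM
    gff: str | None = None
    # analysis settings
    filter_params: FilterParams = field(default_factory=FilterParams)
    lowess_span: float = 0.5
    q_max: float = 0.05
    promoter_window: tuple[int, int] = (-1000, 100)
    tts_window: tuple[int, int] = (-100, 1000)
    mds_top_sites: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        filt = FilterParams(**raw.pop("filter_params", {}))
        for key in ("promoter_window", "tts_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(sim=sim, filter_params=filt, **raw)
        cfg.sim.seed = cfg.seed
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run report (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    stage = "simulate" if config.simulate else "ingest"
    try:
        if config.simulate:
            config.sim.seed = config.seed
            genome, catalog, truth, _true_counts, sheet = simulate_study(
                config.sim, out / "sim"
            )
            gff_text = simulate_gene_models(genome, config.sim)
            gff_path = out / "sim" / "genes.gff3"
            gff_path.write_text(gff_text)
            alignments = {s: out / "sim" / f"{s}.sam" for s in sheet.index}
        else:
            genome = read_fasta(config.genome_fasta)
            sheet = read_sample_sheet(config.sample_sheet)
            sites = scan_recognition_sites(genome)
            catalog = enumerate_junctions(sites, {c: len(s) for c, s in genome.items()})
            alignments = {s: Path(p) for s, p in config.alignments.items()}
            gff_path = Path(config.gff) if config.gff else None
        write_junction_bed(catalog, out / "junctions.bed")
        report["stages"][stage] = {
            "n_recognition_sites": catalog.n_sites,
            "n_junctions": len(catalog),
            "n_libraries": int(len(sheet)),
        }

        stage = "quantify"
        columns, summaries = {}, {}
        for sample_id in sheet.index:
            counts, summary = count_junction_reads(
                alignments[sample_id], catalog, sample_id=sample_id
            )
            columns[sample_id] = counts
            summaries[sample_id] = dataclasses.asdict(summary)
        matrix = assemble_matrix(columns, sheet)
        matrix.to_tsv(out / "counts.tsv")
        report["stages"]["quantify"] = summaries

        stage = "filter"
        filtered, filt_report = apply_filters(matrix, config.filter_params)
        filtered.to_tsv(out / "counts.filtered.tsv")
        filt_report.to_json(out / "filter_report.json")
        report["stages"]["filter"] = dataclasses.asdict(filt_report)

        stage = "differential"
        moderated, calls, _voom = differential_analysis(
            filtered, span=config.lowess_span, q_max=config.q_max
        )
        moderated.table.to_csv(out / "results.tsv", sep="\t", float_format="%.6g")
        calls.to_csv(out / "dhmc_calls.tsv", sep="\t", float_format="%.6g")
        # MDS over all libraries including controls (library-structure QC)
        voom_all = voom_transform(matrix.counts.loc[filtered.counts.index])
        mds = mds_coordinates(voom_all, top_sites=config.mds_top_sites)
        mds.to_csv(out / "mds.tsv", sep="\t", float_format="%.6g")
        report["stages"]["differential"] = {
            "n_sites_tested": int(len(moderated.table)),
            "n_dhmc": int(len(calls)),
            "n_up_in_large": int((calls["direction"] == "up").sum()),
            "n_down_in_large": int((calls["direction"] == "down").sum()),
            "prior_df": moderated.d0,
            "prior_variance": moderated.s0_sq,
        }

        stage = "annotate"
        write_bed6(calls, out / "dhmc.bed")
        if gff_path is not None:
            models = parse_gene_models(gff_path)
            bed = read_bed6(out / "dhmc.bed")
            annotation, tally = batch_annotate(
                bed, models, config.promoter_window, config.tts_window
            )
            annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
            write_tally(tally, out / "annotation_tally.json")
            report["stages"]["annotate"] = tally

        stage = "tracks"
        track_paths = write_igv_tracks(matrix, calls, out / "tracks")
        report["stages"]["tracks"] = {"n_files": len(track_paths)}
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        report["failed_stage"] = stage
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
        raise

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
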
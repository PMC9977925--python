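"""Chemistry-faithful RRHP read simulator.

The generator emulates the assay end to end: a genome with a controlled set
of CCGG sites, a per-site ground-truth hydroxymethylation level pi in [0,1]
shared by both strand junctions (glucosylation protects the CCGG duplex, not
a strand), and per-library junction counts.  In protocol mode the expected
count at a junction is

    multiplier * depth_factor * pi_group

because only glucosylated (5hmC-bearing) junctions survive the second MspI
digestion and keep their P5 adapter; in control mode the second digestion is
omitted, every adapterized fragment amplifies, and the expected count is
``multiplier * depth_factor`` regardless of pi.  Counts are negative
binomial (Gamma-Poisson): RRHP data are count data with biological
overdispersion, like RNA-Seq.

Reads are ``read_length`` bases (75 by default, single-end), begin with CCGG
and extend into the fragment on the junction's strand; a truth SAM places
each read at its junction so the quantifier can be round-tripped exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .digest import (
    Junction,
    JunctionCatalog,
    RecognitionSite,
    enumerate_junctions,
    reverse_complement,
    scan_recognition_sites,
    write_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic RRHP experiment.

    Defaults emulate the profiled design: two groups of five libraries plus
    one 5hmC-irrelevant control, 75 bp single-end reads, baseline
    hydroxymethylation levels averaging ~5% of full protection, and a depth
    factor placing the global median junction count near the real study's
    filtering median (~19).
    """

    genome_length: int = 200_000
    n_contigs: int = 2
    target_site_count: int = 500
    n_per_group: int = 5
    read_length: int = 75
    depth_factor: float = 400.0
    library_size_multipliers: Mapping[str, float] | None = None
    baseline_level_params: tuple[float, float] = (2.0, 38.0)
    diff_fraction: float = 0.1
    effect_logit_shift: float = 1.5581  # ~4-fold at the baseline mean level
    fraction_up: float = 0.5
    nb_dispersion: float = 0.1
    gc_content: float = 0.42
    min_read_length: int = 20
    error_rate: float = 0.0
    phred_quality: int = 35
    seed: int = 0

    def multiplier_for(self, sample_id: str) -> float:
        if self.library_size_multipliers is None:
            return 1.0
        try:
            return float(self.library_size_multipliers[sample_id])
        except KeyError:
            raise KeyError(
                f"no library size multiplier configured for sample {sample_id!r}"
            ) from None


def _stream(config_seed: int, *names: str) -> np.random.Generator:
    """Named, reproducible RNG stream derived from the run seed."""
    digest = hashlib.sha256(("/".join(names)).encode()).digest()
    entropy = [config_seed] + [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _scrub_motif(seq: np.ndarray) -> np.ndarray:
    """Destroy every accidental CCGG by flipping its first C to A."""
    while True:
        hit = (
            (seq[:-3] == ord("C"))
            & (seq[1:-2] == ord("C"))
            & (seq[2:-1] == ord("G"))
            & (seq[3:] == ord("G"))
        )
        idx = np.flatnonzero(hit)
        if idx.size == 0:
            return seq
        seq[idx] = ord("A")


def simulate_genome(config: SimConfig) -> dict[str, str]:
    """Random genome with exactly ``target_site_count`` CCGG sites.

    Background sequence is scrubbed of accidental CCGGs and the motifs are
    planted deliberately, flanked by T guards, spaced at least a read length
    apart and away from contig ends, so every junction supports a full-length
    read and the site count is exact and reproducible.
    """
    if config.target_site_count < 1:
        raise ValueError("target_site_count must be >= 1")
    rng = _stream(config.seed, "genome")
    per_contig = np.full(config.n_contigs, config.target_site_count // config.n_contigs)
    per_contig[: config.target_site_count % config.n_contigs] += 1
    contig_len = config.genome_length // config.n_contigs
    margin = config.read_length + 10
    spacing_floor = config.read_length + 30

    genome: dict[str, str] = {}
    for c in range(config.n_contigs):
        n_sites = int(per_contig[c])
        usable = contig_len - 2 * margin
        if n_sites and usable < n_sites * spacing_floor:
            raise ValueError(
                f"genome_length too small to place {n_sites} sites "
                f"{spacing_floor} bp apart on a {contig_len} bp contig"
            )
        gc = config.gc_content
        probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = _BASES[rng.choice(4, size=contig_len, p=probs)].copy()
        seq = _scrub_motif(seq)
        if n_sites:
            slot = usable // n_sites
            jitter = rng.integers(0, max(1, slot - spacing_floor), size=n_sites)
            starts = margin + np.arange(n_sites) * slot + jitter
            for s in starts:
                seq[s - 1 : s + 5] = np.frombuffer(b"TCCGGT", dtype=np.uint8)
        genome[f"contig{c + 1}"] = seq.tobytes().decode("ascii")
    return genome


def plant_truth(catalog: JunctionCatalog, config: SimConfig) -> pd.DataFrame:
    """Ground-truth hydroxymethylation per recognition site.

    Baseline levels are Beta(a, b) draws shared by both strand junctions of
    a site.  ``round(diff_fraction * n_sites)`` sites are differential: the
    large group's level is shifted by ``effect_logit_shift`` on the logit
    scale, upward with probability ``fraction_up`` and downward otherwise.
    Indexed by (contig, site_start) with columns pi_large, pi_small,
    is_differential.
    """
    site_keys = sorted({(j.contig_id, j.site_start) for j in catalog})
    n = len(site_keys)
    rng = _stream(config.seed, "truth")
    a, b = config.baseline_level_params
    pi0 = rng.beta(a, b, size=n)
    n_diff = int(round(config.diff_fraction * n))
    diff_idx = rng.choice(n, size=n_diff, replace=False)
    is_diff = np.zeros(n, dtype=bool)
    is_diff[diff_idx] = True
    sign = np.where(rng.random(n) < config.fraction_up, 1.0, -1.0)
    pi_large = pi0.copy()
    shifted = expit(logit(pi0[is_diff]) + sign[is_diff] * config.effect_logit_shift)
    pi_large[is_diff] = shifted
    truth = pd.DataFrame(
        {
            "pi_large": pi_large,
            "pi_small": pi0,
            "is_differential": is_diff,
        },
        index=pd.MultiIndex.from_tuples(site_keys, names=["contig", "site_start"]),
    )
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson limit)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if dispersion <= 1e-12:
        out[pos] = rng.poisson(mean[pos])
        return out
    r = 1.0 / dispersion
    p = r / (r + mean[pos])
    out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(
    truth: pd.DataFrame,
    sample_id: str,
    group: str,
    config: SimConfig,
    catalog: JunctionCatalog,
    control: bool = False,
) -> pd.Series:
    """Per-junction counts for one library (protocol or control mode)."""
    multiplier = config.multiplier_for(sample_id)
    pi_col = "pi_large" if group == "large" else "pi_small"
    keys = catalog.keys()
    site_index = pd.MultiIndex.from_tuples([(c, s) for (c, s, _strand) in keys])
    pi = truth[pi_col].reindex(site_index).to_numpy()
    if control:
        mean = np.full(len(keys), multiplier * config.depth_factor)
    else:
        mean = multiplier * config.depth_factor * pi
    rng = _stream(config.seed, "counts", sample_id)
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    return pd.Series(
        counts,
        index=pd.MultiIndex.from_tuples(keys, names=["contig", "site_start", "strand"]),
        name=sample_id,
    )


def _read_window(
    genome: Mapping[str, str],
    catalog: JunctionCatalog,
    junction: Junction,
    next_cut: int | None,
    prev_cut: int | None,
    read_length: int,
) -> tuple[int, int] | None:
    """Genome window [start, end) covered by a read from this junction."""
    contig_len = len(genome[junction.contig_id])
    s = junction.site_start
    if junction.strand == "+":
        end_limit = next_cut if next_cut is not None else contig_len
        end = min(s + read_length, end_limit)
        return (s, end) if end - s >= 4 else None
    start_limit = prev_cut if prev_cut is not None else 0
    start = max(s + 4 - read_length, start_limit)
    return (start, s + 4) if s + 4 - start >= 4 else None


def emit_reads(
    counts: pd.Series,
    genome: Mapping[str, str],
    catalog: JunctionCatalog,
    config: SimConfig,
    fastq_path: str | Path,
    sam_path: str | Path,
    sample_id: str | None = None,
) -> int:
    """Write FASTQ reads and a truth SAM for one library's count vector.

    Every read starts with CCGG (the reconstituted junction) and extends to
    ``read_length`` bases or the fragment boundary, whichever is shorter;
    reads that would fall below ``min_read_length`` are not emitted (size
    selection removes such fragments).  Returns the number of reads written.
    """
    sample = sample_id or (counts.name or "sample")
    qual_char = chr(config.phred_quality + 33)
    err_rng = _stream(config.seed, "errors", str(sample))

    # fragment boundaries per contig: cut positions (site_start + 1), sorted
    cuts: dict[str, list[int]] = {}
    for j in catalog:
        if j.strand == "+":
            cuts.setdefault(j.contig_id, []).append(j.site_start + 1)
    for v in cuts.values():
        v.sort()

    n_written = 0
    with open(fastq_path, "w") as fq, open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        for contig, seq in genome.items():
            sam.write(f"@SQ\tSN:{contig}\tLN:{len(seq)}\n")
        for j in catalog:
            c = int(counts.loc[(j.contig_id, j.site_start, j.strand)])
            if c == 0:
                continue
            contig_cuts = cuts.get(j.contig_id, [])
            i = np.searchsorted(contig_cuts, j.site_start + 1)
            nxt = contig_cuts[i + 1] if i + 1 < len(contig_cuts) else None
            prv = contig_cuts[i - 1] if i > 0 else None
            window = _read_window(genome, catalog, j, nxt, prv, config.read_length)
            if window is None or window[1] - window[0] < config.min_read_length:
                continue
            start, end = window
            ref_seq = genome[j.contig_id][start:end]
            length = end - start
            flag = 0 if j.strand == "+" else 16
            for k in range(c):
                stored = ref_seq
                if config.error_rate > 0:
                    stored = _mutate(stored, config.error_rate, err_rng)
                bio = stored if j.strand == "+" else reverse_complement(stored)
                name = f"{sample}:{j.contig_id}:{j.site_start}:{j.strand}:{k}"
                fq.write(f"@{name}\n{bio}\n+\n{qual_char * length}\n")
                sam.write(
                    f"{name}\t{flag}\t{j.contig_id}\t{start + 1}\t255\t{length}M\t"
                    f"*\t0\t0\t{stored}\t{qual_char * length}\n"
                )
                n_written += 1
    return n_written


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_gene_models(
    genome: Mapping[str, str],
    config: SimConfig,
    gene_length: int = 6000,
    gap: int = 4000,
    n_exons: int = 3,
) -> str:
    """A simple GFF3 gene annotation over a simulated genome.

    Genes alternate strand along each contig, each with ``n_exons`` equal
    exons separated by introns, leaving intergenic gaps in between — enough
    structure to exercise every annotation category.  Returns GFF3 text.
    """
    rng = _stream(config.seed, "genes")
    lines = ["##gff-version 3"]
    gene_no = 0
    for contig, seq in genome.items():
        pos = int(rng.integers(gap // 2, gap))
        strand_flip = 0
        while pos + gene_length + gap < len(seq):
            gene_no += 1
            gid = f"gene{gene_no}"
            strand = "+" if strand_flip % 2 == 0 else "-"
            strand_flip += 1
            start, end = pos + 1, pos + gene_length  # GFF is 1-based inclusive
            lines.append(
                f"{contig}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
            )
            lines.append(
                f"{contig}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gid}.t1;Parent={gid}"
            )
            exon_len = gene_length // (2 * n_exons - 1)
            for e in range(n_exons):
                e_start = start + e * 2 * exon_len
                e_end = min(e_start + exon_len - 1, end)
                lines.append(
                    f"{contig}\tsim\texon\t{e_start}\t{e_end}\t.\t{strand}\t.\t"
                    f"ID={gid}.e{e + 1};Parent={gid}.t1"
                )
            pos += gene_length + gap
    return "\n".join(lines) + "\n"


def default_sample_sheet(config: SimConfig, include_control: bool = True) -> pd.DataFrame:
    """Sample sheet matching the study layout: BL1..BLn, SL1..SLn, C1."""
    rows = []
    for i in range(config.n_per_group):
        rows.append({"sample_id": f"BL{i + 1}", "group": "large", "is_control": False})
    for i in range(config.n_per_group):
        rows.append({"sample_id": f"SL{i + 1}", "group": "small", "is_control": False})
    if include_control:
        rows.append({"sample_id": "C1", "group": "control", "is_control": True})
    return pd.DataFrame(rows).set_index("sample_id")


def study_design_config(seed: int = 0, **overrides) -> SimConfig:
    """A SimConfig emulating the published study's depth structure.

    Library size multipliers are the real libraries' raw-read depths scaled
    to a mean of 1 over the ten biological samples; the control's multiplier
    reflects equal-volume sequencing: its second digestion is omitted so its
    reads spread over ~every fragment, giving per-junction depth comparable
    to the protocol libraries despite a similar lane share.
    """
    raw = {
        "BL1": 29_951_172, "BL2": 64_951_163, "BL3": 46_520_470,
        "BL4": 65_123_992, "BL5": 56_155_408,
        "SL1": 21_105_349, "SL2": 27_287_570, "SL3": 7_105_158,
        "SL4": 24_225_784, "SL5": 12_690_867,
    }
    mean_depth = float(np.mean(list(raw.values())))
    multipliers = {k: v / mean_depth for k, v in raw.items()}
    # control: mean count per junction ~ depth_factor * mean(pi) in protocol
    # libraries; equal-volume sequencing gives the control a similar total.
    cfg = SimConfig(seed=seed)
    a, b = cfg.baseline_level_params
    multipliers["C1"] = 2.26 * a / (a + b)
    defaults = dict(library_size_multipliers=multipliers, seed=seed)
    defaults.update(overrides)
    return replace(cfg, **defaults)


def simulate_study(
    config: SimConfig,
    outdir: str | Path,
    sheet: pd.DataFrame | None = None,
    write_reads: bool = True,
):
    """Generate a full synthetic study: genome, truth, counts, reads.

    Returns (genome, catalog, truth, counts DataFrame, sample sheet); files
    are written under ``outdir`` (FASTA, truth TSV, per-library FASTQ + SAM).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    sites = scan_recognition_sites(genome)
    catalog = enumerate_junctions(sites, {c: len(s) for c, s in genome.items()})
    truth = plant_truth(catalog, config)
    if sheet is None:
        sheet = default_sample_sheet(config)
    write_fasta(genome, outdir / "genome.fa")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    columns = {}
    for sample_id, row in sheet.iterrows():
        counts = simulate_counts(
            truth, sample_id, row["group"], config, catalog,
            control=bool(row["is_control"]),
        )
        columns[sample_id] = counts
        if write_reads:
            emit_reads(
                counts, genome, catalog, config,
                outdir / f"{sample_id}.fastq", outdir / f"{sample_id}.sam",
                sample_id=sample_id,
            )
    count_df = pd.DataFrame(columns)
    count_df.to_csv(outdir / "true_counts.tsv", sep="\t")
    sheet.to_csv(outdir / "samples.tsv", sep="\t")
    return genome, catalog, truth, count_df, sheet
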
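import numpy as np
import pandas as pd
import pytest

from rrhp.annotate import (
    GeneModel,
    annotate_site,
    batch_annotate,
    build_index,
    parse_gene_models,
    read_bed6,
    signed_tss_distance,
    write_bed6,
)

GFF = """\
##gff-version 3
chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1
chr1\tsrc\texon\t1801\t2000\t.\t+\t.\tID=geneA.e2;Parent=geneA.t1
chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tID=geneB
"""


@pytest.fixture()
def models(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(GFF)
    return parse_gene_models(gff)


def test_gff_coordinates_convert_to_zero_based(models):
    a = next(m for m in models if m.gene_id == "geneA")
    assert (a.start, a.end, a.strand) == (1000, 2000, "+")
    assert a.tss == 1000
    assert a.exons == [(1000, 1200), (1800, 2000)]


def test_minus_strand_tss_is_the_right_end(models):
    b = next(m for m in models if m.gene_id == "geneB")
    assert b.tss == 5999
    assert b.tes == 5000
    # exonless gene: whole span treated as one exon
    assert b.exons == [(5000, 6000)]


def test_signed_distance_is_strand_aware(models):
    a = next(m for m in models if m.gene_id == "geneA")
    b = next(m for m in models if m.gene_id == "geneB")
    assert signed_tss_distance(800, a) == -200      # upstream of + gene
    assert signed_tss_distance(1100, a) == 100
    assert signed_tss_distance(6100, b) == -101     # upstream of - gene
    assert signed_tss_distance(5900, b) == 99


def test_promoter_window_upstream_of_plus_tss(models):
    index = build_index(models)
    rec = annotate_site("chr1", 800, index)
    assert rec.category == "promoter-TSS"
    assert rec.nearest_gene == "geneA"
    assert rec.distance_to_tss == -200


def test_priority_exon_inside_gene_outside_windows(models):
    index = build_index(models)
    rec = annotate_site("chr1", 1150, index)
    # 1150 is within the promoter window (+100 of TSS)? no: TSS=1000, window
    # ends at 1100, so the exon wins
    assert rec.category == "exon"


def test_intron_between_exons(models):
    index = build_index(models)
    rec = annotate_site("chr1", 1500, index)
    assert rec.category == "intron"
    assert rec.nearest_gene == "geneA"


def test_tts_window_around_termination_site(models):
    index = build_index(models)
    rec = annotate_site("chr1", 2050, index)
    assert rec.category == "TTS"


def test_far_site_is_intergenic_with_nearest_gene(models):
    index = build_index(models)
    rec = annotate_site("chr1", 50_000, index)
    assert rec.category == "intergenic"
    assert rec.nearest_gene == "geneB"
    rec2 = annotate_site("chrUn", 10, index)
    assert rec2.category == "intergenic" and rec2.nearest_gene is None


def test_every_site_gets_exactly_one_category(models):
    index = build_index(models)
    rng = np.random.default_rng(0)
    for pos in rng.integers(0, 60_000, 500):
        rec = annotate_site("chr1", int(pos), index)
        assert rec.category in {"promoter-TSS", "TTS", "exon", "intron", "intergenic"}


def brute_force_category(position, models, promoter=(-1000, 100), tts=(-100, 1000)):
    """Linear-scan oracle mirroring the priority rule."""

    def in_window(anchor, strand, window):
        rel = position - anchor if strand == "+" else anchor - position
        return window[0] <= rel <= window[1]

    for category, check in [
        ("promoter-TSS", lambda m: in_window(m.tss, m.strand, promoter)),
        ("TTS", lambda m: in_window(m.tes, m.strand, tts)),
        ("exon", lambda m: any(lo <= position < hi for lo, hi in m.exons)),
        ("intron", lambda m: m.start <= position < m.end),
    ]:
        if any(check(m) for m in models):
            return category
    return "intergenic"


def test_interval_tree_agrees_with_linear_scan_on_random_sites():
    rng = np.random.default_rng(42)
    models = []
    pos = 500
    for i in range(20):
        strand = "+" if i % 2 == 0 else "-"
        exons = [(pos, pos + 300), (pos + 900, pos + 1200)]
        models.append(GeneModel(f"g{i}", "chr1", strand, pos, pos + 1200, exons))
        pos += int(rng.integers(1500, 4000))
    index = build_index(models)
    for position in rng.integers(0, pos + 5000, 1000):
        rec = annotate_site("chr1", int(position), index)
        assert rec.category == brute_force_category(int(position), models), position


def test_bed6_round_trip_with_numeric_strand_codes(tmp_path):
    calls = pd.DataFrame(
        {"q": [0.001, 0.02, 0.04]},
        index=pd.MultiIndex.from_tuples(
            [("chr1", 10, "+"), ("chr1", 50, "-"), ("chr2", 7, "+")],
            names=["contig", "site_start", "strand"],
        ),
    )
    path = tmp_path / "dhmc.bed"
    write_bed6(calls, path)
    lines = path.read_text().splitlines()
    assert [ln.split("\t")[3] for ln in lines] == ["1", "2", "3"]
    assert lines[0].split("\t")[:3] == ["chr1", "10", "11"]
    back = read_bed6(path)
    assert list(back["strand"]) == ["+", "-", "+"]
    # the 0/1 dialect reads back to the same strands
    numeric = "\n".join(
        ln.replace("\t+", "\t0").replace("\t-", "\t1") for ln in lines
    )
    path2 = tmp_path / "numeric.bed"
    path2.write_text(numeric + "\n")
    back2 = read_bed6(path2)
    assert list(back2["strand"]) == list(back["strand"])


def test_duplicate_peak_ids_rejected(tmp_path):
    path = tmp_path / "dup.bed"
    path.write_text("chr1\t1\t2\tx\t.\t+\nchr1\t5\t6\tx\t.\t+\n")
    with pytest.raises(ValueError, match="unique"):
        read_bed6(path)


def test_batch_annotation_tally_sums_and_is_order_invariant(models):
    bed = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5,
            "start": [800, 1150, 1500, 2050, 30_000],
            "end": [801, 1151, 1501, 2051, 30_001],
            "peak_id": ["1", "2", "3", "4", "5"],
            "score": ["."] * 5,
            "strand": ["+"] * 5,
        }
    )
    frame, tally = batch_annotate(bed, models)
    assert tally == {
        "promoter-TSS": 1, "TTS": 1, "exon": 1, "intron": 1, "intergenic": 1,
    }
    assert sum(tally.values()) == len(bed)
    shuffled = bed.sample(frac=1, random_state=1)
    frame2, _ = batch_annotate(shuffled, models)
    merged = frame.set_index("peak_id")["category"]
    merged2 = frame2.set_index("peak_id")["category"]
    pd.testing.assert_series_equal(merged.sort_index(), merged2.sort_index())
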
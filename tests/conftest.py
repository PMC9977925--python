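import numpy as np
import pandas as pd
import pytest

from rrhp.digest import RecognitionSite, enumerate_junctions
from rrhp.quantify import CountMatrix
from rrhp.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        genome_length=80_000,
        n_contigs=2,
        target_site_count=150,
        n_per_group=2,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    """A fully materialized synthetic study (genome, truth, reads, SAMs)."""
    outdir = tmp_path_factory.mktemp("study")
    genome, catalog, truth, counts, sheet = simulate_study(small_config, outdir)
    return {
        "config": small_config,
        "outdir": outdir,
        "genome": genome,
        "catalog": catalog,
        "truth": truth,
        "counts": counts,
        "sheet": sheet,
    }


def toy_catalog(n_sites: int, spacing: int = 200, contig: str = "chr1"):
    sites = [RecognitionSite(contig, 100 + i * spacing) for i in range(n_sites)]
    return enumerate_junctions(sites, {contig: 100 + n_sites * spacing + 200})


def make_matrix(counts: np.ndarray, n_large: int = 5, n_small: int = 5,
                controls: int = 0) -> CountMatrix:
    """CountMatrix from a plain array (rows = sites, columns = libraries)."""
    names = (
        [f"BL{i+1}" for i in range(n_large)]
        + [f"SL{i+1}" for i in range(n_small)]
        + [f"C{i+1}" for i in range(controls)]
    )
    frame = pd.DataFrame(
        np.asarray(counts),
        columns=names,
        index=pd.MultiIndex.from_tuples(
            [("chr1", 100 + 200 * i, "+") for i in range(len(counts))],
            names=["contig", "site_start", "strand"],
        ),
    )
    samples = pd.DataFrame(
        {
            "group": ["large"] * n_large + ["small"] * n_small + ["control"] * controls,
            "is_control": [False] * (n_large + n_small) + [True] * controls,
        },
        index=pd.Index(names, name="sample_id"),
    )
    return CountMatrix(frame, samples)
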
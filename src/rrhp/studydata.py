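"""Published summary tables of the profiled Nile tilapia RRHP study.

These are inputs, not results: the morphometrics drive the sample-size
calculation, and the per-library sequencing summary anchors the synthetic
generator's depth structure and the documented aggregate checks (total
biological reads, CCGG capture percentage).
"""

from __future__ import annotations

import io

import pandas as pd

# Morphometrics of the ten full-sib females at sampling (5 months old).
# Size code B = large, S = small.
_MORPHOMETRICS_TSV = """\
sample_id\tsize_code\tweight_g\ttotal_length_cm\tstandard_length_cm
BL1\tB\t512\t29\t24
BL2\tB\t634\t30.2\t25.5
BL3\tB\t587\t29.5\t24.5
BL4\tB\t584\t28.5\t23.5
BL5\tB\t556\t29\t23.7
SL1\tS\t191\t21.4\t17.5
SL2\tS\t113\t17.8\t14
SL3\tS\t138\t18.6\t15
SL4\tS\t192\t21.6\t17.7
SL5\tS\t129\t19.3\t15.7
"""

# Per-library sequencing output.  The control library was sequenced once in
# each flow cell (C1a/C1b) and merged after the flow-cell check.
_LIBRARY_SUMMARY_TSV = """\
sample_id\tgroup\traw_reads\ttotal_5hmc\tunique_5hmc
C1a\tcontrol\t45994060\t22618039\t611908
C1b\tcontrol\t34339125\t16324747\t556289
BL1\tlarge\t29951172\t4702129\t411812
BL2\tlarge\t64951163\t15790930\t517979
BL3\tlarge\t46520470\t17040820\t478241
BL4\tlarge\t65123992\t27719382\t544846
BL5\tlarge\t56155408\t18040871\t534659
SL1\tsmall\t21105349\t3441132\t371621
SL2\tsmall\t27287570\t7637187\t383449
SL3\tsmall\t7105158\t2466658\t279178
SL4\tsmall\t24225784\t6106860\t389376
SL5\tsmall\t12690867\t3898492\t318951
"""

# Genome-wide catalogue sizes and the filtering cascade over the ten
# biological libraries.
TOTAL_CCGG_SITES = 1_613_446
UNIQUE_5HMC_ACROSS_SAMPLES = 1_096_820
SITES_AFTER_ZERO_FILTER = 405_605
SITES_AFTER_MEDIAN_FILTER = 138_000
YMAX = 19
N_DHMC = 2_677
N_DHMC_UP_IN_LARGE = 2_237


def morphometrics() -> pd.DataFrame:
    """Weight and length of the ten individuals, indexed by sample id."""
    return pd.read_csv(io.StringIO(_MORPHOMETRICS_TSV), sep="\t").set_index("sample_id")


def library_summary() -> pd.DataFrame:
    """Raw reads, junction-assigned reads and covered sites per library."""
    return pd.read_csv(io.StringIO(_LIBRARY_SUMMARY_TSV), sep="\t").set_index("sample_id")


def group_weights() -> tuple[list[float], list[float]]:
    """(large, small) body weights in grams, in table order."""
    m = morphometrics()
    return (
        m.loc[m["size_code"] == "B", "weight_g"].tolist(),
        m.loc[m["size_code"] == "S", "weight_g"].tolist(),
    )
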
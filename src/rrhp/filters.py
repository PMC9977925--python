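"""The two-step abundance filter that defines the analysis-ready site set.

Step one removes a site when at least ``max_zero_samples`` biological
libraries have a zero count — eliminating sites with no evidence of
hydroxymethylation in either group.  Step two computes the global median of
the remaining count matrix (Ymax) and removes a site when at least
``max_below_median`` libraries fall strictly below it.  Control libraries
measure library complexity, not 5hmC, and take part in neither filter nor
the median.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .quantify import CountMatrix


@dataclass
class FilterParams:
    max_zero_samples: int = 6
    max_below_median: int = 6
    median_override: float | None = None


@dataclass
class FilterReport:
    input_sites: int = 0
    after_zero_filter: int = 0
    ymax_used: float = 0.0
    after_median_filter: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def zero_count_filter(matrix: CountMatrix, params: FilterParams) -> CountMatrix:
    """Drop sites with >= max_zero_samples zero counts among biological libraries."""
    zeros = (matrix.biological == 0).sum(axis=1)
    return matrix.subset_sites(zeros < params.max_zero_samples)


def compute_global_median(matrix: CountMatrix) -> float:
    """Median over every entry of the biological count matrix (Ymax).

    Even cardinality yields the mean of the two central order statistics.
    """
    values = matrix.biological.to_numpy().ravel()
    if values.size == 0:
        return 0.0
    return float(np.median(values))


def median_filter(matrix: CountMatrix, ymax: float, params: FilterParams) -> CountMatrix:
    """Drop sites where >= max_below_median libraries count strictly below ymax."""
    below = (matrix.biological < ymax).sum(axis=1)
    return matrix.subset_sites(below < params.max_below_median)


def apply_filters(
    matrix: CountMatrix, params: FilterParams | None = None
) -> tuple[CountMatrix, FilterReport]:
    """Zero filter, then global median (unless overridden), then median filter."""
    params = params or FilterParams()
    report = FilterReport(input_sites=len(matrix.counts))
    stage1 = zero_count_filter(matrix, params)
    report.after_zero_filter = len(stage1.counts)
    ymax = (
        params.median_override
        if params.median_override is not None
        else compute_global_median(stage1)
    )
    report.ymax_used = float(ymax)
    stage2 = median_filter(stage1, ymax, params)
    report.after_median_filter = len(stage2.counts)
    return stage2, report
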
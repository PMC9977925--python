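"""Two-group sample-size calculation for a quantitative endpoint.

    n = 2 * (SD * (z_alpha + z_power) / d)^2

where SD is the standard deviation over the pooled individuals (population
form, divisor N), d the absolute difference between group means, z_alpha the
two-sided standard normal quantile at level alpha and z_power the quantile
at the target power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class PowerInputs:
    weights_group_a: Sequence[float]
    weights_group_b: Sequence[float]
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if len(self.weights_group_a) < 2 or len(self.weights_group_b) < 2:
            raise ValueError("each group needs at least 2 values")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")


def power_sample_size(inputs: PowerInputs) -> float:
    """Per-group sample size, reported to 2 decimals."""
    a = np.asarray(inputs.weights_group_a, dtype=float)
    b = np.asarray(inputs.weights_group_b, dtype=float)
    d = abs(a.mean() - b.mean())
    if d == 0:
        raise ValueError("group means are equal; n is undefined (d = 0)")
    sd = np.concatenate([a, b]).std(ddof=0)
    z_alpha = stats.norm.ppf(1 - inputs.alpha / 2)
    z_power = stats.norm.ppf(inputs.power)
    n = 2.0 * (sd * (z_alpha + z_power) / d) ** 2
    return round(float(n), 2)
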
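"""Two-sample t-test power and per-group sample size (noncentral t).

The design computation: given a mean difference ``delta`` and a common SD
``sd`` (effect size d = delta/sd), find the smallest continuous per-group n
for which the equal-n two-sample t test attains the target power.  Solved
exactly under the noncentral-t distribution by bracketed root finding, so
fractional sample sizes (e.g. 8.4) are reported as-is; use ``ceil=True``
for a practical integer design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, stats


@dataclass(frozen=True)
class PowerSpec:
    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80
    sides: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (self.alpha < self.power < 1.0):
            raise ValueError("power must be in (alpha, 1)")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.delta == 0:
            raise ValueError("delta must be nonzero")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")

    @property
    def effect_size(self) -> float:
        return abs(self.delta) / self.sd


def power_at_n(spec: PowerSpec, n: float) -> float:
    """Achieved power of the equal-n two-sample t test at per-group size n."""
    if n <= 1:
        raise ValueError("n per group must exceed 1 (df = 2n - 2 > 0)")
    df = 2.0 * n - 2.0
    ncp = spec.effect_size * math.sqrt(n / 2.0)
    if spec.sides == 2:
        tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        return float(
            1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
        )
    tcrit = stats.t.ppf(1.0 - spec.alpha, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp))


def sample_size_per_group(spec: PowerSpec, ceil: bool = False) -> float:
    """Smallest per-group n achieving the target power; fractional by default."""
    lo, hi = 1.01, 2.0
    while power_at_n(spec, hi) < spec.power:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("power target unattainable within n <= 1e9")
    n = optimize.brentq(
        lambda x: power_at_n(spec, x) - spec.power, lo, hi, xtol=1e-10
    )
    return float(math.ceil(n)) if ceil else float(n)
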
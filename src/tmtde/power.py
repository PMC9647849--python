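"""Sample-size analysis for the two-sample t-test via the noncentral t.

Given the smallest mean difference worth detecting (delta, on the log2
scale), the per-group SD (sigma), a significance level and a target
power, solves for the (possibly fractional) per-group n at which the
two-sided pooled t-test with df = 2n - 2 and noncentrality
d * sqrt(n/2), d = delta/sigma, reaches the target power.  The noncentral
t is used exactly — a normal approximation is visibly off at very small
significance levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import optimize, stats


def effect_size(delta: float, sigma: float) -> float:
    """Cohen's d = delta / sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return delta / sigma


@dataclass
class PowerSpec:
    alpha: float = 1e-4
    power: float = 0.8
    sigma: float = 0.208
    delta: float = 0.585
    sides: str = "two"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.alpha >= self.power:
            raise ValueError("alpha must be smaller than the target power")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.delta == 0:
            raise ValueError("delta must be nonzero")
        if self.sides not in ("two", "one"):
            raise ValueError("sides must be 'two' or 'one'")

    @property
    def d(self) -> float:
        return effect_size(abs(self.delta), self.sigma)


def achieved_power(n: float, spec: PowerSpec) -> float:
    """Power of the t-test at per-group size n (fractional n allowed)."""
    df = 2.0 * n - 2.0
    nc = spec.d * math.sqrt(n / 2.0)
    if spec.sides == "two":
        tc = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        # lower tail written as sf with negated noncentrality: exact by
        # symmetry and numerically stable far out in the tail
        return float(stats.nct.sf(tc, df, nc) + stats.nct.sf(tc, df, -nc))
    tc = stats.t.ppf(1.0 - spec.alpha, df)
    return float(stats.nct.sf(tc, df, nc))


@dataclass
class SampleSizeResult:
    n: float
    n_ceil: int
    achieved_power: float

    def __float__(self) -> float:
        return self.n


N_MIN, N_MAX = 2.0, 1e6


def sample_size(spec: PowerSpec) -> SampleSizeResult:
    """Per-group sample size reaching the target power.

    Monotone root-finding on n in [2, 1e6]; the returned fractional n
    satisfies |power(n) - target| < 1e-8.  Raises if the target power is
    unattainable within the bounds.
    """
    f = lambda n: achieved_power(n, spec) - spec.power
    if f(N_MIN) >= 0:
        return SampleSizeResult(N_MIN, int(N_MIN), achieved_power(N_MIN, spec))
    if f(N_MAX) < 0:
        raise ValueError("target power unattainable for n <= 1e6 per group")
    n = optimize.brentq(f, N_MIN, N_MAX, xtol=1e-10, rtol=8.9e-16)
    return SampleSizeResult(float(n), math.ceil(n), achieved_power(n, spec))
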
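"""Analytic power for two-sample MR, in the style of the mRnd calculator.

The pooled MR estimate behaves asymptotically like a normal variate whose
non-centrality is driven by the outcome sample size N, the variance in the
exposure explained by the instruments (R^2_gx), and the causal effect. Power
of the two-sided level-alpha test is then

    power = Phi(-z_{1-a/2} + sqrt(NCP)) + Phi(-z_{1-a/2} - sqrt(NCP))

with NCP = N * R^2_gx * beta^2 for a continuous outcome in SD units.

For a binary outcome the causal odds ratio is first attenuated to the
linear-probability scale: with case fraction K, the slope of disease status
on the standardized exposure is approximately b = K(1-K) ln(OR), the
residual variance of the 0/1 outcome is K(1-K) - b^2, and
NCP = N * R^2_gx * b^2 / (K(1-K) - b^2). This keeps power symmetric in
OR <-> 1/OR and exactly equal to alpha at OR = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


class PowerParameterError(ValueError):
    """Raised for out-of-range power-calculation inputs."""


@dataclass
class PowerQuery:
    """Inputs for an MR power calculation.

    ``effect`` is the hypothesized causal effect: beta in SD/SD units for a
    continuous outcome, an odds ratio for a binary outcome (``case_fraction``
    then required).
    """

    n: int
    r2_gx: float
    effect: float
    case_fraction: float | None = None
    alpha: float = 0.05

    def validate(self, binary: bool) -> None:
        if self.n <= 0:
            raise PowerParameterError(f"sample size must be positive, got {self.n}")
        if not 0 < self.r2_gx < 1:
            raise PowerParameterError(f"r2_gx must lie in (0,1), got {self.r2_gx}")
        if not 0 < self.alpha < 1:
            raise PowerParameterError(f"alpha must lie in (0,1), got {self.alpha}")
        if binary:
            if self.effect <= 0:
                raise PowerParameterError(
                    f"odds ratio must be positive, got {self.effect}"
                )
            if self.case_fraction is None or not 0 < self.case_fraction < 1:
                raise PowerParameterError(
                    f"case_fraction must lie in (0,1), got {self.case_fraction}"
                )


def _power_from_ncp(ncp: float, alpha: float) -> float:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    root = math.sqrt(ncp)
    return float(stats.norm.cdf(-z + root) + stats.norm.cdf(-z - root))


def mr_power_continuous(q: PowerQuery) -> float:
    """Power for a continuous outcome; ``q.effect`` is beta on the SD scale."""
    q.validate(binary=False)
    ncp = q.n * q.r2_gx * q.effect**2
    return _power_from_ncp(ncp, q.alpha)


def mr_power_binary(q: PowerQuery) -> float:
    """Power for a binary outcome; ``q.effect`` is an odds ratio."""
    q.validate(binary=True)
    k = q.case_fraction
    b = k * (1.0 - k) * math.log(q.effect)
    var_y = k * (1.0 - k) - b * b
    if var_y <= 0:
        return 1.0  # effect so large the linear approximation saturates
    ncp = q.n * q.r2_gx * b * b / var_y
    return _power_from_ncp(ncp, q.alpha)
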
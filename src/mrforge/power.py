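"""Statistical power for MR with a binary outcome.

Uses the standard normal-approximation (noncentrality) formula behind the
mRnd-style calculators: with outcome sample size N, case fraction K,
instrument variance explained R^2 and alternative odds ratio OR, the causal
log-odds estimate has approximate standard error
1 / sqrt(N * R^2 * K * (1 - K)), so the two-sided test at level alpha has

    power = Phi( sqrt(N * R^2 * K(1-K)) * |ln OR| - z_{1-alpha/2} ).

Power rises with each of N, R^2 and |ln OR|; the minimum detectable OR at a
target power is obtained by monotone root-finding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import optimize, stats

from .errors import InvalidInputError

FORMULA_NAME = "binary-outcome noncentrality approximation (mRnd-style)"


@dataclass(frozen=True)
class PowerInput:
    """Inputs for the binary-outcome MR power calculation."""

    n_total: float       # outcome study size (cases + controls)
    case_fraction: float  # K, proportion of cases
    r2: float            # exposure variance explained by the instruments
    alpha: float = 0.05  # two-sided type-I error
    or_alt: float = 1.0  # alternative odds ratio per unit exposure

    def __post_init__(self):
        if self.n_total <= 0:
            raise InvalidInputError("n_total must be > 0")
        for name in ("case_fraction", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InvalidInputError(f"{name} must be in (0, 1), got {v}")
        if not (0 <= self.r2 < 1):
            raise InvalidInputError(f"r2 must be in [0, 1), got {self.r2}")
        if not self.or_alt > 0:
            raise InvalidInputError(f"or_alt must be > 0, got {self.or_alt}")


def mr_power(inp: PowerInput) -> float:
    """Power of the two-sided causal test under the given alternative.

    At ``or_alt = 1`` (or r2 = 0) there is nothing to detect and the value
    degenerates to the one-tail rejection probability alpha/2 (a warning is
    emitted for r2 = 0 rather than an exception).
    """
    if inp.r2 == 0:
        warnings.warn("r2 = 0: instruments explain no variance; power is the "
                      "null rejection rate alpha/2", stacklevel=2)
    z_crit = stats.norm.ppf(1 - inp.alpha / 2)
    ncp = math.sqrt(inp.n_total * inp.r2 * inp.case_fraction * (1 - inp.case_fraction))
    return float(stats.norm.cdf(ncp * abs(math.log(inp.or_alt)) - z_crit))


def detectable_or(
    n_total: float,
    case_fraction: float,
    r2: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> float:
    """Smallest OR > 1 detectable at ``target_power``, to relative tol 1e-8."""
    if not (alpha < target_power < 1):
        raise InvalidInputError(
            f"target_power must be in (alpha, 1), got {target_power} with alpha={alpha}"
        )
    base = PowerInput(n_total, case_fraction, r2, alpha)
    if base.r2 == 0:
        raise InvalidInputError("r2 = 0: no power is attainable at any OR")

    def gap(log_or: float) -> float:
        inp = PowerInput(n_total, case_fraction, r2, alpha, math.exp(log_or))
        return mr_power(inp) - target_power

    hi = 1e-6
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise InvalidInputError("target power unattainable at any finite OR")
    log_or = optimize.brentq(gap, 0.0, hi, rtol=1e-10, xtol=1e-12)
    return float(math.exp(log_or))
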
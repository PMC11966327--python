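"""Moment-matched sampling distributions for probabilistic sensitivity analysis.

Probabilities and utilities are given beta distributions, costs gamma
distributions, each matched to the base-case mean and to a standard
deviation recovered from the printed 95% interval under a normal
approximation: sd = (upper - lower) / (2 * 1.96).  Parameters without a
range collapse to point masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import stats

__all__ = [
    "BetaDistribution",
    "GammaDistribution",
    "PointMass",
    "PsaDistribution",
    "InfeasibleDistributionError",
    "beta_from_mean_ci",
    "gamma_from_mean_range",
    "sd_from_interval",
]

#: Width of a 95% normal interval in standard deviations (2 * 1.96).
_Z95_WIDTH = 3.92


class InfeasibleDistributionError(ValueError):
    """The requested mean/spread cannot be represented by the family."""


def sd_from_interval(low: float, high: float) -> float:
    """Standard deviation implied by a normal-approximation 95% interval."""
    if high < low:
        raise ValueError(f"interval upper bound {high} below lower bound {low}")
    return (high - low) / _Z95_WIDTH


@dataclass(frozen=True)
class PointMass:
    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def sd(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@dataclass(frozen=True)
class BetaDistribution:
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise InfeasibleDistributionError(
                f"beta shape parameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        s = self.alpha + self.beta
        return float(np.sqrt(self.alpha * self.beta / (s * s * (s + 1.0))))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)

    def scipy(self) -> stats.rv_continuous:
        return stats.beta(self.alpha, self.beta)


@dataclass(frozen=True)
class GammaDistribution:
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise InfeasibleDistributionError(
                f"gamma parameters must be positive, got ({self.shape}, {self.scale})"
            )

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.shape) * self.scale)

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, self.scale, size=size)

    def scipy(self) -> stats.rv_continuous:
        return stats.gamma(self.shape, scale=self.scale)


PsaDistribution = Union[PointMass, BetaDistribution, GammaDistribution]


def beta_from_mean_ci(mean: float, ci_low: float, ci_high: float) -> PsaDistribution:
    """Beta distribution matching ``mean`` and the sd implied by the 95% CI.

    Method of moments: with nu = mean*(1-mean)/var - 1, alpha = mean*nu and
    beta = (1-mean)*nu.  A degenerate interval yields a point mass; a spread
    too wide for the beta family (var >= mean*(1-mean)) is an error.
    """
    if ci_low == ci_high:
        return PointMass(mean)
    if not 0.0 < mean < 1.0:
        raise InfeasibleDistributionError(
            f"beta moment matching needs 0 < mean < 1, got {mean}"
        )
    var = sd_from_interval(ci_low, ci_high) ** 2
    if var >= mean * (1.0 - mean):
        raise InfeasibleDistributionError(
            f"variance {var:.6g} infeasible for a beta with mean {mean}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return BetaDistribution(mean * nu, (1.0 - mean) * nu)


def gamma_from_mean_range(mean: float, low: float, high: float) -> PsaDistribution:
    """Gamma distribution matching ``mean`` and the sd implied by the range."""
    if low == high:
        return PointMass(mean)
    if mean <= 0.0:
        raise InfeasibleDistributionError(
            f"gamma moment matching needs mean > 0, got {mean}"
        )
    sd = sd_from_interval(low, high)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return GammaDistribution(shape, scale)
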
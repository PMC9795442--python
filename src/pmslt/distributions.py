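"""BMI exposure distributions on the clipped support [15, 50] kg/m^2.

The population's BMI in each stratum is summarised by a single parametric
distribution (right-skewed lognormal by default, normal as an alternative),
clipped to the support on which the dose-response curves are defined and
renormalised. Vectorised density/CDF helpers operate on whole stratum
lattices at once; the scalar :class:`BMIDistribution` is the user-facing
object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .types import BMI_MAX, BMI_MIN, OVERWEIGHT_CUTOFF

_SQRT2PI = np.sqrt(2.0 * np.pi)

MEAN_LOW = 15.0
MEAN_HIGH = 45.0


def lognormal_params(mean, sd):
    """(mu, sigma) of the underlying normal from the distribution's mean/sd."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def _raw_pdf(x, mean, sd, family: str):
    x = np.asarray(x, dtype=float)
    if family == "lognormal":
        mu, sigma = lognormal_params(mean, sd)
        z = (np.log(x) - mu) / sigma
        return np.exp(-0.5 * z * z) / (x * sigma * _SQRT2PI)
    if family == "normal":
        z = (x - np.asarray(mean, dtype=float)) / np.asarray(sd, dtype=float)
        return np.exp(-0.5 * z * z) / (np.asarray(sd, dtype=float) * _SQRT2PI)
    raise ValueError(f"unknown family {family!r}")


def _raw_cdf(x, mean, sd, family: str):
    x = np.asarray(x, dtype=float)
    if family == "lognormal":
        mu, sigma = lognormal_params(mean, sd)
        return ndtr((np.log(x) - mu) / sigma)
    if family == "normal":
        return ndtr((x - np.asarray(mean, dtype=float)) / np.asarray(sd, dtype=float))
    raise ValueError(f"unknown family {family!r}")


def support_mass(mean, sd, family: str):
    """Unclipped probability mass on [BMI_MIN, BMI_MAX] (the renormaliser)."""
    return _raw_cdf(BMI_MAX, mean, sd, family) - _raw_cdf(BMI_MIN, mean, sd, family)


def clipped_mass(low, high, mean, sd, family: str):
    """Mass of the clipped, renormalised density on [low, high] (vectorised)."""
    lo = np.maximum(low, BMI_MIN)
    hi = np.minimum(high, BMI_MAX)
    num = _raw_cdf(hi, mean, sd, family) - _raw_cdf(lo, mean, sd, family)
    return np.clip(num, 0.0, None) / support_mass(mean, sd, family)


def overweight_mass(mean, sd, family: str):
    """Clipped-density mass at or above the overweight cutoff (vectorised)."""
    return clipped_mass(OVERWEIGHT_CUTOFF, BMI_MAX, mean, sd, family)


@dataclass(frozen=True)
class BMIDistribution:
    """A stratum's BMI distribution, clipped and renormalised to [15, 50].

    Parameters
    ----------
    family : {"lognormal", "normal"}
        Parametric family of the *unclipped* distribution.
    mean, sd : float
        Mean and standard deviation (kg/m^2) of the unclipped distribution;
        the mean must lie in (15, 45) and sd must be positive.
    """

    family: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ValueError("family must be 'lognormal' or 'normal'")
        if not (MEAN_LOW < self.mean < MEAN_HIGH):
            raise ValueError(f"mean {self.mean} outside ({MEAN_LOW}, {MEAN_HIGH})")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    # the clipped, renormalised density -------------------------------
    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= BMI_MIN) & (x <= BMI_MAX)
        dens = np.where(inside, _raw_pdf(np.clip(x, BMI_MIN, BMI_MAX), self.mean, self.sd, self.family), 0.0)
        return dens / support_mass(self.mean, self.sd, self.family)

    def mass(self, low: float, high: float) -> float:
        return float(clipped_mass(low, high, self.mean, self.sd, self.family))

    def overweight_prevalence(self) -> float:
        return float(overweight_mass(self.mean, self.sd, self.family))

    def with_mean(self, mean: float) -> "BMIDistribution":
        return BMIDistribution(self.family, float(mean), self.sd)


@dataclass(frozen=True)
class UniformExposure:
    """A uniform exposure distribution on [low, high] within the BMI support.

    Used for the theoretical-minimum-risk (TMREL) counterfactual: the whole
    population relocated uniformly onto a low-risk BMI range.
    """

    low: float = 20.0
    high: float = 25.0

    def __post_init__(self) -> None:
        if not (BMI_MIN <= self.low < self.high <= BMI_MAX):
            raise ValueError("uniform exposure bounds must satisfy 15 <= low < high <= 50")

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x >= self.low) & (x <= self.high), 1.0 / (self.high - self.low), 0.0)

    def mass(self, low: float, high: float) -> float:
        lo = max(low, self.low)
        hi = min(high, self.high)
        return max(hi - lo, 0.0) / (self.high - self.low)

    def overweight_prevalence(self) -> float:
        return self.mass(OVERWEIGHT_CUTOFF, BMI_MAX)


@dataclass(frozen=True)
class PointExposure:
    """A point-mass exposure (everyone at one BMI); the degenerate TMREL choice."""

    at: float = 22.5

    def __post_init__(self) -> None:
        if not (BMI_MIN <= self.at <= BMI_MAX):
            raise ValueError("point exposure must lie inside the BMI support")
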
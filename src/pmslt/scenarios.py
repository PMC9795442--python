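"""BMI exposure trajectories for business-as-usual and counterfactual scenarios.

Year 0 of every trajectory is the shared baseline; scenario changes apply to
simulation years 1..horizon (calendar 2021-2030 for the default ten-year
horizon), with per-stratum means moving linearly over the horizon:

* BAU continues each stratum's observed yearly mean drift;
* S1 halves the yearly drift;
* S2 freezes the distribution at its baseline;
* S3 lowers each stratum's terminal overweight prevalence by a target
  fraction (default 6.7%, interpreted as a relative reduction), solving for
  the terminal mean with the sd held fixed (a shape-preserving shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .distributions import MEAN_HIGH, MEAN_LOW, BMIDistribution, overweight_mass
from .types import AGES, N_AGES, N_SEXES, SEXES, AgeSexTable, BMITable

SCENARIO_NAMES = ("BAU", "S1_half_rate", "S2_freeze", "S3_reduce_prevalence")


@dataclass(frozen=True)
class ScenarioSpec:
    """Which counterfactual to build and with what settings."""

    name: str
    reduction_fraction: float = 0.067
    horizon_years: int = 10
    relative_reduction: bool = True  # False: subtract percentage points instead

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}; expected one of {SCENARIO_NAMES}")
        if self.name == "S3_reduce_prevalence" and not (0.0 < self.reduction_fraction < 1.0):
            raise ValueError("reduction_fraction must lie in (0, 1)")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be at least 1")


@dataclass
class BMITrajectory:
    """Per-stratum BMI distributions for simulation years 0..horizon.

    ``means`` and ``sds`` have shape (horizon + 1, 2 sexes, 81 ages).
    """

    scenario: ScenarioSpec
    family: str
    means: np.ndarray
    sds: np.ndarray

    @property
    def horizon(self) -> int:
        return self.means.shape[0] - 1

    def distribution(self, year: int, sex: str, age: int) -> BMIDistribution:
        from .types import age_index, sex_index
        s, a = sex_index(sex), age_index(age)
        return BMIDistribution(self.family, float(self.means[year, s, a]), float(self.sds[year, s, a]))

    def overweight_prevalence(self, year: int) -> np.ndarray:
        """Per-stratum overweight prevalence (2, 81) at a simulation year."""
        return overweight_mass(self.means[year], self.sds[year], self.family)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        prev = np.stack([self.overweight_prevalence(y) for y in range(self.horizon + 1)])
        for y in range(self.horizon + 1):
            for s_i, s in enumerate(SEXES):
                for a_i, a in enumerate(AGES):
                    recs.append((self.scenario.name, int(a), s, y,
                                 self.means[y, s_i, a_i], self.sds[y, s_i, a_i], prev[y, s_i, a_i]))
        return pd.DataFrame(recs, columns=["scenario", "age", "sex", "year", "mean", "sd",
                                           "overweight_prev"])


def project_bau(baseline: BMITable, annual_mean_delta: AgeSexTable, horizon: int = 10) -> BMITrajectory:
    """Continue the observed yearly BMI mean drift linearly over the horizon."""
    if horizon < 1:
        raise ValueError("horizon must be at least 1")
    years = np.arange(horizon + 1, dtype=float)[:, None, None]
    means = baseline.mean.values[None] + years * annual_mean_delta.values[None]
    sds = np.broadcast_to(baseline.sd.values[None], means.shape).copy()
    spec = ScenarioSpec("BAU", horizon_years=horizon)
    return BMITrajectory(spec, baseline.family, means, sds)


def overweight_prevalence(dist: BMIDistribution) -> float:
    """Mass of the clipped, renormalised BMI density at or above 25 kg/m^2."""
    return dist.overweight_prevalence()


def mean_for_target_prevalence(dist: BMIDistribution, target: float) -> float:
    """The mean (sd fixed) at which overweight prevalence hits ``target``.

    Overweight prevalence is strictly increasing in the mean, so the root is
    unique; solved by bracketing bisection to |prevalence error| < 1e-8.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target prevalence must lie in (0, 1)")

    def gap(m: float) -> float:
        return overweight_mass(m, dist.sd, dist.family) - target

    lo, hi = MEAN_LOW + 1e-6, MEAN_HIGH - 1e-6
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(f"target prevalence {target} unattainable for mean in (15, 45)")
    m = brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14)
    if abs(gap(m)) > 1e-8:  # pragma: no cover - brentq converges far tighter
        raise ArithmeticError("prevalence solver did not converge")
    return float(m)


def _solve_terminal_means(bau: BMITrajectory, spec: ScenarioSpec) -> np.ndarray:
    """Per-stratum terminal means achieving the S3 prevalence target."""
    base_means = bau.means[0]
    sds = bau.sds[0]
    prev0 = overweight_mass(base_means, sds, bau.family)
    if spec.relative_reduction:
        target = (1.0 - spec.reduction_fraction) * prev0
    else:
        target = prev0 - spec.reduction_fraction
    if (target <= 0).any() or (target >= 1).any():
        raise ValueError("S3 target prevalence outside (0, 1) for some stratum")
    out = np.empty_like(base_means)
    for s_i in range(N_SEXES):
        for a_i in range(N_AGES):
            dist = BMIDistribution(bau.family, float(base_means[s_i, a_i]), float(sds[s_i, a_i]))
            out[s_i, a_i] = mean_for_target_prevalence(dist, float(target[s_i, a_i]))
    return out


def apply_scenario(bau: BMITrajectory, spec: ScenarioSpec) -> BMITrajectory:
    """Derive a counterfactual trajectory from the BAU one.

    All scenarios agree with BAU at year 0. S1 halves every year's mean
    increment; S2 holds the baseline distribution; S3 interpolates linearly
    from the baseline mean to the solved terminal mean.
    """
    H = bau.horizon
    means = bau.means.copy()
    if spec.name == "BAU":
        pass
    elif spec.name == "S1_half_rate":
        means = means[0][None] + 0.5 * (means - means[0][None])
    elif spec.name == "S2_freeze":
        means = np.broadcast_to(means[0][None], means.shape).copy()
    elif spec.name == "S3_reduce_prevalence":
        terminal = _solve_terminal_means(bau, spec)
        frac = (np.arange(H + 1, dtype=float) / H)[:, None, None]
        means = means[0][None] * (1.0 - frac) + terminal[None] * frac
    return BMITrajectory(spec, bau.family, means, bau.sds.copy())


def standard_trajectories(baseline: BMITable, annual_mean_delta: AgeSexTable,
                          horizon: int = 10, reduction_fraction: float = 0.067
                          ) -> dict[str, BMITrajectory]:
    """The four study trajectories keyed by scenario name."""
    bau = project_bau(baseline, annual_mean_delta, horizon)
    out = {"BAU": bau}
    for name in SCENARIO_NAMES[1:]:
        spec = ScenarioSpec(name, reduction_fraction=reduction_fraction, horizon_years=horizon)
        out[name] = apply_scenario(bau, spec)
    return out
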
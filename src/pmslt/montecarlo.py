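"""Monte Carlo propagation of parameter uncertainty to 95% uncertainty intervals.

Each draw perturbs the model inputs — relative risks from lognormals whose
median is the central RR and whose log-scale sd comes from the published CI,
baseline BMI means from normals, and disease rates by per-stratum gamma
factors — then reruns the full engine for the requested pair of runs. 95%
uncertainty intervals are empirical 2.5th/97.5th percentiles (linear
interpolation) across draws; the point estimate is the unperturbed central
run. Draws are a deterministic function of (seed, draw index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import BurdenResult, EngineConfig, MSLTModel, attributable_burden, prevented_burden
from .scenarios import ScenarioSpec, apply_scenario, project_bau
from .types import AgeSexTable, BMITable, DiseaseRates, ModelInputs, SEXES

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ParameterDistributions:
    """Families and hyperparameters of the input uncertainty distributions.

    Relative risks: lognormal with median equal to the central RR and
    ln-scale sd (ln ci_high - ln ci_low) / (2 * 1.96). Baseline BMI means:
    normal with standard error ``exposure_mean_se`` kg/m^2. Rates
    (incidence, remission, case fatality): multiplicative gamma factors with
    unit mean and coefficient of variation ``rate_cv``, independent across
    diseases and strata. ``share_rr_draws_within_disease`` moves all of a
    disease's RR rows (e.g. age bands) with one common draw.
    """

    exposure_mean_se: float = 0.1
    rate_cv: float = 0.05
    n_draws: int = 5000
    seed: int = 0
    share_rr_draws_within_disease: bool = False
    perturb_rr: bool = True
    perturb_exposure: bool = True
    perturb_rates: bool = True

    def __post_init__(self) -> None:
        if self.exposure_mean_se < 0 or self.rate_cv < 0:
            raise ValueError("standard errors must be non-negative")
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")


def rr_log_sd(spec) -> float:
    """Log-scale sd of an RR implied by its 95% CI."""
    return (np.log(spec.ci_high) - np.log(spec.ci_low)) / (2.0 * Z_95)


def sample_inputs(base_inputs: ModelInputs, dists: ParameterDistributions,
                  draw_index: int) -> ModelInputs:
    """One perturbed input bundle; deterministic in (seed, draw_index)."""
    if draw_index >= dists.n_draws:
        raise ValueError("draw_index must be below n_draws")
    rng = np.random.default_rng([dists.seed, draw_index])
    out = base_inputs.copy()

    # relative risks
    new_rr = []
    shared: dict[str, float] = {}
    for spec in base_inputs.rr_table:
        sd = rr_log_sd(spec)
        if dists.perturb_rr and sd > 0:
            if dists.share_rr_draws_within_disease:
                z = shared.setdefault(spec.disease, float(rng.standard_normal()))
            else:
                z = float(rng.standard_normal())
            rr = float(spec.rr_per_5 * np.exp(sd * z))
            lo = min(rr, spec.ci_low * rr / spec.rr_per_5)
            hi = max(rr, spec.ci_high * rr / spec.rr_per_5)
            new_rr.append(replace(spec, rr_per_5=rr, ci_low=lo, ci_high=hi))
        else:
            if dists.perturb_rr:
                rng.standard_normal()  # keep the draw stream aligned
            new_rr.append(spec)
    out.rr_table = new_rr

    # baseline exposure means
    if dists.perturb_exposure:
        noise = rng.normal(0.0, dists.exposure_mean_se, size=out.bmi_baseline.mean.values.shape) \
            if dists.exposure_mean_se > 0 else 0.0
        means = np.clip(out.bmi_baseline.mean.values + noise, 15.5, 44.5)
        out.bmi_baseline = BMITable(out.bmi_baseline.family, AgeSexTable(means),
                                    out.bmi_baseline.sd)

    # rates: unit-mean gamma factors, independent across diseases and strata
    if dists.perturb_rates and dists.rate_cv > 0:
        shape = 1.0 / dists.rate_cv ** 2
        new_rates = []
        for rs in out.disease_rates:
            def factor():
                return rng.gamma(shape, 1.0 / shape, size=rs.incidence.values.shape)
            inc = AgeSexTable(rs.incidence.values * factor())
            rem = AgeSexTable(rs.remission.values * factor()) if rs.definition.has_remission \
                else rs.remission
            cf = AgeSexTable(rs.case_fatality.values * factor())
            new_rates.append(DiseaseRates(rs.definition, inc, rem, cf, rs.baseline_prevalence))
        out.disease_rates = new_rates
    return out


@dataclass
class UncertaintyResult:
    """Point estimates with empirical 95% uncertainty intervals.

    ``point`` is the central (unperturbed) run's burden; ``lower``/``upper``
    arrays share its (disease, sex, year) shape for both metrics. Totals are
    percentiles of the per-draw totals, not sums of cell percentiles.
    """

    point: BurdenResult
    lower_cases: np.ndarray
    upper_cases: np.ndarray
    lower_deaths: np.ndarray
    upper_deaths: np.ndarray
    total_cases_ui: tuple[float, float]
    total_deaths_ui: tuple[float, float]
    n_draws: int
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        recs = []
        b = self.point
        for m, pt, lo, hi in (("cases", b.cases, self.lower_cases, self.upper_cases),
                              ("deaths", b.deaths, self.lower_deaths, self.upper_deaths)):
            for d_i, d in enumerate(b.diseases):
                for s_i, s in enumerate(SEXES):
                    for y in range(b.horizon):
                        recs.append((m, d, s, y + 1, pt[d_i, s_i, y], lo[d_i, s_i, y], hi[d_i, s_i, y]))
        recs.append(("cases", "total", "both", 0, b.total_cases, *self.total_cases_ui))
        recs.append(("deaths", "total", "both", 0, b.total_deaths, *self.total_deaths_ui))
        return pd.DataFrame(recs, columns=["metric", "disease", "sex", "year",
                                           "point", "lo95", "hi95"])

    def summary(self) -> str:
        c_lo, c_hi = self.total_cases_ui
        d_lo, d_hi = self.total_deaths_ui
        return (f"total cases  {self.point.total_cases:,.0f} (95% UI {c_lo:,.0f}-{c_hi:,.0f})\n"
                f"total deaths {self.point.total_deaths:,.0f} (95% UI {d_lo:,.0f}-{d_hi:,.0f})\n"
                f"draws used {self.n_draws - self.n_excluded}/{self.n_draws}")


def percentile_interval(draws: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Empirical (2.5th, 97.5th) percentiles with linear interpolation."""
    lo = np.percentile(draws, 2.5, axis=axis, method="linear")
    hi = np.percentile(draws, 97.5, axis=axis, method="linear")
    return lo, hi


def _burden_for(inputs: ModelInputs, pair, config: EngineConfig) -> BurdenResult:
    """Run the engine for a (reference, comparison) scenario pair.

    ``pair`` is ``("bau", "tmrel")`` for attributable burden or
    ``("bau", ScenarioSpec)`` for prevented burden.
    """
    model = MSLTModel(inputs, config)
    bau = project_bau(inputs.bmi_baseline, inputs.annual_mean_delta, config.horizon)
    ref_name, cmp_spec = pair
    if ref_name != "bau":
        raise ValueError("the reference run of a pair must be 'bau'")
    bau_run = model.run(bau)
    if cmp_spec == "tmrel":
        return attributable_burden(bau_run, model.run("tmrel"))
    if isinstance(cmp_spec, ScenarioSpec):
        return prevented_burden(bau_run, model.run(apply_scenario(bau, cmp_spec)))
    raise TypeError("comparison must be 'tmrel' or a ScenarioSpec")


def run_monte_carlo(base_inputs: ModelInputs, pair, dists: ParameterDistributions,
                    config: EngineConfig | None = None,
                    max_exclusion_fraction: float = 0.01) -> UncertaintyResult:
    """Propagate input uncertainty through the full engine.

    Failed draws (e.g. a perturbed rate set implying negative other-cause
    mortality) are excluded and counted; more than
    ``max_exclusion_fraction`` exclusions is a hard error.
    """
    config = config or EngineConfig()
    point = _burden_for(base_inputs, pair, config)
    shape = point.cases.shape
    cases = np.empty((dists.n_draws,) + shape)
    deaths = np.empty((dists.n_draws,) + shape)
    excluded = []
    for k in range(dists.n_draws):
        try:
            perturbed = sample_inputs(base_inputs, dists, k)
            b = _burden_for(perturbed, pair, config)
            cases[k] = b.cases
            deaths[k] = b.deaths
        except (ValueError, ArithmeticError) as exc:
            excluded.append(k)
            logger.warning("draw %d excluded: %s", k, exc)
            cases[k] = np.nan
            deaths[k] = np.nan
    if len(excluded) > max_exclusion_fraction * dists.n_draws:
        raise RuntimeError(f"{len(excluded)} of {dists.n_draws} draws failed")
    keep = np.setdiff1d(np.arange(dists.n_draws), np.array(excluded, dtype=int))
    cases, deaths = cases[keep], deaths[keep]
    lo_c, hi_c = percentile_interval(cases)
    lo_d, hi_d = percentile_interval(deaths)
    tot_c = percentile_interval(cases.sum(axis=(1, 2, 3)))
    tot_d = percentile_interval(deaths.sum(axis=(1, 2, 3)))
    return UncertaintyResult(point, lo_c, hi_c, lo_d, hi_d,
                             (float(tot_c[0]), float(tot_c[1])),
                             (float(tot_d[0]), float(tot_d[1])),
                             dists.n_draws, len(excluded))
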
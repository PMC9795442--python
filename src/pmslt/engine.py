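"""The proportional multistate life table engine.

A main (all-cause) cohort life table runs alongside one four-state life
table per disease (healthy, diseased, dead from the disease, dead from other
causes). Disease inflow is modulated by lag-adjusted potential impact
fractions computed from the BMI exposure path of the run; disease
prevalence feeds back into the main table's all-cause mortality each annual
cycle (the "proportional" coupling), so cause-specific and total mortality
stay mutually consistent.

Transitions within a cycle use exact exponential competing-risk allocation:
with exit rates r_1..r_k the total exit probability is 1 - exp(-sum r_j),
apportioned to destinations proportionally to the rates. This is exact for
rates constant within the cycle and can never produce negative occupancy.

The population is open: a new age-20 cohort enters each calendar year,
scaled by a configurable growth factor; survivorship closes at age 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import PointExposure, UniformExposure
from .doseresponse import (
    DEFAULT_ANCHOR,
    LagSpec,
    build_risk_functions,
    mean_rr_lattice,
    mean_rr_uniform,
)
from .scenarios import BMITrajectory
from .types import (
    AGES,
    AGE_MIN,
    N_AGES,
    N_SEXES,
    SEXES,
    AgeSexTable,
    DiseaseRates,
    ModelInputs,
    MortalitySchedule,
)

REPORT_AGE_MAX = 79  # burden is reported for adults aged 20-79


# ---------------------------------------------------------------------------
# mortality decomposition
# ---------------------------------------------------------------------------

def decompose_mortality(all_cause: MortalitySchedule,
                        rates: Sequence[DiseaseRates]) -> AgeSexTable:
    """Residual other-cause mortality: all-cause minus disease excess.

    residual = all_cause - sum_d case_fatality_d * prevalence_d; raises a
    consistency error naming the first offending stratum if any residual
    would be negative.
    """
    excess = np.zeros((N_SEXES, N_AGES))
    for rs in rates:
        excess += rs.case_fatality.values * rs.baseline_prevalence.values
    residual = all_cause.rates.values - excess
    if (residual < 0).any():
        bad = np.argwhere(residual < 0)[0]
        raise ValueError(
            "disease excess mortality exceeds all-cause mortality at "
            f"age {AGES[bad[1]]}, sex {SEXES[bad[0]]}")
    return AgeSexTable(residual)


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def _competing_probs(*rates: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-destination transition probabilities for competing exit rates."""
    total = np.zeros_like(rates[0], dtype=float)
    for r in rates:
        total = total + r
    p_exit = -np.expm1(-total)
    safe = np.where(total > 0, total, 1.0)
    return tuple(p_exit * (r / safe) for r in rates)


def disease_transition(healthy, diseased, dead_disease, dead_other,
                       incidence, remission, case_fatality, other_cause):
    """One annual cycle of a four-state disease life table (vectorised).

    Returns the updated (healthy, diseased, dead_disease, dead_other); the
    four states conserve their sum exactly up to floating point.
    """
    p_h_d, p_h_o = _competing_probs(np.asarray(incidence, float), np.asarray(other_cause, float))
    p_d_h, p_d_f, p_d_o = _competing_probs(np.asarray(remission, float),
                                           np.asarray(case_fatality, float),
                                           np.asarray(other_cause, float))
    new_cases = healthy * p_h_d
    recovered = diseased * p_d_h
    disease_deaths = diseased * p_d_f
    h_other = healthy * p_h_o
    d_other = diseased * p_d_o
    healthy2 = healthy - new_cases - h_other + recovered
    diseased2 = diseased + new_cases - recovered - disease_deaths - d_other
    return healthy2, diseased2, dead_disease + disease_deaths, dead_other + h_other + d_other


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EngineConfig:
    """Structural settings of a projection run."""

    horizon: int = 10
    entrant_growth: float = 1.01  # yearly scaling of the entering age-20 cohort
    anchor: float = DEFAULT_ANCHOR
    tmrel: object = field(default_factory=UniformExposure)  # UniformExposure | PointExposure
    floor_rr_at_one: bool = False  # floor below-reference RR segments at 1 in PIFs
    pif_nodes: int = 64


@dataclass
class RunResult:
    """Outputs of one projection run (all arrays age-resolved, 20-100).

    ``incident_cases`` and ``disease_deaths`` have shape
    (n_diseases, 2 sexes, 81 ages, horizon); the year axis indexes
    simulation years 1..horizon. ``allcause_mortality_rate`` and
    ``morbidity`` (mean number of modelled conditions per person) have shape
    (2, 81, horizon).
    """

    diseases: tuple[str, ...]
    incident_cases: np.ndarray
    disease_deaths: np.ndarray
    allcause_mortality_rate: np.ndarray
    morbidity: np.ndarray
    alive: np.ndarray  # (2, 81, horizon + 1) survivorship history

    @property
    def horizon(self) -> int:
        return self.incident_cases.shape[-1]

    def reported(self, array: np.ndarray) -> np.ndarray:
        """Restrict an age-resolved output to the reported ages 20-79."""
        n_report = REPORT_AGE_MAX - AGE_MIN + 1
        return array[..., :n_report, :]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for d_i, d in enumerate(self.diseases):
            for s_i, s in enumerate(SEXES):
                for a_i, a in enumerate(AGES):
                    for y in range(self.horizon):
                        recs.append((d, s, int(a), y + 1,
                                     self.incident_cases[d_i, s_i, a_i, y],
                                     self.disease_deaths[d_i, s_i, a_i, y]))
        return pd.DataFrame(recs, columns=["disease", "sex", "age", "year",
                                           "incident_cases", "deaths"])


@dataclass
class BurdenResult:
    """Difference between two runs, aggregated over the reported ages 20-79.

    ``cases`` and ``deaths`` have shape (n_diseases, 2 sexes, horizon);
    the year axis indexes simulation years 1..horizon.
    """

    diseases: tuple[str, ...]
    cases: np.ndarray
    deaths: np.ndarray

    @property
    def horizon(self) -> int:
        return self.cases.shape[-1]

    @property
    def total_cases(self) -> float:
        # summed disease-by-disease so the total equals the sum of its
        # reported components exactly, not merely to rounding
        return float(sum(self.cases[i].sum() for i in range(len(self.diseases))))

    @property
    def total_deaths(self) -> float:
        return float(sum(self.deaths[i].sum() for i in range(len(self.diseases))))

    def yearly_totals(self, metric: str = "cases") -> np.ndarray:
        arr = self.cases if metric == "cases" else self.deaths
        return arr.sum(axis=(0, 1))

    def by_disease(self, metric: str = "cases") -> dict[str, float]:
        arr = self.cases if metric == "cases" else self.deaths
        return {d: float(arr[i].sum()) for i, d in enumerate(self.diseases)}

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for d_i, d in enumerate(self.diseases):
            for s_i, s in enumerate(SEXES):
                for y in range(self.horizon):
                    recs.append((d, s, y + 1, self.cases[d_i, s_i, y], self.deaths[d_i, s_i, y]))
        return pd.DataFrame(recs, columns=["disease", "sex", "year", "cases", "deaths"])

    def summary(self) -> str:
        lines = [f"{'disease':<28}{'cases':>14}{'deaths':>14}"]
        for d_i, d in enumerate(self.diseases):
            lines.append(f"{d:<28}{self.cases[d_i].sum():>14,.0f}{self.deaths[d_i].sum():>14,.0f}")
        lines.append(f"{'Total':<28}{self.total_cases:>14,.0f}{self.total_deaths:>14,.0f}")
        return "\n".join(lines)


def _difference(a: RunResult, b: RunResult) -> BurdenResult:
    if a.diseases != b.diseases or a.incident_cases.shape != b.incident_cases.shape:
        raise ValueError("runs have mismatched shapes; they must share all structural inputs")
    cases = a.reported(a.incident_cases - b.incident_cases).sum(axis=2)
    deaths = a.reported(a.disease_deaths - b.disease_deaths).sum(axis=2)
    return BurdenResult(a.diseases, cases, deaths)


def attributable_burden(factual: RunResult, tmrel_counterfactual: RunResult) -> BurdenResult:
    """Burden attributable to overweight: factual minus no-overweight run."""
    return _difference(factual, tmrel_counterfactual)


def prevented_burden(bau: RunResult, scenario: RunResult) -> BurdenResult:
    """Cases/deaths prevented or postponed by a scenario relative to BAU."""
    return _difference(bau, scenario)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class MSLTModel:
    """Proportional multistate life table model over a 10-year horizon.

    Built from a :class:`~pmslt.types.ModelInputs` bundle; ``run`` simulates
    one exposure path, and ``attributable``/``prevented`` return burden
    differences between runs.
    """

    def __init__(self, inputs: ModelInputs, config: EngineConfig | None = None):
        self.inputs = inputs
        self.config = config or EngineConfig()
        self.residual = decompose_mortality(inputs.mortality, inputs.disease_rates)
        names = tuple(r.definition.name for r in inputs.disease_rates)
        self.diseases = names
        self.risk = build_risk_functions(inputs.rr_table, names, self.config.anchor)
        self._betas = {n: self._effective_betas(n) for n in names}
        bmi = inputs.bmi_baseline
        self._ref_mean_rr = {
            n: mean_rr_lattice(bmi.mean.values, bmi.sd.values, bmi.family,
                               self._betas[n], self.config.anchor, self.config.pif_nodes)
            for n in names}

    def _effective_betas(self, name: str) -> np.ndarray:
        betas = self.risk[name].betas.copy()
        if self.config.floor_rr_at_one:
            betas = np.clip(betas, 0.0, None)
        return betas

    def _lag(self, name: str) -> LagSpec:
        d = dict(zip(self.diseases, self.inputs.disease_rates))[name].definition
        return LagSpec(d.lag_years, d.lag_form)

    # -- PIF tables ---------------------------------------------------
    def pif_table(self, exposure) -> np.ndarray:
        """Effective (lag-adjusted) PIFs, shape (n_dis, horizon, 2, 81).

        ``exposure`` is ``"baseline"`` (all PIFs zero), ``"tmrel"`` (the
        attributable-burden counterfactual) or a
        :class:`~pmslt.scenarios.BMITrajectory`; PIFs compare the exposure
        at each simulation year against the year-0 baseline distribution.
        """
        H = self.config.horizon
        pifs = np.zeros((len(self.diseases), H, N_SEXES, N_AGES))
        if exposure == "baseline":
            return pifs
        if not (exposure == "tmrel" or isinstance(exposure, BMITrajectory)):
            raise TypeError("exposure must be 'baseline', 'tmrel' or a BMITrajectory")
        if isinstance(exposure, BMITrajectory) and exposure.horizon < H:
            raise ValueError("trajectory horizon shorter than run horizon")
        for d_i, name in enumerate(self.diseases):
            betas = self._betas[name]
            if np.all(betas == 0.0):  # unit curve: exposure is irrelevant
                continue
            ref = self._ref_mean_rr[name]
            lag = self._lag(name).factor(np.arange(1, H + 1))
            if exposure == "tmrel":
                cf = np.broadcast_to(self._tmrel_mean_rr(betas), (H, N_SEXES, N_AGES))
            else:
                traj: BMITrajectory = exposure
                cf = mean_rr_lattice(traj.means[1:H + 1], traj.sds[1:H + 1], traj.family,
                                     betas, self.config.anchor, self.config.pif_nodes)
            pifs[d_i] = lag[:, None, None] * (1.0 - cf / ref)
        return pifs

    def _tmrel_mean_rr(self, betas: np.ndarray) -> np.ndarray:
        t = self.config.tmrel
        if isinstance(t, UniformExposure):
            return mean_rr_uniform(t.low, t.high, betas, self.config.anchor, self.config.pif_nodes)
        if isinstance(t, PointExposure):
            from .doseresponse import _log_rr
            return np.exp(_log_rr(np.array(t.at), betas, self.config.anchor))
        raise TypeError("tmrel must be UniformExposure or PointExposure")

    # -- running ------------------------------------------------------
    def run(self, exposure="baseline") -> RunResult:
        """Simulate one exposure path; see :meth:`pif_table` for choices."""
        return self.run_with_pifs(self.pif_table(exposure))

    def run_with_pifs(self, eff_pifs: np.ndarray) -> RunResult:
        """Core annual-cycle loop driven by a precomputed effective-PIF table."""
        H = self.config.horizon
        n_dis = len(self.diseases)
        if eff_pifs.shape != (n_dis, H, N_SEXES, N_AGES):
            raise ValueError("effective PIF table has the wrong shape")
        if (eff_pifs > 1.0).any():
            raise ValueError("PIF values must not exceed 1")

        pop = self.inputs.population.counts.values
        residual = self.residual.values
        inc = np.stack([r.incidence.values for r in self.inputs.disease_rates])
        rem = np.stack([r.remission.values for r in self.inputs.disease_rates])
        cfat = np.stack([r.case_fatality.values for r in self.inputs.disease_rates])
        prev0 = np.stack([r.baseline_prevalence.values for r in self.inputs.disease_rates])

        alive = pop.copy()
        healthy = pop[None] * (1.0 - prev0)
        diseased = pop[None] * prev0
        dead_dis = np.zeros_like(healthy)
        dead_oth = np.zeros_like(healthy)

        incident = np.zeros((n_dis, N_SEXES, N_AGES, H))
        deaths = np.zeros((n_dis, N_SEXES, N_AGES, H))
        mort_out = np.zeros((N_SEXES, N_AGES, H))
        morb_out = np.zeros((N_SEXES, N_AGES, H))
        alive_hist = np.zeros((N_SEXES, N_AGES, H + 1))
        alive_hist[..., 0] = alive

        entrants0 = pop[:, 0].copy()
        entrant_prev0 = prev0[:, :, 0].copy()

        for y in range(1, H + 1):
            track_alive = healthy + diseased
            prev = np.where(track_alive > 0, diseased / np.where(track_alive > 0, track_alive, 1.0), 0.0)
            m = residual + np.sum(cfat * prev, axis=0)
            mort_out[..., y - 1] = m
            morb_out[..., y - 1] = prev.sum(axis=0)

            for d_i in range(n_dis):
                i_eff = inc[d_i] * (1.0 - eff_pifs[d_i, y - 1])
                p_h_d, _ = _competing_probs(i_eff, residual)
                _, p_d_f, _ = _competing_probs(rem[d_i], cfat[d_i], residual)
                incident[d_i, ..., y - 1] = healthy[d_i] * p_h_d
                deaths[d_i, ..., y - 1] = diseased[d_i] * p_d_f
                healthy[d_i], diseased[d_i], dead_dis[d_i], dead_oth[d_i] = disease_transition(
                    healthy[d_i], diseased[d_i], dead_dis[d_i], dead_oth[d_i],
                    i_eff, rem[d_i], cfat[d_i], residual)
                if (healthy[d_i] < -1e-9).any() or (diseased[d_i] < -1e-9).any():
                    raise ArithmeticError(f"negative occupancy in {self.diseases[d_i]} track")

            alive = alive * np.exp(-m)

            # age everyone by one year; survivorship closes at age 100
            alive[:, 1:] = alive[:, :-1]
            for arr in (healthy, diseased, dead_dis, dead_oth):
                arr[:, :, 1:] = arr[:, :, :-1]

            entrants = entrants0 * self.config.entrant_growth ** y
            alive[:, 0] = entrants
            healthy[:, :, 0] = entrants[None, :] * (1.0 - entrant_prev0)
            diseased[:, :, 0] = entrants[None, :] * entrant_prev0
            dead_dis[:, :, 0] = 0.0
            dead_oth[:, :, 0] = 0.0

            alive_hist[..., y] = alive

        return RunResult(self.diseases, incident, deaths, mort_out, morb_out, alive_hist)

    # -- burden conveniences ------------------------------------------
    def attributable(self, trajectory) -> BurdenResult:
        """Attributable burden of overweight along a trajectory (vs TMREL)."""
        return attributable_burden(self.run(trajectory), self.run("tmrel"))

    def prevented(self, bau_trajectory, scenario_trajectory) -> BurdenResult:
        return prevented_burden(self.run(bau_trajectory), self.run(scenario_trajectory))
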
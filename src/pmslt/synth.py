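"""Seeded synthetic inputs: population, mortality, disease rates and BMI.

The generators emulate the *shape* of the data sources a national burden
projection draws on — an adult age pyramid, Gompertz-Makeham all-cause
mortality, age-increasing disease rates, right-skewed BMI distributions
whose means drift upward — without calibrating to any real country's
figures. Disease rate sets are made internally consistent with the life
table engine's own dynamics by a forward cohort recursion (standing in for
the usual DISMOD-style readjustment), so that with no intervention the
model's prevalence and all-cause mortality are stationary by construction.

`builtin_rr_table` packages the published relative risks per +5 kg/m^2 BMI
used for the 11 modelled diseases.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from . import engine as _engine
from .types import (
    AGES,
    AGE_MIN,
    N_AGES,
    N_SEXES,
    SEXES,
    AgeSexTable,
    BMITable,
    DiseaseDefinition,
    DiseaseRates,
    DISEASES,
    ModelInputs,
    MortalitySchedule,
    PopulationTable,
    RRSpec,
)

__all__ = [
    "generate_population",
    "generate_mortality_schedule",
    "generate_disease_rates",
    "generate_all_disease_rates",
    "generate_bmi_baseline",
    "default_annual_mean_delta",
    "builtin_rr_table",
    "default_inputs",
    "RateShape",
]


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def generate_population(total_size: float, seed: int, *, modal_age: int = 30,
                        decline_scale: float = 24.0, reference_year: int = 2020) -> PopulationTable:
    """Apportion ``total_size`` adults over the stratum lattice.

    Weights are flat up to ``modal_age`` and decay smoothly beyond it, so
    counts weakly decrease above the modal age. The seed jitters the sex
    split and the decay scale slightly; a fixed seed is fully reproducible.
    Integer apportionment uses the largest-remainder method so the counts
    sum exactly to ``total_size``.
    """
    if total_size <= 0:
        raise ValueError("total_size must be positive")
    rng = np.random.default_rng(seed)
    scale = decline_scale * float(np.exp(rng.normal(0.0, 0.03)))
    male_share = float(np.clip(0.49 + rng.normal(0.0, 0.004), 0.45, 0.55))

    ages = AGES.astype(float)
    w = np.where(ages <= modal_age, 1.0, np.exp(-((ages - modal_age) / scale) ** 2))
    shares = np.vstack([w * male_share, w * (1.0 - male_share)])
    shares /= shares.sum()

    raw = shares * float(total_size)
    counts = np.floor(raw)
    remainder = int(round(total_size - counts.sum()))
    if remainder > 0:
        frac = (raw - counts).ravel()
        top = np.argsort(frac)[::-1][:remainder]
        flat = counts.ravel()
        flat[top] += 1
        counts = flat.reshape(counts.shape)
    return PopulationTable(AgeSexTable(counts), reference_year)


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def generate_mortality_schedule(makeham_c: float = 8e-4, gompertz_b: float = 4e-5,
                                gompertz_theta: float = 0.105,
                                sex_multiplier: Mapping[str, float] | None = None) -> MortalitySchedule:
    """Gompertz-Makeham all-cause mortality: c + b*exp(theta*(age-20)).

    Identical for both sexes unless ``sex_multiplier`` (e.g. ``{"male": 1.3,
    "female": 0.8}``) is supplied.
    """
    if makeham_c < 0 or gompertz_theta < 0:
        raise ValueError("Gompertz-Makeham parameters must be non-negative")
    if gompertz_b <= 0:
        raise ValueError("gompertz_b must be positive")
    base = makeham_c + gompertz_b * np.exp(gompertz_theta * (AGES.astype(float) - AGE_MIN))
    mult = sex_multiplier or {}
    rows = [base * float(mult.get(s, 1.0)) for s in SEXES]
    return MortalitySchedule(AgeSexTable(np.vstack(rows)))


# ---------------------------------------------------------------------------
# disease rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateShape:
    """A smooth age-increasing rate curve: logistic rise from ``lo`` to ``hi``."""

    lo: float
    hi: float
    midpoint: float = 65.0
    width: float = 10.0

    def __post_init__(self) -> None:
        if self.lo < 0 or self.hi < self.lo:
            raise ValueError("need 0 <= lo <= hi")
        if self.width <= 0:
            raise ValueError("width must be positive")

    def values(self, ages: np.ndarray) -> np.ndarray:
        return self.lo + (self.hi - self.lo) * expit((ages - self.midpoint) / self.width)


def _shape_table(shape: RateShape | None, sex_factor: Mapping[str, float]) -> AgeSexTable:
    if shape is None:
        return AgeSexTable.zeros()
    ages = AGES.astype(float)
    rows = [shape.values(ages) * float(sex_factor.get(s, 1.0)) for s in SEXES]
    return AgeSexTable(np.vstack(rows))


def _consistent_prevalence(incidence: AgeSexTable, remission: AgeSexTable,
                           case_fatality: AgeSexTable, other_cause: AgeSexTable) -> AgeSexTable:
    """Forward cohort recursion: prevalence implied by the engine's own step.

    A cohort enters at age 20 disease-free; one annual engine transition per
    year of age yields the prevalence-by-age profile that is exactly
    stationary under the life table dynamics.
    """
    i, r = incidence.values, remission.values
    f, mu = case_fatality.values, other_cause.values
    prev = np.zeros((N_SEXES, N_AGES))
    h = np.ones(N_SEXES)
    d = np.zeros(N_SEXES)
    for a_i in range(N_AGES - 1):
        h, d, _, _ = _engine.disease_transition(
            h, d, np.zeros(N_SEXES), np.zeros(N_SEXES),
            i[:, a_i], r[:, a_i], f[:, a_i], mu[:, a_i])
        alive = h + d
        prev[:, a_i + 1] = np.where(alive > 0, d / np.where(alive > 0, alive, 1.0), 0.0)
    return AgeSexTable(prev)


def generate_disease_rates(definition: DiseaseDefinition, shape_params: Mapping[str, RateShape],
                           mortality: MortalitySchedule, burn_in_years: int = 80,
                           seed: int | None = None,
                           sex_factor: Mapping[str, float] | None = None) -> DiseaseRates:
    """Synthesize one disease's rate set, internally consistent with the engine.

    ``shape_params`` maps "incidence"/"case_fatality" (and "remission" for
    cancers) to :class:`RateShape` curves; ``seed`` applies a small
    multiplicative jitter to the curve levels; ``sex_factor`` scales the
    incidence by sex. Baseline prevalence is produced by the forward cohort
    recursion of the engine's own annual transition (the stand-in for a
    DISMOD-style consistency fit), iterating the other-cause residual to a
    fixed point so one further engine step reproduces the prevalence to well
    below 1e-6.
    """
    if burn_in_years < 50:
        raise ValueError("burn_in_years must be at least 50")
    sex_factor = dict(sex_factor or {})
    jitter = {"incidence": 1.0, "remission": 1.0, "case_fatality": 1.0}
    if seed is not None:
        rng = np.random.default_rng(seed)
        for k in jitter:
            jitter[k] = float(np.exp(rng.normal(0.0, 0.05)))

    def build(name: str, factor: Mapping[str, float]) -> AgeSexTable:
        shape = shape_params.get(name)
        if shape is None:
            return AgeSexTable.zeros()
        scaled = RateShape(shape.lo * jitter[name], shape.hi * jitter[name],
                           shape.midpoint, shape.width)
        return _shape_table(scaled, factor)

    incidence = build("incidence", sex_factor)
    remission = build("remission", {}) if definition.has_remission else AgeSexTable.zeros()
    case_fatality = build("case_fatality", {})

    # other-cause residual fixed point for the single-disease system
    residual = mortality.rates.copy()
    prev = AgeSexTable.zeros()
    for _ in range(min(burn_in_years, 60)):
        prev = _consistent_prevalence(incidence, remission, case_fatality, residual)
        new_resid = mortality.rates.values - case_fatality.values * prev.values
        if (new_resid < 0).any():
            bad = np.argwhere(new_resid < 0)[0]
            raise ValueError(
                f"{definition.name}: case fatality x prevalence exceeds all-cause mortality "
                f"at age {AGES[bad[1]]}, sex {SEXES[bad[0]]}")
        if np.max(np.abs(new_resid - residual.values)) < 1e-14:
            residual = AgeSexTable(new_resid)
            break
        residual = AgeSexTable(new_resid)
    return DiseaseRates(definition, incidence, remission, case_fatality, prev)


#: Default rate shapes and incidence sex factors for the 11 diseases
#: (events per person-year; plausible orders of magnitude for an adult
#: middle-income population, not calibrated to any real registry).
DEFAULT_DISEASE_SHAPES: dict[str, dict] = {
    "coronary_heart_disease": dict(
        shapes={"incidence": RateShape(1e-4, 9e-3, 68, 11),
                "case_fatality": RateShape(0.008, 0.07, 75, 10)},
        sex_factor={"male": 1.4, "female": 0.75}),
    "stroke": dict(
        shapes={"incidence": RateShape(6e-5, 8e-3, 72, 10),
                "case_fatality": RateShape(0.015, 0.09, 78, 9)},
        sex_factor={"male": 1.1, "female": 0.9}),
    "hypertensive_heart_disease": dict(
        shapes={"incidence": RateShape(2e-5, 2.5e-3, 72, 10),
                "case_fatality": RateShape(0.01, 0.05, 78, 10)},
        sex_factor={"male": 1.0, "female": 1.0}),
    "type2_diabetes": dict(
        shapes={"incidence": RateShape(8e-4, 9e-3, 52, 9),
                "case_fatality": RateShape(0.001, 0.008, 70, 12)},
        sex_factor={"male": 0.95, "female": 1.05}),
    "chronic_kidney_disease": dict(
        shapes={"incidence": RateShape(4e-4, 8e-3, 70, 11),
                "case_fatality": RateShape(0.002, 0.02, 75, 10)},
        sex_factor={"male": 0.9, "female": 1.1}),
    "cirrhosis": dict(
        shapes={"incidence": RateShape(8e-5, 1.2e-3, 58, 12),
                "case_fatality": RateShape(0.02, 0.08, 70, 12)},
        sex_factor={"male": 1.6, "female": 0.6}),
    "breast_cancer": dict(
        shapes={"incidence": RateShape(1e-4, 1.4e-3, 58, 10),
                "remission": RateShape(0.04, 0.06, 60, 15),
                "case_fatality": RateShape(0.01, 0.05, 70, 12)},
        sex_factor={"male": 0.01, "female": 1.0}),
    "colorectal_cancer": dict(
        shapes={"incidence": RateShape(2e-5, 1.6e-3, 72, 10),
                "remission": RateShape(0.03, 0.05, 60, 15),
                "case_fatality": RateShape(0.03, 0.10, 75, 10)},
        sex_factor={"male": 1.2, "female": 0.85}),
    "pancreas_cancer": dict(
        shapes={"incidence": RateShape(5e-6, 4e-4, 72, 9),
                "remission": RateShape(0.005, 0.01, 60, 15),
                "case_fatality": RateShape(0.25, 0.45, 70, 12)},
        sex_factor={"male": 1.1, "female": 0.9}),
    "kidney_cancer": dict(
        shapes={"incidence": RateShape(1e-5, 4e-4, 70, 10),
                "remission": RateShape(0.03, 0.05, 60, 15),
                "case_fatality": RateShape(0.03, 0.09, 75, 10)},
        sex_factor={"male": 1.3, "female": 0.8}),
    "liver_cancer": dict(
        shapes={"incidence": RateShape(8e-6, 3.5e-4, 70, 10),
                "remission": RateShape(0.01, 0.02, 60, 15),
                "case_fatality": RateShape(0.2, 0.35, 70, 12)},
        sex_factor={"male": 1.5, "female": 0.7}),
}


def generate_all_disease_rates(mortality: MortalitySchedule, seed: int | None = None,
                               diseases: Sequence[DiseaseDefinition] = DISEASES,
                               burn_in_years: int = 80) -> list[DiseaseRates]:
    """Generate all disease rate sets, jointly consistent with the engine.

    After per-disease generation, the shared other-cause residual
    (all-cause minus the sum of case-fatality x prevalence over diseases)
    is iterated to a joint fixed point so the whole bundle is stationary
    under the engine with `decompose_mortality`.
    """
    shapes = {d.name: DEFAULT_DISEASE_SHAPES[d.name] for d in diseases}
    jitters = {}
    for d in diseases:
        if seed is None:
            jitters[d.name] = None
        else:
            tag = zlib.crc32(d.name.encode()) % 2**31
            jitters[d.name] = int(np.random.default_rng([seed, tag]).integers(2**31))

    # initial per-disease pass against the raw all-cause schedule
    rate_sets = {d.name: generate_disease_rates(d, shapes[d.name]["shapes"], mortality,
                                                burn_in_years, jitters[d.name],
                                                shapes[d.name]["sex_factor"])
                 for d in diseases}

    # joint residual fixed point: prevalence of every disease recomputed
    # against the shared other-cause schedule until stationary
    residual = mortality.rates.values.copy()
    for _ in range(40):
        total_excess = sum(rs.case_fatality.values * rs.baseline_prevalence.values
                           for rs in rate_sets.values())
        new_resid = mortality.rates.values - total_excess
        if (new_resid < 0).any():
            bad = np.argwhere(new_resid < 0)[0]
            raise ValueError(
                "disease case fatality implies negative other-cause mortality at "
                f"age {AGES[bad[1]]}, sex {SEXES[bad[0]]}")
        delta = np.max(np.abs(new_resid - residual))
        residual = new_resid
        resid_table = AgeSexTable(residual)
        for name, rs in rate_sets.items():
            prev = _consistent_prevalence(rs.incidence, rs.remission, rs.case_fatality, resid_table)
            rate_sets[name] = DiseaseRates(rs.definition, rs.incidence, rs.remission,
                                           rs.case_fatality, prev)
        if delta < 1e-14:
            break
    return [rate_sets[d.name] for d in diseases]


# ---------------------------------------------------------------------------
# BMI
# ---------------------------------------------------------------------------

def generate_bmi_baseline(mean_by_stratum: AgeSexTable | None = None,
                          sd_by_stratum: AgeSexTable | None = None,
                          family: str = "lognormal") -> BMITable:
    """Baseline BMI distribution parameters per stratum.

    Defaults rise from ~24 kg/m^2 at age 20 to ~27.5 in late middle age and
    ease off at the oldest ages, with sd ~3.6-4.4 — a right-skewed profile
    whose population mean sits near 26 kg/m^2. Distributions are clipped and
    renormalised to [15, 50] when evaluated (see
    :class:`~pmslt.distributions.BMIDistribution`).
    """
    if mean_by_stratum is None:
        def mean_fn(ages, sex):
            base = 23.6 + 4.0 * expit((ages - 42.0) / 10.0) - 1.5 * expit((ages - 75.0) / 6.0)
            return base + (0.2 if sex == "male" else -0.2) * expit((45.0 - ages) / 10.0)
        mean_by_stratum = AgeSexTable.from_function(mean_fn)
    if sd_by_stratum is None:
        def sd_fn(ages, sex):
            return 3.6 + 0.5 * expit((ages - 50.0) / 10.0) + (0.3 if sex == "female" else 0.0)
        sd_by_stratum = AgeSexTable.from_function(sd_fn)
    if (sd_by_stratum.values <= 0).any():
        raise ValueError("BMI sd must be positive everywhere")
    m = mean_by_stratum.values
    if (m <= 15.0).any() or (m >= 45.0).any():
        raise ValueError("BMI means must lie in (15, 45)")
    return BMITable(family, mean_by_stratum, sd_by_stratum)


def default_annual_mean_delta() -> AgeSexTable:
    """Default yearly BMI mean drift (kg/m^2 per year) under continued trends.

    Larger among younger adults, tapering with age; population-average close
    to 0.16 kg/m^2/year (a decade-long rise of roughly 1.6 units).
    """
    def delta_fn(ages, sex):
        d = 0.20 - 0.0015 * (ages - 20.0)
        return d + (0.01 if sex == "female" else 0.0)
    return AgeSexTable.from_function(delta_fn)


# ---------------------------------------------------------------------------
# published relative-risk table
# ---------------------------------------------------------------------------

def builtin_rr_table() -> list[RRSpec]:
    """The packaged RR-per-5-BMI-units table for the 11 modelled diseases.

    Age-banded single slopes for coronary heart disease and stroke; two BMI
    segments (15-25, 25-50) for hypertensive heart disease, type 2 diabetes,
    chronic kidney disease and cirrhosis; cancer rows carry their published
    sex and age restrictions.
    """
    rows: list[RRSpec] = []

    def band(disease, lo, hi, rr, cl, ch, sex="both"):
        rows.append(RRSpec(disease, rr, cl, ch, sex_scope=sex, age_low=lo, age_high=hi))

    def seg(disease, blo, bhi, rr, cl, ch, sex="both"):
        rows.append(RRSpec(disease, rr, cl, ch, sex_scope=sex, bmi_low=blo, bmi_high=bhi))

    band("coronary_heart_disease", 35, 59, 1.50, 1.39, 1.62)
    band("coronary_heart_disease", 60, 69, 1.40, 1.32, 1.49)
    band("coronary_heart_disease", 70, 79, 1.31, 1.23, 1.40)
    band("coronary_heart_disease", 80, 89, 1.30, 1.17, 1.45)

    band("stroke", 35, 59, 1.76, 1.52, 2.04)
    band("stroke", 60, 69, 1.49, 1.34, 1.67)
    band("stroke", 70, 79, 1.33, 1.19, 1.48)
    band("stroke", 80, 89, 1.10, 0.94, 1.30)

    seg("hypertensive_heart_disease", 15, 25, 1.17, 0.77, 1.76)
    seg("hypertensive_heart_disease", 25, 50, 2.03, 1.75, 2.36)

    seg("type2_diabetes", 15, 25, 0.96, 0.59, 1.55)
    seg("type2_diabetes", 25, 50, 2.16, 1.89, 2.46)

    seg("chronic_kidney_disease", 15, 25, 1.14, 0.74, 1.77)
    seg("chronic_kidney_disease", 25, 50, 1.59, 1.27, 1.99)

    seg("cirrhosis", 15, 25, 0.73, 0.54, 1.00)
    seg("cirrhosis", 25, 50, 1.79, 1.54, 2.08)

    rows.append(RRSpec("breast_cancer", 1.12, 1.08, 1.16, sex_scope="female", age_low=61))
    rows.append(RRSpec("colorectal_cancer", 1.24, 1.20, 1.28, sex_scope="male"))
    rows.append(RRSpec("colorectal_cancer", 1.09, 1.05, 1.13, sex_scope="female"))
    rows.append(RRSpec("pancreas_cancer", 1.10, 1.07, 1.14))
    rows.append(RRSpec("kidney_cancer", 1.24, 1.20, 1.28, sex_scope="male"))
    rows.append(RRSpec("kidney_cancer", 1.09, 1.05, 1.13, sex_scope="female"))
    rows.append(RRSpec("liver_cancer", 1.47, 1.26, 1.71, age_low=35, age_high=79))
    return rows


# ---------------------------------------------------------------------------
# full default bundle
# ---------------------------------------------------------------------------

def default_inputs(seed: int = 0, total_population: float = 155_000_000) -> ModelInputs:
    """The full synthetic study fixture: one call, fully seeded."""
    population = generate_population(total_population, seed)
    mortality = generate_mortality_schedule(sex_multiplier={"male": 1.3, "female": 0.8})
    disease_rates = generate_all_disease_rates(mortality, seed=seed)
    bmi = generate_bmi_baseline()
    return ModelInputs(
        population=population,
        mortality=mortality,
        disease_rates=disease_rates,
        bmi_baseline=bmi,
        annual_mean_delta=default_annual_mean_delta(),
        rr_table=builtin_rr_table(),
    )
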
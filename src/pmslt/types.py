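"""Core domain types: the (age, sex) stratum lattice, rate tables and disease registry.

Every model input is indexed by single year of age 20–100 and sex. Tables are
stored as dense ``(2, 81)`` float arrays (sex x age) behind a thin wrapper so
the whole engine stays vectorised; CSV round-trips live in :mod:`pmslt.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AGE_MIN = 20
AGE_MAX = 100
AGES = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES = AGES.size
SEXES = ("male", "female")
N_SEXES = len(SEXES)

BMI_MIN = 15.0
BMI_MAX = 50.0
OVERWEIGHT_CUTOFF = 25.0

DISEASE_GROUPS = ("cardiovascular", "cancer", "diabetes", "chronic_kidney", "cirrhosis")


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


def age_index(age: int) -> int:
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}]")
    return int(age) - AGE_MIN


@dataclass(frozen=True)
class Stratum:
    """A single (age, sex) cell of the population lattice."""

    age: int
    sex: str

    def __post_init__(self) -> None:
        age_index(self.age)
        sex_index(self.sex)


class AgeSexTable:
    """Dense table over the full stratum lattice.

    Parameters
    ----------
    values : array-like, shape (2, 81)
        Row 0 is male, row 1 female; columns are ages 20..100.
    """

    __slots__ = ("values",)

    def __init__(self, values: np.ndarray):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (N_SEXES, N_AGES):
            raise ValueError(f"expected shape {(N_SEXES, N_AGES)}, got {arr.shape}")
        self.values = arr

    # -- constructors -------------------------------------------------
    @classmethod
    def zeros(cls) -> "AgeSexTable":
        return cls(np.zeros((N_SEXES, N_AGES)))

    @classmethod
    def full(cls, value: float) -> "AgeSexTable":
        return cls(np.full((N_SEXES, N_AGES), float(value)))

    @classmethod
    def from_function(cls, fn) -> "AgeSexTable":
        """Build from ``fn(age_array, sex) -> array`` evaluated per sex."""
        rows = [np.broadcast_to(np.asarray(fn(AGES.astype(float), s), dtype=float), (N_AGES,))
                for s in SEXES]
        return cls(np.vstack(rows))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str) -> "AgeSexTable":
        required = {"age", "sex", value_col}
        if not required.issubset(df.columns):
            raise ValueError(f"frame must have columns {sorted(required)}")
        tab = np.full((N_SEXES, N_AGES), np.nan)
        ages = df["age"].to_numpy(dtype=int)
        if ages.min() < AGE_MIN or ages.max() > AGE_MAX:
            raise ValueError("ages outside lattice bounds")
        for s_i, s in enumerate(SEXES):
            sub = df[df["sex"] == s]
            tab[s_i, sub["age"].to_numpy(dtype=int) - AGE_MIN] = sub[value_col].to_numpy(dtype=float)
        if np.isnan(tab).any():
            raise ValueError("stratum lattice has gaps: every (age, sex) must appear exactly once")
        if len(df) != N_SEXES * N_AGES:
            raise ValueError("stratum lattice has duplicates")
        return cls(tab)

    # -- access -------------------------------------------------------
    def __getitem__(self, key) -> float:
        age, sex = key
        return float(self.values[sex_index(sex), age_index(age)])

    def to_frame(self, value_col: str) -> pd.DataFrame:
        recs = []
        for s_i, s in enumerate(SEXES):
            for a_i, a in enumerate(AGES):
                recs.append((int(a), s, self.values[s_i, a_i]))
        return pd.DataFrame(recs, columns=["age", "sex", value_col])

    def copy(self) -> "AgeSexTable":
        return AgeSexTable(self.values.copy())

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, AgeSexTable) and np.array_equal(self.values, other.values)


@dataclass
class PopulationTable:
    """Person counts on the stratum lattice for a reference calendar year."""

    counts: AgeSexTable
    reference_year: int = 2020

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("population counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.values.sum())


@dataclass
class MortalitySchedule:
    """All-cause mortality rates (events per person-year) by stratum."""

    rates: AgeSexTable

    def __post_init__(self) -> None:
        if (self.rates.values < 0).any():
            raise ValueError("mortality rates must be non-negative")


@dataclass(frozen=True)
class DiseaseDefinition:
    """One modelled disease: its reporting group, remission flag and lag."""

    name: str
    group: str
    has_remission: bool = False
    lag_years: float = 5.0
    lag_form: str = "ramp"  # "ramp" | "step"

    def __post_init__(self) -> None:
        if self.group not in DISEASE_GROUPS:
            raise ValueError(f"unknown disease group {self.group!r}")
        if self.has_remission != (self.group == "cancer"):
            raise ValueError("remission is modelled for cancers and only cancers")
        if self.lag_years < 0:
            raise ValueError("lag_years must be non-negative")
        if self.lag_form not in ("ramp", "step"):
            raise ValueError("lag_form must be 'ramp' or 'step'")


def _cancer(name: str) -> DiseaseDefinition:
    return DiseaseDefinition(name, "cancer", has_remission=True, lag_years=10.0, lag_form="step")


#: The 11 BMI-related diseases modelled: three cardiovascular conditions,
#: type 2 diabetes, chronic kidney disease, cirrhosis and five cancers.
DISEASES: tuple[DiseaseDefinition, ...] = (
    DiseaseDefinition("coronary_heart_disease", "cardiovascular"),
    DiseaseDefinition("stroke", "cardiovascular"),
    DiseaseDefinition("hypertensive_heart_disease", "cardiovascular"),
    DiseaseDefinition("type2_diabetes", "diabetes"),
    DiseaseDefinition("chronic_kidney_disease", "chronic_kidney"),
    DiseaseDefinition("cirrhosis", "cirrhosis"),
    _cancer("breast_cancer"),
    _cancer("colorectal_cancer"),
    _cancer("pancreas_cancer"),
    _cancer("kidney_cancer"),
    _cancer("liver_cancer"),
)

DISEASE_BY_NAME: Mapping[str, DiseaseDefinition] = {d.name: d for d in DISEASES}


@dataclass
class DiseaseRates:
    """Incidence, remission, case-fatality and baseline prevalence for one disease."""

    definition: DiseaseDefinition
    incidence: AgeSexTable
    remission: AgeSexTable
    case_fatality: AgeSexTable
    baseline_prevalence: AgeSexTable

    def __post_init__(self) -> None:
        for name in ("incidence", "remission", "case_fatality"):
            if (getattr(self, name).values < 0).any():
                raise ValueError(f"{name} rates must be non-negative")
        prev = self.baseline_prevalence.values
        if (prev < 0).any() or (prev > 1).any():
            raise ValueError("baseline prevalence must lie in [0, 1]")
        if not self.definition.has_remission and (self.remission.values != 0).any():
            raise ValueError(f"{self.definition.name}: remission must be identically zero")

    def copy(self) -> "DiseaseRates":
        return DiseaseRates(
            self.definition,
            self.incidence.copy(),
            self.remission.copy(),
            self.case_fatality.copy(),
            self.baseline_prevalence.copy(),
        )


@dataclass(frozen=True)
class RRSpec:
    """A relative risk per +5 kg/m^2 BMI with its 95% CI and applicability.

    ``age_low``/``age_high`` restrict the curve to an age band (inclusive);
    ``bmi_low``/``bmi_high`` restrict it to a BMI segment. ``None`` means
    unrestricted. Strata outside the restriction receive the unit curve.
    """

    disease: str
    rr_per_5: float
    ci_low: float
    ci_high: float
    sex_scope: str = "both"  # "both" | "male" | "female"
    age_low: float | None = None
    age_high: float | None = None
    bmi_low: float | None = None
    bmi_high: float | None = None

    def __post_init__(self) -> None:
        if self.rr_per_5 <= 0:
            raise ValueError("rr_per_5 must be positive")
        if not (self.ci_low <= self.rr_per_5 <= self.ci_high):
            raise ValueError("require ci_low <= rr_per_5 <= ci_high")
        if self.sex_scope not in ("both", "male", "female"):
            raise ValueError("sex_scope must be both/male/female")

    def applies_to(self, sex: str, age: float) -> bool:
        if self.sex_scope != "both" and self.sex_scope != sex:
            return False
        if self.age_low is not None and age < self.age_low:
            return False
        if self.age_high is not None and age > self.age_high:
            return False
        return True


@dataclass
class BMITable:
    """Per-stratum BMI distribution parameters (one parametric family)."""

    family: str  # "lognormal" | "normal"
    mean: AgeSexTable
    sd: AgeSexTable

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal"):
            raise ValueError("family must be 'lognormal' or 'normal'")
        if (self.sd.values <= 0).any():
            raise ValueError("BMI sd must be positive everywhere")
        m = self.mean.values
        if (m <= BMI_MIN).any() or (m >= 45.0).any():
            raise ValueError("BMI means must lie in (15, 45)")

    def copy(self) -> "BMITable":
        return BMITable(self.family, self.mean.copy(), self.sd.copy())


@dataclass
class ModelInputs:
    """The complete input bundle a projection is built from."""

    population: PopulationTable
    mortality: MortalitySchedule
    disease_rates: Sequence[DiseaseRates]
    bmi_baseline: BMITable
    annual_mean_delta: AgeSexTable
    rr_table: Sequence[RRSpec]

    @property
    def diseases(self) -> tuple[DiseaseDefinition, ...]:
        return tuple(r.definition for r in self.disease_rates)

    def copy(self) -> "ModelInputs":
        return ModelInputs(
            population=PopulationTable(self.population.counts.copy(), self.population.reference_year),
            mortality=MortalitySchedule(self.mortality.rates.copy()),
            disease_rates=[r.copy() for r in self.disease_rates],
            bmi_baseline=self.bmi_baseline.copy(),
            annual_mean_delta=self.annual_mean_delta.copy(),
            rr_table=list(self.rr_table),
        )
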
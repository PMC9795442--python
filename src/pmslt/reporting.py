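"""Aggregation of burden results into report tables, plus sensitivity analyses.

Report tables group the 11 diseases into five groups (cardiovascular,
cancers, diabetes, chronic kidney disease, cirrhosis) with Men/Women/Total
columns. Sex and group totals are summed *before* rounding; cells are then
rounded half-away-from-zero to the nearest hundred, the convention of the
published national projection whose reference tables ship with the package
(``pmslt/data/*.csv``) for consistency checks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .engine import BurdenResult, EngineConfig, MSLTModel, attributable_burden
from .scenarios import project_bau
from .types import AgeSexTable, BMITable, DiseaseRates, ModelInputs

#: Disease -> report group mapping.
DEFAULT_GROUPING: Mapping[str, str] = {
    "coronary_heart_disease": "cardiovascular",
    "stroke": "cardiovascular",
    "hypertensive_heart_disease": "cardiovascular",
    "breast_cancer": "cancers",
    "colorectal_cancer": "cancers",
    "pancreas_cancer": "cancers",
    "kidney_cancer": "cancers",
    "liver_cancer": "cancers",
    "type2_diabetes": "diabetes",
    "chronic_kidney_disease": "chronic_kidney_disease",
    "cirrhosis": "cirrhosis",
}

GROUP_ORDER = ("cardiovascular", "cancers", "diabetes", "chronic_kidney_disease", "cirrhosis")


def round_to_hundred(x) -> np.ndarray:
    """Round half away from zero to the nearest hundred."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) / 100.0 + 0.5) * 100.0


@dataclass
class ReportTable:
    """A disease-group x sex burden table with pre-rounding internal sums.

    ``raw`` holds the unrounded cells; ``rounded`` the presentation values.
    Both have groups plus a Total row and Men/Women/Total columns, and
    satisfy Total = Men + Women (computed before rounding) in every row.
    """

    raw: pd.DataFrame
    rounded: pd.DataFrame

    def __str__(self) -> str:
        return self.rounded.to_string(float_format=lambda v: f"{v:,.0f}")


def aggregate_results(burden: BurdenResult, grouping: Mapping[str, str] = DEFAULT_GROUPING,
                      metric: str = "cases") -> ReportTable:
    """Sum a burden difference over years and ages into the report layout."""
    arr = burden.cases if metric == "cases" else burden.deaths
    unmapped = [d for d in burden.diseases if d not in grouping]
    if unmapped:
        raise ValueError(f"diseases missing from the grouping: {unmapped}")
    groups = [g for g in GROUP_ORDER if g in set(grouping.values())]
    rows = {}
    for g in groups:
        idx = [i for i, d in enumerate(burden.diseases) if grouping[d] == g]
        men = float(arr[idx, 0].sum())
        women = float(arr[idx, 1].sum())
        rows[g] = (men, women, men + women)
    men_t = sum(v[0] for v in rows.values())
    women_t = sum(v[1] for v in rows.values())
    rows["Total"] = (men_t, women_t, men_t + women_t)
    raw = pd.DataFrame.from_dict(rows, orient="index", columns=["Men", "Women", "Total"])
    return ReportTable(raw, raw.apply(round_to_hundred))


# ---------------------------------------------------------------------------
# published reference tables
# ---------------------------------------------------------------------------

def load_reference_table(which: str) -> pd.DataFrame:
    """Load a packaged published reference table.

    ``which`` is one of ``"attributable_cases"``, ``"attributable_deaths"``
    or ``"prevented_burden"`` — the attributable-burden and
    scenario-comparison tables of the published Brazilian 2021-2030
    projection, as printed (points and 95% UI bounds).
    """
    name = f"reference_{which}.csv"
    ref = importlib.resources.files("pmslt.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def sex_total_check(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute Men + Women per row and compare with the printed Total."""
    out = table.copy()
    out["men_plus_women"] = out["men"] + out["women"]
    out["matches_total"] = out["men_plus_women"] == out["total"]
    return out


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------

def _scale_table(tab: AgeSexTable, factor: float) -> AgeSexTable:
    return AgeSexTable(tab.values * factor)


def _variant_bmi(inputs: ModelInputs, factor: float) -> ModelInputs:
    out = inputs.copy()
    out.bmi_baseline = BMITable(out.bmi_baseline.family,
                                _scale_table(out.bmi_baseline.mean, factor),
                                out.bmi_baseline.sd)
    return out


def _variant_delta(inputs: ModelInputs, factor: float) -> ModelInputs:
    out = inputs.copy()
    out.annual_mean_delta = _scale_table(out.annual_mean_delta, factor)
    return out


def _variant_rr(inputs: ModelInputs, factor: float) -> ModelInputs:
    out = inputs.copy()
    out.rr_table = [replace(s, rr_per_5=s.rr_per_5 * factor,
                            ci_low=min(s.ci_low * factor, s.rr_per_5 * factor),
                            ci_high=max(s.ci_high * factor, s.rr_per_5 * factor))
                    for s in out.rr_table]
    return out


def _variant_incidence(inputs: ModelInputs, factor: float) -> ModelInputs:
    out = inputs.copy()
    out.disease_rates = [DiseaseRates(r.definition, _scale_table(r.incidence, factor),
                                      r.remission, r.case_fatality, r.baseline_prevalence)
                         for r in out.disease_rates]
    return out


#: variant name -> (input transform, engine-config transform)
SENSITIVITY_VARIANTS: Mapping[str, tuple[Callable, Callable]] = {
    "null": (lambda inp: inp, lambda cfg: cfg),
    "bmi_plus_10pct": (lambda inp: _variant_bmi(inp, 1.10), lambda cfg: cfg),
    "yearly_delta_plus_5pct": (lambda inp: _variant_delta(inp, 1.05), lambda cfg: cfg),
    "yearly_delta_minus_5pct": (lambda inp: _variant_delta(inp, 0.95), lambda cfg: cfg),
    "rr_plus_2pct": (lambda inp: _variant_rr(inp, 1.02), lambda cfg: cfg),
    "rr_minus_2pct": (lambda inp: _variant_rr(inp, 0.98), lambda cfg: cfg),
    "incidence_plus_2pct": (lambda inp: _variant_incidence(inp, 1.02), lambda cfg: cfg),
    "incidence_minus_2pct": (lambda inp: _variant_incidence(inp, 0.98), lambda cfg: cfg),
    "no_population_growth": (lambda inp: inp, lambda cfg: replace(cfg, entrant_growth=1.0)),
}


@dataclass
class SensitivityReport:
    """Percent change of total attributable burden per perturbation variant."""

    table: pd.DataFrame  # index: variant; columns: cases_pct_change, deaths_pct_change

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:+.2f}%")


def _attributable_totals(inputs: ModelInputs, config: EngineConfig) -> tuple[float, float]:
    model = MSLTModel(inputs, config)
    bau = project_bau(inputs.bmi_baseline, inputs.annual_mean_delta, config.horizon)
    burden = attributable_burden(model.run(bau), model.run("tmrel"))
    return burden.total_cases, burden.total_deaths


def run_sensitivity(inputs: ModelInputs, config: EngineConfig | None = None,
                    variants: Mapping[str, tuple[Callable, Callable]] = SENSITIVITY_VARIANTS
                    ) -> SensitivityReport:
    """Re-run the BAU attributable burden under each one-input perturbation.

    Each variant perturbs exactly one input family and reports
    100 * (variant - primary) / primary for total cases and deaths.
    """
    config = config or EngineConfig()
    base_cases, base_deaths = _attributable_totals(inputs, config)
    recs = {}
    for name, (f_inp, f_cfg) in variants.items():
        cases, deaths = _attributable_totals(f_inp(inputs), f_cfg(config))
        recs[name] = (100.0 * (cases - base_cases) / base_cases,
                      100.0 * (deaths - base_deaths) / base_deaths)
    table = pd.DataFrame.from_dict(recs, orient="index",
                                   columns=["cases_pct_change", "deaths_pct_change"])
    return SensitivityReport(table)
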
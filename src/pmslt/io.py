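"""CSV schemas for model inputs and outputs.

One row per stratum throughout: population.csv [age,sex,count];
mortality.csv [age,sex,rate]; disease_rates.csv
[disease,age,sex,incidence,remission,case_fatality,prevalence]; bmi.csv
[age,sex,family,mean,sd]; rr_table.csv
[disease,sex_scope,age_low,age_high,bmi_low,bmi_high,rr_per_5,ci_low,ci_high].
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    AgeSexTable,
    BMITable,
    DISEASE_BY_NAME,
    DiseaseRates,
    ModelInputs,
    MortalitySchedule,
    PopulationTable,
    RRSpec,
)


def write_population(pop: PopulationTable, path: Path) -> None:
    pop.counts.to_frame("count").to_csv(path, index=False)


def read_population(path: Path, reference_year: int = 2020) -> PopulationTable:
    return PopulationTable(AgeSexTable.from_frame(pd.read_csv(path), "count"), reference_year)


def write_mortality(m: MortalitySchedule, path: Path) -> None:
    m.rates.to_frame("rate").to_csv(path, index=False)


def read_mortality(path: Path) -> MortalitySchedule:
    return MortalitySchedule(AgeSexTable.from_frame(pd.read_csv(path), "rate"))


def write_disease_rates(rates: Sequence[DiseaseRates], path: Path) -> None:
    frames = []
    for rs in rates:
        df = rs.incidence.to_frame("incidence")
        df["remission"] = rs.remission.to_frame("v")["v"]
        df["case_fatality"] = rs.case_fatality.to_frame("v")["v"]
        df["prevalence"] = rs.baseline_prevalence.to_frame("v")["v"]
        df.insert(0, "disease", rs.definition.name)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_disease_rates(path: Path) -> list[DiseaseRates]:
    df = pd.read_csv(path)
    out = []
    for name, sub in df.groupby("disease", sort=False):
        if name not in DISEASE_BY_NAME:
            raise ValueError(f"unknown disease {name!r} in {path}")
        out.append(DiseaseRates(
            DISEASE_BY_NAME[name],
            AgeSexTable.from_frame(sub, "incidence"),
            AgeSexTable.from_frame(sub, "remission"),
            AgeSexTable.from_frame(sub, "case_fatality"),
            AgeSexTable.from_frame(sub, "prevalence"),
        ))
    return out


def write_bmi(bmi: BMITable, path: Path) -> None:
    df = bmi.mean.to_frame("mean")
    df["sd"] = bmi.sd.to_frame("v")["v"]
    df.insert(2, "family", bmi.family)
    df.to_csv(path, index=False)


def read_bmi(path: Path) -> BMITable:
    df = pd.read_csv(path)
    families = df["family"].unique()
    if len(families) != 1:
        raise ValueError("bmi.csv must use a single distribution family")
    return BMITable(str(families[0]), AgeSexTable.from_frame(df, "mean"),
                    AgeSexTable.from_frame(df, "sd"))


def write_rr_table(specs: Sequence[RRSpec], path: Path) -> None:
    recs = [(s.disease, s.sex_scope, s.age_low, s.age_high, s.bmi_low, s.bmi_high,
             s.rr_per_5, s.ci_low, s.ci_high) for s in specs]
    pd.DataFrame(recs, columns=["disease", "sex_scope", "age_low", "age_high",
                                "bmi_low", "bmi_high", "rr_per_5", "ci_low", "ci_high"]
                 ).to_csv(path, index=False)


def read_rr_table(path: Path) -> list[RRSpec]:
    df = pd.read_csv(path)

    def opt(v):
        return None if pd.isna(v) else float(v)

    return [RRSpec(r.disease, float(r.rr_per_5), float(r.ci_low), float(r.ci_high),
                   sex_scope=str(r.sex_scope), age_low=opt(r.age_low), age_high=opt(r.age_high),
                   bmi_low=opt(r.bmi_low), bmi_high=opt(r.bmi_high))
            for r in df.itertuples()]


def write_annual_delta(delta: AgeSexTable, path: Path) -> None:
    delta.to_frame("delta").to_csv(path, index=False)


def read_annual_delta(path: Path) -> AgeSexTable:
    return AgeSexTable.from_frame(pd.read_csv(path), "delta")


INPUT_FILES = ("population.csv", "mortality.csv", "disease_rates.csv", "bmi.csv",
               "rr_table.csv", "annual_delta.csv")


def write_inputs(inputs: ModelInputs, directory: Path) -> None:
    """Emit the full fixture set to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_population(inputs.population, directory / "population.csv")
    write_mortality(inputs.mortality, directory / "mortality.csv")
    write_disease_rates(inputs.disease_rates, directory / "disease_rates.csv")
    write_bmi(inputs.bmi_baseline, directory / "bmi.csv")
    write_rr_table(inputs.rr_table, directory / "rr_table.csv")
    write_annual_delta(inputs.annual_mean_delta, directory / "annual_delta.csv")


def read_inputs(directory: Path) -> ModelInputs:
    directory = Path(directory)
    missing = [f for f in INPUT_FILES if not (directory / f).exists()]
    if missing:
        raise FileNotFoundError(f"input directory {directory} is missing {missing}")
    return ModelInputs(
        population=read_population(directory / "population.csv"),
        mortality=read_mortality(directory / "mortality.csv"),
        disease_rates=read_disease_rates(directory / "disease_rates.csv"),
        bmi_baseline=read_bmi(directory / "bmi.csv"),
        annual_mean_delta=read_annual_delta(directory / "annual_delta.csv"),
        rr_table=read_rr_table(directory / "rr_table.csv"),
    )
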
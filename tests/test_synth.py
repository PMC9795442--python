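"""Synthetic input generators: conservation, determinism, closed forms, consistency."""

import numpy as np
import pytest
from scipy.integrate import quad

from pmslt.distributions import BMIDistribution
from pmslt.engine import decompose_mortality
from pmslt.io import read_rr_table, write_rr_table
from pmslt.synth import (
    RateShape,
    _consistent_prevalence,
    builtin_rr_table,
    generate_all_disease_rates,
    generate_bmi_baseline,
    generate_disease_rates,
    generate_mortality_schedule,
    generate_population,
)
from pmslt.types import (
    AGES,
    DISEASE_BY_NAME,
    N_AGES,
    N_SEXES,
    AgeSexTable,
    MortalitySchedule,
)


class TestPopulation:
    def test_total_is_conserved(self):
        pop = generate_population(100_000, seed=1)
        assert pop.counts.values.sum() == pytest.approx(100_000, abs=1)

    def test_fixed_seed_is_reproducible(self):
        a = generate_population(50_000, seed=3)
        b = generate_population(50_000, seed=3)
        assert np.array_equal(a.counts.values, b.counts.values)

    def test_counts_decline_above_modal_age(self):
        pop = generate_population(1_000_000, seed=1)
        v = pop.counts.values
        assert (v[:, AGES >= 30][:, :-1] + 1 >= v[:, AGES >= 30][:, 1:]).all()
        assert (v[:, 95 - 20] <= v[:, 60 - 20]).all()

    def test_rejects_non_positive_size(self):
        with pytest.raises(ValueError):
            generate_population(0, seed=1)


class TestMortality:
    def test_degenerate_exponent_gives_flat_rate(self):
        m = generate_mortality_schedule(makeham_c=0.0, gompertz_b=1e-4, gompertz_theta=0.0)
        assert np.allclose(m.rates.values, 1e-4)

    def test_rate_at_youngest_age(self):
        m = generate_mortality_schedule(makeham_c=0.001, gompertz_b=5e-5, gompertz_theta=0.09)
        assert m.rates[20, "male"] == pytest.approx(0.00105, rel=1e-12)

    def test_gompertz_ratio_closed_form(self):
        theta = 0.08
        m = generate_mortality_schedule(makeham_c=0.0, gompertz_b=3e-5, gompertz_theta=theta)
        ratio = m.rates[80, "female"] / m.rates[40, "female"]
        assert ratio == pytest.approx(np.exp(40 * theta), rel=1e-12)

    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            generate_mortality_schedule(makeham_c=-1e-3)


class TestDiseaseRates:
    def test_zero_incidence_gives_zero_prevalence(self):
        mort = generate_mortality_schedule()
        rates = generate_disease_rates(
            DISEASE_BY_NAME["type2_diabetes"],
            {"incidence": RateShape(0.0, 0.0), "case_fatality": RateShape(0.001, 0.01)},
            mort)
        assert np.all(rates.baseline_prevalence.values == 0.0)

    def test_pure_accumulation_closed_form(self):
        """No remission/fatality/mortality: prevalence(a) -> 1 - exp(-i (a-20))."""
        i = 0.02
        mort = MortalitySchedule(AgeSexTable.zeros())
        rates = generate_disease_rates(
            DISEASE_BY_NAME["type2_diabetes"], {"incidence": RateShape(i, i)}, mort)
        expected = 1.0 - np.exp(-i * (AGES - 20.0))
        assert np.abs(rates.baseline_prevalence.values - expected[None]).max() < 1e-3

    def test_rejects_short_burn_in(self):
        mort = generate_mortality_schedule()
        with pytest.raises(ValueError):
            generate_disease_rates(DISEASE_BY_NAME["stroke"],
                                   {"incidence": RateShape(1e-4, 1e-3)}, mort, burn_in_years=10)

    def test_excess_mortality_above_all_cause_is_an_error(self):
        mort = generate_mortality_schedule(makeham_c=1e-4, gompertz_b=1e-6, gompertz_theta=0.0)
        with pytest.raises(ValueError, match="all-cause"):
            generate_disease_rates(
                DISEASE_BY_NAME["type2_diabetes"],
                {"incidence": RateShape(0.05, 0.05), "case_fatality": RateShape(0.5, 0.5)},
                mort)

    def test_rate_set_is_stationary_under_one_engine_step(self, inputs):
        """The DISMOD-style consistency contract: one more engine recursion
        reproduces the generated prevalence to < 1e-6 in sup norm."""
        residual = decompose_mortality(inputs.mortality, inputs.disease_rates)
        worst = 0.0
        for rs in inputs.disease_rates:
            again = _consistent_prevalence(rs.incidence, rs.remission, rs.case_fatality, residual)
            worst = max(worst, np.abs(again.values - rs.baseline_prevalence.values).max())
        assert worst < 1e-6

    def test_generation_is_deterministic(self):
        mort = generate_mortality_schedule()
        a = generate_all_disease_rates(mort, seed=5)
        b = generate_all_disease_rates(mort, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.incidence.values, y.incidence.values)
            assert np.array_equal(x.baseline_prevalence.values, y.baseline_prevalence.values)


class TestBMIBaseline:
    def test_overweight_prevalence_matches_independent_quadrature(self):
        dist = BMIDistribution("lognormal", 26.2, 4.0)
        oracle, _ = quad(dist.pdf, 25.0, 50.0, epsabs=1e-12, limit=200)
        assert dist.overweight_prevalence() == pytest.approx(oracle, abs=1e-8)

    def test_tiny_sd_below_cutoff_gives_zero_prevalence(self):
        dist = BMIDistribution("lognormal", 23.0, 1e-4)
        assert dist.overweight_prevalence() == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_normal_at_cutoff_gives_half(self):
        dist = BMIDistribution("normal", 25.0, 2.0)
        assert dist.overweight_prevalence() == pytest.approx(0.5, abs=1e-6)

    def test_mean_bounds_enforced(self):
        with pytest.raises(ValueError):
            BMIDistribution("lognormal", 14.0, 3.0)
        table = generate_bmi_baseline()
        assert ((table.mean.values > 15) & (table.mean.values < 45)).all()


class TestBuiltinRRTable:
    @pytest.mark.parametrize("disease,sel,rr,ci", [
        ("type2_diabetes", dict(bmi_low=25), 2.16, (1.89, 2.46)),
        ("type2_diabetes", dict(bmi_low=15), 0.96, (0.59, 1.55)),
        ("coronary_heart_disease", dict(age_low=35), 1.50, (1.39, 1.62)),
        ("stroke", dict(age_low=80), 1.10, (0.94, 1.30)),
        ("cirrhosis", dict(bmi_low=15), 0.73, (0.54, 1.00)),
        ("colorectal_cancer", dict(sex_scope="male"), 1.24, (1.20, 1.28)),
        ("colorectal_cancer", dict(sex_scope="female"), 1.09, (1.05, 1.13)),
        ("kidney_cancer", dict(sex_scope="male"), 1.24, (1.20, 1.28)),
        ("breast_cancer", dict(sex_scope="female"), 1.12, (1.08, 1.16)),
        ("pancreas_cancer", dict(), 1.10, (1.07, 1.14)),
        ("liver_cancer", dict(age_low=35), 1.47, (1.26, 1.71)),
    ])
    def test_published_values(self, disease, sel, rr, ci):
        rows = [r for r in builtin_rr_table() if r.disease == disease
                and all(getattr(r, k) == v for k, v in sel.items())]
        assert len(rows) == 1
        assert (rows[0].rr_per_5, rows[0].ci_low, rows[0].ci_high) == (rr, *ci)

    def test_covers_all_eleven_diseases(self):
        assert {r.disease for r in builtin_rr_table()} == set(DISEASE_BY_NAME)

    def test_round_trips_through_csv(self, tmp_path):
        rows = builtin_rr_table()
        path = tmp_path / "rr.csv"
        write_rr_table(rows, path)
        assert read_rr_table(path) == rows


def test_generated_tables_cover_full_lattice(inputs):
    """Every table spans exactly [20,100] x {male, female}, no gaps."""
    for tab in (inputs.population.counts, inputs.mortality.rates,
                inputs.bmi_baseline.mean, inputs.annual_mean_delta):
        assert tab.values.shape == (N_SEXES, N_AGES)
        assert np.isfinite(tab.values).all()
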
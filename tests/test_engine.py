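"""The multistate life table engine: decomposition, transitions, oracles, burden."""

import math

import numpy as np
import pytest

from pmslt.engine import (
    EngineConfig,
    MSLTModel,
    attributable_burden,
    decompose_mortality,
    disease_transition,
    prevented_burden,
)
from pmslt.scenarios import apply_scenario, project_bau, ScenarioSpec
from pmslt.synth import generate_mortality_schedule
from pmslt.types import (
    AGES,
    DISEASE_BY_NAME,
    N_AGES,
    N_SEXES,
    AgeSexTable,
    BMITable,
    DiseaseRates,
    ModelInputs,
    MortalitySchedule,
    PopulationTable,
    RRSpec,
)


def _table(value: float) -> AgeSexTable:
    return AgeSexTable.full(value)


def _toy_inputs(incidence=0.1, remission=0.0, case_fatality=0.0, mortality=0.0,
                pop=None, rr=2.0, disease="type2_diabetes") -> ModelInputs:
    """A configurable single-disease bundle with zero baseline prevalence."""
    counts = AgeSexTable.zeros() if pop is None else pop
    rates = DiseaseRates(DISEASE_BY_NAME[disease], _table(incidence), _table(remission),
                         _table(case_fatality), AgeSexTable.zeros())
    return ModelInputs(
        population=PopulationTable(counts),
        mortality=MortalitySchedule(_table(mortality)),
        disease_rates=[rates],
        bmi_baseline=BMITable("normal", _table(27.0), _table(3.0)),
        annual_mean_delta=_table(0.15),
        rr_table=[RRSpec(disease, rr, rr, rr)],
    )


class TestDecomposeMortality:
    def test_no_diseases_returns_all_cause(self):
        mort = generate_mortality_schedule()
        residual = decompose_mortality(mort, [])
        assert np.array_equal(residual.values, mort.rates.values)

    def test_boundary_stratum_reaches_zero(self):
        mort = MortalitySchedule(_table(0.02))
        rates = DiseaseRates(DISEASE_BY_NAME["stroke"], _table(0.0), _table(0.0),
                             _table(0.04), _table(0.5))
        residual = decompose_mortality(mort, [rates])
        assert np.allclose(residual.values, 0.0)

    def test_reconstruction_identity(self, inputs):
        residual = decompose_mortality(inputs.mortality, inputs.disease_rates)
        rebuilt = residual.values + sum(r.case_fatality.values * r.baseline_prevalence.values
                                        for r in inputs.disease_rates)
        assert np.abs(rebuilt - inputs.mortality.rates.values).max() < 1e-12

    def test_negative_residual_names_the_stratum(self):
        mort = MortalitySchedule(_table(0.001))
        rates = DiseaseRates(DISEASE_BY_NAME["stroke"], _table(0.0), _table(0.0),
                             _table(0.1), _table(0.5))
        with pytest.raises(ValueError, match="age 20"):
            decompose_mortality(mort, [rates])


class TestDiseaseTransition:
    def test_zero_rates_leave_state_unchanged(self):
        h, d, dd, do = (np.array([100.0]), np.array([20.0]), np.array([3.0]), np.array([7.0]))
        out = disease_transition(h, d, dd, do, 0.0 * h, 0.0 * h, 0.0 * h, 0.0 * h)
        for a, b in zip(out, (h, d, dd, do)):
            assert np.array_equal(a, b)

    def test_single_transition_closed_form(self):
        """Pure incidence: diseased after one cycle is N (1 - exp(-i))."""
        n, i = 1000.0, 0.1
        h, d, dd, do = disease_transition(np.array([n]), np.zeros(1), np.zeros(1), np.zeros(1),
                                          np.array([i]), np.zeros(1), np.zeros(1), np.zeros(1))
        assert d[0] == pytest.approx(n * (1 - math.exp(-0.1)), rel=1e-12)
        assert h[0] + d[0] == pytest.approx(n, rel=1e-12)

    def test_conservation_under_random_rates(self, rng):
        """Four-state sums are invariant over repeated random transitions."""
        h = rng.uniform(0, 1000, size=(N_SEXES, N_AGES))
        d = rng.uniform(0, 300, size=(N_SEXES, N_AGES))
        dd = np.zeros_like(h)
        do = np.zeros_like(h)
        total0 = h + d
        for _ in range(10):
            rates = [rng.uniform(0, 0.5, size=h.shape) for _ in range(4)]
            h, d, dd, do = disease_transition(h, d, dd, do, *rates)
            assert (h >= 0).all() and (d >= 0).all()
        assert np.abs((h + d + dd + do) - total0).max() < 1e-9 * total0.max()


class TestRunProjection:
    def test_zero_horizon_gives_empty_accumulators(self, inputs):
        model = MSLTModel(inputs, EngineConfig(horizon=0))
        result = model.run("baseline")
        assert result.incident_cases.shape[-1] == 0

    def test_unit_rr_makes_exposure_irrelevant(self):
        inp = _toy_inputs(incidence=0.05, mortality=0.01,
                          pop=AgeSexTable.full(100.0), rr=1.0)
        model = MSLTModel(inp)
        bau = project_bau(inp.bmi_baseline, inp.annual_mean_delta, 10)
        frozen = apply_scenario(bau, ScenarioSpec("S2_freeze"))
        a, b = model.run(bau), model.run(frozen)
        assert np.array_equal(a.incident_cases, b.incident_cases)
        assert np.array_equal(a.disease_deaths, b.disease_deaths)

    def test_null_pifs_match_reference_run(self, model, runs):
        byhand = model.run_with_pifs(np.zeros_like(model.pif_table("baseline")))
        assert np.array_equal(byhand.incident_cases, runs["reference"].incident_cases)

    def test_proportionality_with_null_pifs(self, inputs, model, runs):
        """The PIF=0 run reproduces the plain all-cause life table to 1e-9.

        Survivorship is compared per capita of the initial population so the
        tolerance does not scale with cohort size.
        """
        m = inputs.mortality.rates.values
        alive = inputs.population.counts.values.copy()
        growth = model.config.entrant_growth
        scale = max(alive.max(), 1.0)
        for y in range(1, model.config.horizon + 1):
            alive = alive * np.exp(-m)
            alive[:, 1:] = alive[:, :-1]
            alive[:, 0] = inputs.population.counts.values[:, 0] * growth ** y
            diff = np.abs(alive - runs["reference"].alive[..., y]).max()
            assert diff / scale < 1e-9

    def test_small_instance_matches_markov_enumeration(self, rng):
        """Engine vs an independently coded per-state Markov chain, 1e-9.

        Random single-disease instances with population on three ages only;
        the oracle tracks each cohort's four states with scalar arithmetic.
        """
        for trial in range(5):
            i, r, f, mu = rng.uniform(0.01, 0.4, size=4)
            pop_ages = {40: 500.0, 41: 300.0, 42: 200.0}
            counts = AgeSexTable.zeros()
            for a, n in pop_ages.items():
                counts.values[:, a - 20] = n
            inp = _toy_inputs(incidence=i, remission=r, case_fatality=f, mortality=0.0,
                              pop=counts, disease="breast_cancer")
            # other-cause mortality enters via the residual: use a flat schedule
            inp.mortality.rates.values[:] = mu
            H = 2
            pif = rng.uniform(-0.3, 0.5, size=(1, H, N_SEXES, N_AGES))
            model = MSLTModel(inp, EngineConfig(horizon=H, entrant_growth=1.0))
            result = model.run_with_pifs(pif)

            # --- oracle: explicit per-cohort state propagation ---
            expected_cases = np.zeros((N_SEXES, N_AGES, H))
            expected_deaths = np.zeros((N_SEXES, N_AGES, H))
            for s_i in range(N_SEXES):
                for a0, n in pop_ages.items():
                    h, d = n, 0.0
                    for y in range(1, H + 1):
                        age = a0 + (y - 1)  # age during the cycle
                        a_i = age - 20
                        i_eff = i * (1.0 - pif[0, y - 1, s_i, a_i])
                        th = i_eff + mu
                        p_exit_h = 1.0 - math.exp(-th)
                        p_h_d = p_exit_h * i_eff / th
                        p_h_o = p_exit_h * mu / th
                        td = r + f + mu
                        p_exit_d = 1.0 - math.exp(-td)
                        p_d_h = p_exit_d * r / td
                        p_d_f = p_exit_d * f / td
                        p_d_o = p_exit_d * mu / td
                        cases = h * p_h_d
                        deaths = d * p_d_f
                        h, d = (h - cases - h * p_h_o + d * p_d_h,
                                d + cases - d * (p_d_h + p_d_f + p_d_o))
                        expected_cases[s_i, a_i, y - 1] = cases
                        expected_deaths[s_i, a_i, y - 1] = deaths
            assert np.abs(result.incident_cases[0] - expected_cases).max() < 1e-9
            assert np.abs(result.disease_deaths[0] - expected_deaths).max() < 1e-9


class TestBurdenDifferences:
    def test_identical_runs_give_zero_burden(self, runs):
        zero = attributable_burden(runs["BAU"], runs["BAU"])
        assert zero.total_cases == 0.0 and zero.total_deaths == 0.0

    def test_totals_equal_component_sums_exactly(self, runs):
        burden = attributable_burden(runs["BAU"], runs["TMREL"])
        assert burden.total_cases == sum(burden.by_disease("cases").values())
        assert burden.total_deaths == sum(burden.by_disease("deaths").values())

    def test_mismatched_shapes_rejected(self, inputs, runs):
        short = MSLTModel(inputs, EngineConfig(horizon=3)).run("baseline")
        with pytest.raises(ValueError):
            attributable_burden(runs["BAU"], short)

    def test_toy_attributable_burden_approximation(self):
        """Constant PIF p, no fatality/remission/mortality: attributable cases
        over T years is close to N (1 - exp(-i)) p T.

        The healthy pool depletes slightly faster in the factual run, so the
        leading error is of order i*T; asserted at relative error < i*(T+1).
        """
        i, p, T = 1e-3, 0.3, 5
        counts = AgeSexTable.zeros()
        counts.values[:, 20:50] = 100.0  # keep cohorts far from the closing age
        inp = _toy_inputs(incidence=i, mortality=0.0, pop=counts)
        model = MSLTModel(inp, EngineConfig(horizon=T, entrant_growth=1.0))
        factual = model.run_with_pifs(np.zeros((1, T, N_SEXES, N_AGES)))
        counter = model.run_with_pifs(np.full((1, T, N_SEXES, N_AGES), p))
        burden = attributable_burden(factual, counter)
        n_total = counts.values.sum()
        approx = n_total * (1 - math.exp(-i)) * p * T
        assert abs(burden.total_cases - approx) / approx < i * (T + 1)

    def test_prevented_burden_is_ordered_across_scenarios(self, runs):
        """S3 >= S2 >= S1 >= 0 in every yearly total on the default fixture."""
        p1 = prevented_burden(runs["BAU"], runs["S1_half_rate"])
        p2 = prevented_burden(runs["BAU"], runs["S2_freeze"])
        p3 = prevented_burden(runs["BAU"], runs["S3_reduce_prevalence"])
        for metric in ("cases", "deaths"):
            y1, y2, y3 = (p.yearly_totals(metric) for p in (p1, p2, p3))
            assert (y1 >= -1e-9).all()
            assert (y2 >= y1 - 1e-9).all()
            assert (y3 >= y2 - 1e-9).all()

    def test_cancer_prevented_cases_zero_before_step_lag(self, runs):
        burden = prevented_burden(runs["BAU"], runs["S2_freeze"])
        cancer_idx = [i for i, d in enumerate(burden.diseases)
                      if DISEASE_BY_NAME[d].group == "cancer"]
        assert np.all(burden.cases[cancer_idx, :, :9] == 0.0)
        assert np.any(burden.cases[cancer_idx, :, 9] > 0.0)

    def test_attributable_trend_is_nondecreasing(self, runs):
        """Yearly attributable totals rise through the lag phase-in under BAU."""
        burden = attributable_burden(runs["BAU"], runs["TMREL"])
        yearly = burden.yearly_totals("cases")
        assert (np.diff(yearly) > -1e-9).all()


def test_conservation_over_default_ten_year_run(inputs, model):
    """Four-state sums per disease track stay equal to the entry size through
    ten annual transition cycles (tolerance 1e-9 per unit of population)."""
    pop = inputs.population.counts.values
    residual = model.residual.values
    for rs in inputs.disease_rates:
        h = pop * (1 - rs.baseline_prevalence.values)
        d = pop * rs.baseline_prevalence.values
        dd = np.zeros_like(h)
        do = np.zeros_like(h)
        for _ in range(10):
            h, d, dd, do = disease_transition(h, d, dd, do, rs.incidence.values,
                                              rs.remission.values, rs.case_fatality.values,
                                              residual)
        assert np.abs((h + d + dd + do) - pop).max() < 1e-9 * max(pop.max(), 1.0)
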
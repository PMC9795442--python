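# Methods

## Model structure

The engine is a proportional multistate life table (PMSLT). One main
cohort life table carries all-cause survivorship for every (age, sex)
stratum on the lattice 20–100 × {male, female}. Alongside it run 11
disease life tables, each with four states — healthy, diseased, dead from
the disease, dead from other causes. Disease state occupancy determines
per-stratum prevalence, and each cycle the main table's mortality is
recomputed as

    m = residual + Σ_d  case_fatality_d × prevalence_d ,

where the residual (other-cause) schedule is obtained once at model
construction by subtracting baseline disease excess mortality from the
all-cause schedule (`decompose_mortality`; a negative residual anywhere is
a hard consistency error naming the stratum). This coupling is what makes
the life table "proportional": an intervention that lowers disease
prevalence lowers all-cause mortality and so changes survivorship.

### Cycles and transitions

Cycles are annual. Within a cycle all competing exits from a state use
exact exponential allocation: with exit rates r_1..r_k, the probability of
leaving is 1 − exp(−Σ r_j), shared among destinations in proportion to the
rates. This is exact when rates are constant within the cycle, and —
unlike naive r·Δt products — can never produce negative occupancy. After
transitions, cohorts age by one year; survivorship closes at age 100
(occupants aging past 100 leave the modelled range). A new age-20 cohort
enters each calendar year, scaled by a configurable growth factor
(default 1.01/year); the no-population-growth sensitivity sets the factor
to 1. Incident cases are gross inflow into the diseased state; deaths are
cause-specific (transitions into dead-from-disease). Burden is reported
for ages 20–79; the simulation itself ages cohorts beyond 79 so there is
no truncation bias at the reporting boundary.

### Dose-response and PIFs

Relative risks are piecewise log-linear in BMI on the support
[15, 50] kg/m², represented by a slope per kg/m² on each of the canonical
segments (15, 25) and (25, 50). Age-banded published RRs give a single
slope on both segments for the band; BMI-segmented RRs set each segment's
slope; strata outside a published restriction (e.g. breast cancer in men,
liver cancer outside 35–79) get the unit curve. The curve chains
multiplicatively across segments, so it is continuous, with RR = 1 at the
anchor (default 22.5 kg/m², the midpoint of the theoretical-minimum-risk
range; PIFs are anchor-invariant, so the anchor only fixes presentation).
Below-25 segments are applied as published even where they are < 1
(e.g. cirrhosis 0.73); `EngineConfig(floor_rr_at_one=True)` floors them
at 1 instead.

The potential impact fraction between two exposure densities is
PIF = 1 − E_cf[RR]/E_ref[RR]. The public `compute_pif` evaluates both
integrals with adaptive quadrature split at the segment boundary
(absolute tolerance 1e-9); the engine's vectorised path uses fixed-order
Gauss–Legendre (64 nodes per segment) on whole stratum lattices, which for
these smooth integrands agrees with the adaptive path to well below 1e-9
(asserted in tests, along with a 10⁶-point Riemann cross-check).

Every run's PIFs compare its exposure path at each simulation year against
the shared year-0 baseline distribution, then apply the disease's lag: a
linear 5-year ramp for the non-cancer diseases and a 10-year step for
cancers. The lag multiplies the PIF sequence of **every** non-reference
run, including the theoretical-minimum-risk counterfactual, so
attributable burden phases in over the first five years and attributable
cancer burden appears only in the final simulated year. The
attributable-burden counterfactual relocates all exposure mass to a
uniform distribution on 20–25 kg/m² (configurable to a point mass at the
anchor).

## Exposure model

Each stratum's BMI is one parametric distribution — lognormal by default
(right-skewed, positive), normal as an option — parameterised by the mean
and sd of the unclipped distribution, then clipped to [15, 50] and
renormalised so the dose-response curve is defined wherever mass exists.
Trajectories are linear in the stratum mean over the horizon with the sd
fixed. The S3 scenario is interpreted as a *relative* reduction of each
stratum's overweight prevalence (terminal prevalence = 93.3% of baseline
by default; an absolute-percentage-point switch is provided), realised as
a shape-preserving mean shift: the terminal mean is solved per stratum by
bracketed root finding (overweight prevalence is strictly increasing in
the mean, so the root is unique; solved to |Δprevalence| < 1e-8).

## Synthetic inputs

The generator emulates the inputs a national projection draws on without
calibrating to any real registry:

* **Population** — flat weights to a modal age (30), smooth Gaussian-tail
  decline above it; largest-remainder integer apportionment conserves the
  configured total exactly. The seed jitters the sex split and decline
  scale only, preserving monotonicity above the modal age.
* **Mortality** — Gompertz–Makeham, rate = c + b·exp(θ(age − 20)) with
  defaults c = 8e-4, b = 4e-5, θ = 0.105 and sex multipliers 1.3/0.8,
  giving rates from ~1e-3 at age 20 to ~0.3 at 100 so survivorship is
  effectively exhausted by the closing age.
* **Disease rates** — smooth logistic age-increasing curves per disease
  (orders of magnitude chosen to be plausible for an adult middle-income
  population: e.g. diabetes incidence rising to ~9/1000 person-years,
  pancreatic-cancer case fatality ~0.25–0.45/year), with per-disease sex
  factors and a small seeded level jitter. Remission is nonzero for
  cancers only.
* **Consistency** — baseline prevalence is *not* free: it is produced by
  running the engine's own annual transition forward over a cohort from
  age 20 (disease-free) to 100, iterating the shared other-cause residual
  to a joint fixed point across all 11 diseases. The returned bundle is
  therefore stationary under the engine: one further step reproduces
  prevalence to ~1e-16, and a null-PIF run reproduces the plain all-cause
  life table. This replaces an external incidence–prevalence–mortality
  consistency fit and guarantees exactly the consistency the model needs.
* **BMI** — lognormal, means rising from ~24 kg/m² at 20 to ~27.5 in late
  middle age (population mean ≈ 26), sd 3.6–4.4, yearly drift defaulting
  to ~0.2 kg/m²/year at 20 tapering to ~0.08 at 100 (population average
  ≈ 0.16, a ~1.6-unit rise per decade).

What the generator does **not** emulate: secular trends in disease rates,
within-stratum exposure heterogeneity beyond one parametric family,
migration, cohort effects, or correlation between diseases. Passing tests
therefore demonstrate the correctness of the machinery (conservation,
consistency, ordering, oracle agreement), not the realism of any absolute
burden number for a real country.

## Uncertainty

Monte Carlo draws perturb: relative risks (lognormal, median at the
central RR, log-sd from the published 95% CI as (ln hi − ln lo)/(2·1.96));
baseline BMI means (normal, se 0.1 kg/m² by default); and rates
(multiplicative unit-mean gamma factors, cv 0.05 by default, independent
across diseases and strata — a config hook shares one draw across a
disease's RR rows so age bands move together). Baseline prevalence is kept
at its central value rather than re-running the consistency recursion per
draw; the induced residual is recomputed each draw and draws implying a
negative residual are excluded (more than 1% exclusions is a hard error).
Intervals are empirical 2.5/97.5 percentiles (linear interpolation) across
draws; the point estimate is the unperturbed run, so the interval is not
forced to cover it. Draws are a deterministic function of
(seed, draw index). The default is 5,000 draws; the test suite and the
acceptance script use 200, which reproduces interval tables bit-identically
under a fixed seed and is enough for the structural checks they make.

## Sensitivity analysis

Nine variants, each perturbing exactly one input family of the primary
BAU attributable-burden run: baseline BMI means +10%; yearly drift ±5%;
all relative risks ±2%; all incidence ±2%; entrant growth removed; plus an
explicit null variant that must report exactly 0%. Results are percent
changes of total attributable cases and deaths against the primary run.
On the default synthetic fixture the +10% BMI variant is strongly positive
and the RR pair brackets zero nearly symmetrically; the no-growth variant
is necessarily small here because only the size of entering age-20 cohorts
changes over a ten-year window.

## Numerical choices and edge cases

* Gauss–Legendre order 64 per segment for lattice PIFs (machine precision
  for these integrands); adaptive quadrature (1e-9) for the scalar API.
* Brentq with xtol 1e-12 for the prevalence inversion; targets outside the
  range attainable with means in (15, 45) raise a solver error.
* Zero-rate cells in the competing-risk allocation are handled by a guarded
  division (exit probability 0).
* An empty disease track (zero occupancy) reports prevalence 0.
* Rounding for presentation is half-away-from-zero to the nearest hundred,
  applied strictly after summation, so Men + Women = Total pre-rounding in
  every report row.
* Problem sizes: the default projection lattice is 2 sexes × 81 ages ×
  11 diseases × 10 annual cycles; the acceptance script projects a
  synthetic population of 155 million and uses 200 Monte Carlo draws and
  100/10 randomized oracle cases — sizes chosen so the whole acceptance
  pass completes in well under a minute while leaving the oracle
  tolerances at 1e-6 or tighter.

## Known limitations

Diseases are modelled independently (no comorbidity interactions); the
attributable-deaths difference is cause-specific, not all-cause (a
different convention would also count mortality displaced to other
causes); incident cases are gross inflow, not net of remission; the lag
functional forms (linear ramp, hard step) are conventions — only the lag
lengths are data-driven; and the synthetic generator's absolute levels are
plausible but uncalibrated, so absolute burden numbers from the default
fixture characterise the machinery, not any real population.
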
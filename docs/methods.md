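# Methods

## Disease progression chain

Progression is a discrete-time absorbing Markov chain on
{Mild, Moderate, Severe, Death} with a one-year step. The transient block and
death vector of the baseline law are

|          | Mild  | Moderate | Severe | Death |
|----------|-------|----------|--------|-------|
| Mild     | 0.774 | 0.158    | 0.013  | 0.055 |
| Moderate | 0.070 | 0.501    | 0.214  | 0.215 |
| Severe   | 0     | 0.028    | 0.492  | 0.480 |

Severe→Mild is structurally zero (no two-stage improvement within a year).
Death probabilities are stage-specific but age-constant — a strong assumption
inherited from the clinical source data and the model's main known
limitation: at high ages real all-cause mortality overtakes the Severe-stage
death rate, so the chain understates old-age patient mortality (see the
demography section for how the synthetic population absorbs this).

### Sojourn metric

All scenario comparisons use the expected **total** years spent in a stage by
a patient entering at Mild, i.e. the Mild row of the fundamental matrix
N = (I − Q)⁻¹, not the consecutive-stay expectation 1/(1 − p_stay). The two
differ because patients can leave and re-enter a stage (Moderate→Mild→
Moderate). The total-years metric is the one under which all five shipped
scenario matrices deliver their advertised prolongation: the gains from Mild
entry are +1.01, +2.09, +1.07, +1.88 and +1.05 years for `mild+1`, `mild+2`,
`moderate+1`, `moderate+2` and `severe+1`, each rounding to the advertised
whole number.

The "limit stage mix" used for initialisation and steady-state costs is the
normalised Mild-entry row of N. Under a constant stream of Mild entrants the
cross-sectional stage distribution of the patient population converges to
exactly this vector (patient-years per stage per entrant, normalised), so it
is the closed-form, deterministic stand-in for an empirical end-of-simulation
snapshot.

### Prolongation solver

`solve_prolongation(model, stage, delta)` scales both worsening probabilities
out of the stage by a common factor α ∈ (0, 1], holds the stage's death
probability fixed, gives the freed mass to staying, and bisects α
(`scipy.optimize.brentq`, xtol 1e-14) until the Mild-entry sojourn in the
stage exceeds baseline by exactly `delta`. For Severe — which has no onward
worsening — the death probability is lowered instead, with staying absorbing
the mass. Requests beyond the policy's reach raise with the attainable
maximum. The solver is monotone (larger δ ⇒ larger stay probability) and
δ = 0 returns the input model unchanged.

With δ = 1 year in Mild the solver lands on stay = 0.81360, worsenings
0.12141 and 0.00999 — the published one-year matrix to rounding. With δ = 2
it gives stay = 0.84175, whereas the shipped `mild+2` matrix has 0.844 (which
delivers +2.09 years); the two-year matrix is therefore stored verbatim
rather than re-derived, and the solver is not claimed to reproduce it.

## Synthetic demography

`generate_projection` is a closed cohort-component model: single ages 0–100,
years 2015–2080, no migration, constant annual births, deaths applied at
age-specific one-year probabilities, exact bookkeeping
`counts[a+1, t+1] = counts[a, t] − deaths[a, t]`. The 2015 pyramid is the
survival curve of the mortality law modulated by a Gaussian cohort-size bulge
(a baby-boom echo, default centre 50, width 12, amplitude 0.35) and rescaled
to 5.08 × 10⁸ persons. The generator is fully deterministic; optional
lognormal pyramid jitter sits behind `noise_sd`/`seed` and defaults to off.

Mortality is Gompertz–Makeham, m(a) = c + A·e^{b·a} with c = 5 × 10⁻⁴,
A = 6.3 × 10⁻⁶, b = 0.11, **plateauing at the disease chain's limit-mix
patient mortality** d̄ = limit_mix · death ≈ 0.1365 (reached near age 90),
with the closed top age 100 fully mortal within its year. The plateau is the
well-posedness condition of the incidence calibration, not a demographic
estimate: at ages where the prevalence curve is cap-saturated (≥ 97 under the
defaults) about 95% of the cohort are patients whose death rates the chain
fixes at d̄ regardless of age. If cohort mortality exceeded d̄ there, the
healthy 5% would be consumed by the entrant demand needed to hold prevalence
at the cap (and the derived healthy mortality would go negative); if it fell
below d̄, surviving patients would overshoot the cap and incidence would need
to be negative. An age-constant-mortality disease model is only consistent
with a demography whose extreme-age mortality matches it, and the stand-in
makes that choice explicitly. Real EU life tables are steeper above ~95
(q ≈ 0.25–0.35); users substituting a real Eurostat extract should expect
logged calibration-gap diagnostics at the very top ages. Life expectancy at
birth under the preset is ≈ 82.6 years and the 65+ share rises over the
horizon, so the preset reproduces the EU features that drive the results —
scale, ageing, smooth cohort survival — without claiming life-table realism.

What the generator deliberately does not emulate: migration, fertility
dynamics, per-country heterogeneity, period mortality shocks. Passing tests
on this demography therefore validate the *mechanics* (calibration closure,
conservation, scenario arithmetic, sign patterns) and the
demography-independent quantities (sojourns, per-patient costs); absolute €
totals are specific to the demographic input and are not asserted anywhere.

## Prevalence and incidence calibration

Prevalence is r(x) = 0.0142 · e^{0.1161·x}, interpreted with x = age − 60
(onset age 60, configurable) and clamped to a cap of 0.95: with x read as
calendar age the formula exceeds 1 already at age 37, while the adopted
reading gives 1.42% at 60 and ≈ 26% at 85, in line with AD epidemiology. The
raw formula crosses the cap near age 97.

The reference run starts from 2015 patients = prevalence × counts, split by
the limit mix, and steps yearly in a fixed order:

1. patient deaths by stage death probability;
2. stage transitions among survivors, with the conditional matrix
   q[i, j]/(1 − death[i]) so that Q and the death vector jointly form the
   one-year law;
3. healthy deaths;
4. ageing by one year (the top age leaves the grid and is tallied as deaths;
   the youngest age refills from the projection);
5. new Mild entrants from the healthy pool.

During calibration the entrant count per (age, year) is whatever makes
post-update patients equal prevalence × projected counts — floored at zero
when survivors already exceed the target and truncated at the available
healthy pool, both recorded in diagnostics — and the incidence rate is
entrants / healthy pool. Healthy mortality is the residual
(cohort deaths − patient deaths)/healthy, clipped to [0, 1] with negative
residuals counted in diagnostics. Both tables are frozen afterwards;
scenarios replay them verbatim, which makes incidence independent of the
treatment choice by construction. The replay executes the same
floating-point operations as the calibration pass, so re-simulating the
reference is bit-identical — the calibration is a fixed point, not an
approximation. On the EU preset the re-simulated prevalence stays within
0.24% of r(x) at every age ≥ 60 and every year (the only binding cells are
at the closed top age, where the healthy pool runs out by construction).

Scenario switching: for the yearly update running from year t to t+1, the
scenario transition law and incidence multiplier apply when t ≥ drug year
(default 2023), so the first affected counts appear in 2024. MCI is not a
compartment — people with mild cognitive impairment live inside the healthy
pool and the MCI scenarios act purely as incidence multipliers.

Counts propagate as deterministic expected values (fractional persons). The
individual-based `micro_oracle` replays the identical ordered probabilities
as Bernoulli/multinomial draws on integer persons and is used to validate
the deterministic engine (agreement within three binomial standard errors on
a 10⁵-person toy population); `mc_stage_walk` does the same for the chain
algebra against 10⁶ simulated patient histories, using the closed-form
occupation-time variance N(2N_dg − I) − N∘N for the standard errors.

## Costs

The stage cost table is monthly € per patient by Drummond class; the annual
stage cost is 12 × the row sum (23 112 / 40 118.4 / 55 401.6 € for
Mild/Moderate/Severe). The monthly reading is a deliberate interpretation:
it is the one that places the limit-mix weighted per-patient annual averages
(28 070–33 521 € across scenarios) in the 28–33 k€ range that published
per-patient figures occupy, while weekly or yearly readings are off by an
order of magnitude. Prices are constant — no discounting, no inflation —
so all deltas are real-terms comparisons under today's cost structure.

`steady_state_average_cost` = limit mix · annual stage costs approximates a
scenario's long-run per-patient average independently of demography; the
trajectory-based `per_patient_average` is the exact cross-sectional figure
and always lies between the cheapest and most expensive stage cost.
Comparison reports round deltas to 0.1 billion € and percentages to two
decimals, mirroring the conventional layout.

## Numerical choices and degenerate inputs

- Fundamental matrices come from a dense LAPACK solve of (I − Q)X = I;
  singular systems (a transient stage with no exit) are rejected, as are
  negative entries. Row-stochasticity is enforced at 1e-12 by every
  constructor.
- Bisection brackets for the solver are [1e-12, 1] on α (and
  [1e-12, d_baseline] on the Severe death probability); the solved model is
  re-checked against the target at 1e-9 before being returned.
- Zero-count cohorts get mortality and incidence 0; healthy mortality is
  clipped to [0, 1]; entrant demand is clipped to the available healthy pool.
  All clips are counted in the calibration diagnostics and logged.
- The toy projection used for oracle tests (20 ages × 10 years, 10⁵ persons,
  flat 2% mortality) keeps the micro-oracle's multinomial sampling exact on
  integer persons.
- Problem sizes: the EU grid is 101 ages × 66 years, so a full nine-scenario
  sweep is a few hundred 3 × 101 matrix products and runs in well under a
  second; the Monte-Carlo oracles use 10⁶ walkers and 10⁵ persons
  respectively, chosen to make three-standard-error bands a few permille
  wide while keeping the whole suite interactive.

## Known limitations

- Transition and death probabilities do not depend on age or calendar time;
  treatment scenarios switch the law once, with no uptake ramp.
- The synthetic demography trades extreme-age realism for calibration
  well-posedness (see above) and models no migration.
- Absolute cost projections inherit the demographic input and the constant
  price level; only signs, percentages and per-patient averages are
  portable.
- One improvement step per year at most; MCI carries no costs of its own.
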
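# Methods

## Model structure

The model is a deterministic (expectation) cohort state-transition model
with annual cycles. Eight five-year cohorts — start ages 65, 70, …, 100 —
are each run separately by sex from their band's lower age until age 105.
Within a cycle the order of events is: deaths first (band- and
sex-specific all-cause probability), then HZ episodes among survivors at
the band-specific annual incidence. Recurrence is allowed every cycle at
the incident rate, because the incidence data already pool first and
recurrent episodes; HZ itself causes no mortality in the model. Cohorts
age through the parameter bands (a person who starts at 65 uses 70–74
inputs from cycle 6, and so on); the oldest utility band (80+) also
serves ages 100+, and the male 100+ incidence carries the 95–99 value
forward (both documented reconstructions).

HZ, PHN and the complication categories are sub-annual tunnel episodes in
spirit: each incident episode is charged its full expected QALY loss and
cost in the onset cycle, even though severe PHN (13 months) overruns the
cycle. The alternative — fractional carry-over into the next cycle —
changes results only by one year of discounting on at most one month of
spillover, and is not worth the machinery. There is no half-cycle
correction: survivors accrue a full year of baseline utility per cycle,
after deaths are removed. Cycle *t* is discounted by (1+r)^−(t−1) with
r = 3%, so the first year is undiscounted.

Vaccination is delivered entirely at model start: covered persons (63%)
receive dose one, 74.9% of them complete dose two, and all doses (price
176.4 EUR + administration 7.2 EUR each) are charged in cycle 1. The
incidence multiplier for the vaccinated arm mixes unvaccinated persons
(weight 1−c), one-dose recipients (c(1−q), protected in year 1 only) and
completers (cq, on the scenario's waning curve).

## Parameters and their uncertainty

All inputs live in a single YAML document (`src/zoster_cea/data/
basecase.yaml`) mirrored by the immutable `ParameterSet`. Probabilities
and proportions are unitless per cycle; costs are 2021 EUR (100 SEK =
10.15 EUR annotation only — no conversion machinery); durations are
months; utilities are EQ-5D-3L index values in [0,1].

Uncertain quantities carry distributions for the probabilistic
sensitivity analysis:

* PHN-given-HZ proportions and baseline utilities: Beta via method of
  moments from the published mean and standard error (`beta_from_mean_se`
  reproduces both moments exactly; it requires se² < mean(1−mean)).
* Pain-state utility multipliers: the published explicit Beta shapes
  (mild β(81.27; 8.08), moderate β(153; 62.55), severe β(13.76; 29.38)).
* Visit counts per case: one draw from Binomial(1000, mean/1000), which
  preserves the mean. Taken literally this puts a standard deviation of
  ≈1.0 visits on the 1.17-visit primary-care mean and ≈0.22 on the
  0.05-visit inpatient mean, so cost-side credible intervals are wide;
  the QALY side is unaffected.
* Everything else (demography, incidence, unit costs, programme,
  efficacy) is fixed, matching the published uncertainty table.

The acute pain-severity row for under-70s is published summing to 1.01;
rows within 0.02 of 1 are renormalised on load, anything further off is a
validation error. Validation also enforces probability bounds, monotone
band mortality, the mild > moderate > severe multiplier ordering, a
category mix summing to 1, and non-negative costs, naming the offending
field.

### Reconstructed inputs

Three inputs the model needs are not published and ship as flagged
package defaults (see `basecase_manifest()`):

* **One-dose year-1 protection**: 0.70, between published single-dose
  estimates; it affects only the 25.1% of vaccinees who skip dose two,
  and only in year 1. Configurable per scenario.
* **Complication-category mix**: 95% of episodes uncomplicated (B02.9),
  the remaining 5% split evenly across B02.2/B02.3/B02.7/B02.8.
  Complications are rare in the source registry; sensitivity to this
  choice can be probed through the one-way runner.
* **Trial-scenario years 2–10**: a linear decline of 3.1 percentage
  points per year from 97.7% (the published ten-year average rate),
  continued beyond year 10 and floored at zero. An explicit year-by-year
  vector can be supplied to override the parametric rule. The same
  absolute waning applies to the observational curve from year 2.

The PHN severity split (0.89 moderate / 0.11 severe) carries no mild
mass; mild is kept as a structural state with zero default probability so
alternative splits are configurable.

## Episode outcomes

Expected QALY loss per episode adds the acute month (age-group severity
mix, multiplicative decrement on baseline utility) and, with the
age-band PHN probability, the severity-weighted PHN months (7/10/13).
Individuals return to baseline utility immediately afterwards. Expected
cost per episode mixes the five ICD-10 categories: visits times unit
costs, plus an antiviral course for 62% of cases, plus analgesics at
16.6 EUR per month over the expected pain period — the acute month mixed
with the PHN durations by PHN probability — with uptake 20%
(uncomplicated) or 50% (complicated). Both quantities are exercised
against brute-force pathway enumeration and a per-person microsimulation
oracle in the test suite.

An optional stroke add-on (disabled, values user-supplied) charges each
incident episode (RR−1) × baseline stroke incidence excess strokes, each
with a one-off cost and one year at a reduced utility multiplier.

## Outcomes, threshold price, aggregation

Net cost = vaccination cost − discounted HZ-cost offset; ICER = net cost
/ discounted QALY gain, flagged (never an infinity) when the gain is not
positive. Net cost is linear in the price per dose with slope equal to
doses delivered, so the threshold price at a given WTP is solved in
closed form and verified by re-running the model at the solution
(|ICER−WTP|/WTP < 1e-6, with a bisection fallback guarding nonlinear
add-ons). Combined 65+/70+/75+ results use the population-size-weighted
mean of cohort ICERs — the estimator the underlying evaluation reports —
with the pooled-increment ratio also computed and clearly labelled; under
the linear base model the ICER is invariant to first-dose coverage, so
the published uptake variations are reported but not interpreted here.

## Sensitivity analyses

The shipped one-way set covers discounting (0%, 5%), dose-1 uptake (50%,
70%), dose-2 compliance (50%, 100%), no protection after year 10, PHN
proportions at mean ± 1.96 SE (a normal approximation to the unpublished
meta-analytic interval limits), and all healthcare unit costs ±40%
(vaccine price excluded — it is the decision variable). Stroke and the
four alternative HRQoL-multiplier sets from other European evaluations
are accepted by the same override mechanism but ship without values, as
those are not published.

The PSA makes 1,000 full model evaluations. One master seed spawns an
independent child stream per draw, so adding a parameter leaves other
draws' values untouched and runs are bit-reproducible. Credible
intervals are the empirical 2.5th/97.5th percentiles of the incremental
outcomes (not of the ICER ratio); the per-draw ICER and the
ratio-of-means ICER are both reported. Visit-count draws are per draw,
not per cohort.

## Numerical choices and degenerate inputs

* Cohort arithmetic is vectorised over cycles; occupancy conservation is
  exact (survival is a cumulative product, deaths a difference).
* Discount rate 0 makes discounted and undiscounted totals identical to
  1e-9 relative; this is tested.
* All-fixed parameter sets (no se/shape/n fields) make `draw_parameters`
  the identity and collapse PSA intervals to zero width.
* Zero coverage gives a multiplier of exactly 1 and a zero QALY gain;
  the ICER is then flagged undefined rather than divided.
* Ties in tornado ordering are broken by input order; low/high pairs
  stay adjacent via their group label.

## What the synthetic generator does and does not emulate

`random_parameter_set` perturbs the base case multiplicatively within
ranges plausible for an elderly European population (incidence 0.5–1.5×,
mortality ±20% re-sorted to stay monotone, utilities ±10%, costs
0.6–1.6×, efficacy scaled toward the observational end), and every draw
passes full validation. It emulates the *statistical shape* of the real
inputs — bounded probabilities, ordered multipliers, non-negative costs —
not their joint structure: real incidence, mortality and utilization are
correlated through underlying health status, and real efficacy estimates
come with sampling covariance across years. Tests passing on synthetic
sets therefore demonstrate engine correctness and invariance properties,
not calibration to any real population.

## Known limitations

* Static cohort model: no herd effects (HZ is reactivation, not
  transmission at these ages), no HZ-attributable mortality, no booster
  doses, no immunocompromised stratification.
* Episode costs use the published registry utilization only; PHN-specific
  utilization beyond analgesic months is not published and is not
  modelled, so absolute cost offsets are conservative relative to models
  that include it.
* The waning rule between trial read-outs is a linear reconstruction;
  supplying the trial's year-by-year estimates via `explicit_ve` is
  preferred when available.
* Stroke effects are first-year only; longer-run sequelae and mortality
  would need additional states.
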
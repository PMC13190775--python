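# zoster-cea

A Markov cohort cost-effectiveness model of adjuvanted recombinant zoster
vaccination (RZV, two doses) versus no vaccination for the Swedish
population aged 65 and over, from a healthcare perspective.

Herpes zoster (HZ, shingles) is a reactivation of latent varicella-zoster
virus whose incidence and complication burden — above all post-herpetic
neuralgia (PHN), pain persisting three months or more — rise steeply in
old age. The package is aimed at health economists and vaccination
policy analysts who want a transparent, scriptable version of this class
of decision model: to reproduce the published Swedish base case, to probe
its assumptions one parameter at a time, or to re-run it with their own
inputs (other countries' demography, newer effectiveness estimates,
negotiated prices).

## The model

Eight five-year age-sex cohorts (65–69 … 100+) are projected in annual
cycles to age 105. Each cycle, persons die with the band-specific
all-cause probability *q(a,s)*, and survivors develop an HZ episode with
probability *inc(a,s) · m(t)*, where the vaccinated arm's incidence
multiplier combines first-dose coverage *c* = 63%, second-dose compliance
*q* = 74.9%, and the scenario's efficacy curve:

```
m(t) = 1 − c · [ q · VE₂(t) + (1 − q) · VE₁(t) ]
```

Two-dose protection starts at 97.7% (scenario I, trial efficacy) or 79.2%
(scenario II, observational effectiveness) in year 1 and wanes by an
absolute 3.1 percentage points per year, floored at zero; one dose
protects in year 1 only. Each episode is charged, in its onset cycle, an
expected QALY loss

```
ΔQALY = Σₛ p(s|age) · u(a,s) · (1 − mₛ) · 1/12
      + p_PHN(a) · Σₛ p_PHN(s) · u(a,s) · (1 − mₛ) · Dₛ/12
```

(pain states retain fraction *mₛ* of baseline utility *u*; PHN severities
last *Dₛ* = 7/10/13 months) and an expected cost built from the
registry visit counts times 2021-EUR unit costs plus antiviral and
analgesic use. Cycle *t* is discounted by (1+3%)^−(t−1). The incremental
cost-effectiveness ratio (ICER) divides net cost (vaccination cost minus
HZ cost offset) by the QALY gain; since net cost is linear in the price
per dose, the threshold price at a willingness to pay (WTP) of 80,000
EUR/QALY is solved in closed form. Parameter uncertainty propagates
through a 1,000-draw probabilistic sensitivity analysis (Beta-distributed
proportions and utilities, Binomial visit counts) with empirical 95%
credible intervals and acceptability curves.

See `docs/methods.md` for assumptions, reconstructed inputs and known
limitations.

## Worked example

```python
from zoster_cea import basecase_fixture, evaluate_cohort, threshold_price

params = basecase_fixture()
res = evaluate_cohort(params, start_age=65, scenario_id="rct")
print(res.summary().to_string())
```

prints (values in expected episodes, QALYs and 2021 EUR):

```
cohort                                65-69
scenario                                rct
hz_cases_rzv                      71672.175
hz_cases_no_vaccination        98815.926548
hz_cases_averted               27143.751548
phn_cases_averted               3876.462801
incremental_qalys                737.001479
vaccination_costs           109288306.01304
hz_cost_offset              11942367.585969
net_cost                    97345938.427071
icer                          132083.776294
```

Vaccinating the 540,220 Swedes aged 65–69 costs ≈ 109.3 million EUR and
averts ≈ 27,100 HZ episodes (≈ 3,900 of them with PHN) over the cohort's
remaining lifetime, gaining ≈ 737 discounted QALYs at ≈ 132,000 EUR per
QALY — well above the 80,000 EUR willingness to pay. Accordingly:

```python
tp = threshold_price(params, 65, "rct", wtp=80_000.0)
print(f"threshold price: {tp.price_per_dose:.1f} EUR per dose")
# threshold price: 111.9 EUR per dose  (market price: 176.4)
```

The same analyses are available from the shell:

```sh
zoster-cea basecase --cohort 65-69 --scenario both --out results/
zoster-cea one-way --cohort 65-69 --out results/
zoster-cea psa --seed 1 --draws 1000 --scenario rct --out results/
zoster-cea threshold-price --wtp 80000 --out results/
zoster-cea price-sweep --cohort all --scenario rct --out results/
```

Every run writes tidy CSV/JSON plus a `run.log` with the seed,
configuration checksum and package version.

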
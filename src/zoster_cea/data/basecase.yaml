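# Swedish RZV base case, 2021 EUR.
#
# Values are the published model inputs (demography, HZ epidemiology,
# utilities, utilization, unit costs, programme assumptions).  Fields marked
# "reconstruction" are not published and carry package defaults; see the
# fixture manifest (zoster_cea.fixtures.basecase_manifest) and
# docs/methods.md.
fixture_id: sweden-rzv-basecase-2021

demography:
  cohort_size:          # persons per 5-year band, December 2021
    65-69: {female: 272568, male: 267652}
    70-74: {female: 275284, male: 260832}
    75-79: {female: 251189, male: 231607}
    80-84: {female: 159458, male: 131553}
    85-89: {female: 100350, male: 66971}
    90-94: {female: 52199, male: 25549}
    95-99: {female: 15643, male: 5239}
    100+: {female: 2226, male: 436}
  death_probability:    # annual all-cause probability of death
    65-69: {female: 0.010, male: 0.008}
    70-74: {female: 0.016, male: 0.013}
    75-79: {female: 0.027, male: 0.022}
    80-84: {female: 0.049, male: 0.042}
    85-89: {female: 0.093, male: 0.080}
    90-94: {female: 0.167, male: 0.153}
    95-99: {female: 0.251, male: 0.315}
    100+: {female: 0.353, male: 0.434}

epidemiology:
  hz_incidence:         # annual probability of an HZ episode
    65-69: {female: 0.0071, male: 0.0051}
    70-74: {female: 0.009, male: 0.0068}
    75-79: {female: 0.0119, male: 0.0079}
    80-84: {female: 0.0119, male: 0.0092}
    85-89: {female: 0.0117, male: 0.0088}
    90-94: {female: 0.0131, male: 0.0089}
    95-99: {female: 0.011, male: 0.0042}
    # male 100+ is not published; carried forward from 95-99 (reconstruction)
    100+: {female: 0.0083, male: 0.0042}
  phn_given_hz:         # proportion of HZ episodes developing PHN, mean (SE)
    65-69: {mean: 0.12, se: 0.022}
    70-74: {mean: 0.15, se: 0.016}
    75-79: {mean: 0.15, se: 0.016}
    80-84: {mean: 0.15, se: 0.015}
    85+: {mean: 0.16, se: 0.015}
  hz_pain_severity:     # acute-episode pain mix (the under-70 row sums to
                        # 1.01 as published and is renormalised on load)
    under70: {no_pain: 0.65, mild: 0.24, moderate: 0.04, severe: 0.08}
    70plus: {no_pain: 0.45, mild: 0.41, moderate: 0.05, severe: 0.09}
  phn_pain_severity:    # mild kept as a structural state with zero mass
    mild: 0.0
    moderate: 0.89
    severe: 0.11
  duration_months:      # pain durations; analgesics run for the pain period
    hz: 1.0
    mild: 7.0
    moderate: 10.0
    severe: 13.0

utilities:
  baseline:             # general-population HRQoL (EQ-5D-3L), mean (SE)
    65-69:
      female: {mean: 0.75, se: 0.01}
      male: {mean: 0.78, se: 0.012}
    70-79:
      female: {mean: 0.66, se: 0.014}
      male: {mean: 0.76, se: 0.013}
    80+:
      female: {mean: 0.57, se: 0.021}
      male: {mean: 0.68, se: 0.027}
  pain_multipliers:     # fraction of baseline utility retained in pain
    mild: {mean: 0.91, alpha: 81.27, beta: 8.08}
    moderate: {mean: 0.71, alpha: 153.0, beta: 62.55}
    severe: {mean: 0.32, alpha: 13.76, beta: 29.38}

utilization:
  visits:               # mean visits per HZ case, by ICD-10 category
    B02.9: {primary: 1.17, outpatient: 0.14, inpatient: 0.05}
    B02.2: {primary: 1.38, outpatient: 0.27, inpatient: 0.14}
    B02.3: {primary: 0.87, outpatient: 1.82, inpatient: 0.17}
    B02.7: {primary: 1.00, outpatient: 0.22, inpatient: 0.15}
    B02.8: {primary: 1.25, outpatient: 0.21, inpatient: 0.11}
  binomial_n: 1000      # PSA: visit means re-drawn as Binomial(n, mean/n)
  medication_uptake:    # proportion of cases prescribed each drug class
    uncomplicated: {antivirals: 0.62, analgesics: 0.20}
    complicated: {antivirals: 0.62, analgesics: 0.50}
  category_mix:         # share of HZ episodes per category (reconstruction:
                        # complications are rare; 5% split evenly)
    B02.9: 0.95
    B02.2: 0.0125
    B02.3: 0.0125
    B02.7: 0.0125
    B02.8: 0.0125

costs:                  # unit costs, 2021 EUR (100 SEK = 10.15 EUR)
  vaccine_price_per_dose: 176.4
  administration_per_dose: 7.2
  primary_care_visit: 182.0
  outpatient_visit:
    B02.9: 369.0
    B02.2: 613.0
    B02.3: 193.0
    B02.7: 393.0
    B02.8: 384.0
  inpatient_episode: 5180.0
  antiviral_course: 18.7      # one week of antivirals per treated case
  analgesic_per_month: 16.6   # per month of pain
  per_dose_metadata: {antiviral: 0.72, analgesic: 0.18}
  currency: EUR-2021

program:
  coverage: 0.63              # first-dose coverage
  compliance_second_dose: 0.749
  doses_per_completer: 2

economics:
  discount_rate: 0.03
  wtp_per_qaly: 80000.0
  max_age: 105
  cycle_length_years: 1.0

scenarios:
  rct:                        # efficacy from long-term RCT follow-up
    scenario_id: rct
    ve_year1_two_dose: 0.977
    waning_per_year: 0.031
    one_dose_ve_year1: 0.70   # not published; reconstruction
    one_dose_ve_later: 0.0
    zero_after_10_years: false
  observational:              # effectiveness from observational meta-analysis
    scenario_id: observational
    ve_year1_two_dose: 0.792
    waning_per_year: 0.031
    one_dose_ve_year1: 0.70   # not published; reconstruction
    one_dose_ve_later: 0.0
    zero_after_10_years: false

stroke:
  enabled: false              # optional add-on; values are user-supplied
  relative_risk_first_year: 1.0
  cost_per_stroke: 0.0
  utility_multiplier_first_year: 1.0
  baseline_incidence: null
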
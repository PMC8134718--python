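# National cancer incidence and mortality baselines (France, 2018) with the
# per-tumor rates used by the tumor-specific comparison. Each block carries a
# `source` string; the nationwide observed reduction is an external figure
# recorded as-is, never recomputed by this package.
baseline:
  monthly_new_cases: 31833
  annual_new_cases: 382000
  annual_deaths: 157400
  national_observed_reduction: 0.233
  sources:
    annual_new_cases: "INCA / e-cancer.fr, new solid-tumor diagnoses, 2018"
    annual_deaths: "INCA / e-cancer.fr, cancer-related deaths, 2018"
    monthly_new_cases: "e-cancer.fr, new diagnoses per month"
    national_observed_reduction: "national social security platform, new cancer diagnoses Jan-Jul 2020 vs 2019, consulted 24 Nov 2020"

risk:
  rd: 0.41
  hr: 1.06

hr_sweep: [1.02, 1.06, 1.1]

resolution_month: [2020, 8]

grid:
  extra_months: [0, 1, 2, 3, 4]
  extra_fraction: [0.0, 0.05, 0.10, 0.15, 0.20, 0.25]

# Five-tumor comparison inputs: national 2018 incidence/deaths, hazard ratio
# per month of delay (1.08 for breast surgery, 1.06 elsewhere), and the
# network's March-July new-patient counts in the reference (2019) and
# observation (2020) years.
tumors:
  - label: colorectal
    annual_incidence: 20120
    annual_deaths: 7908
    hr: 1.06
    missing_ref: 1626
    missing_obs: 1439
  - label: head_and_neck
    annual_incidence: 4298
    annual_deaths: 1055
    hr: 1.06
    missing_ref: 1977
    missing_obs: 1826
  - label: bladder
    annual_incidence: 2448
    annual_deaths: 1223
    hr: 1.06
    missing_ref: 553
    missing_obs: 514
  - label: breast
    annual_incidence: 58547
    annual_deaths: 12146
    hr: 1.08
    missing_ref: 10115
    missing_obs: 8194
  - label: lung
    annual_incidence: 15132
    annual_deaths: 10356
    hr: 1.06
    missing_ref: 2701
    missing_obs: 2590
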
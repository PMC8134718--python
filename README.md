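# oncodelay

Estimating the excess cancer mortality caused by pandemic-related delays in
new cancer diagnoses.

During the first COVID-19 lockdown, hospital networks saw a sharp drop in
*newly diagnosed* cancer patients while the care of previously diagnosed
patients continued normally. Those missing patients were not cured
elsewhere — their diagnoses were deferred, and delayed diagnosis and
treatment measurably raise cancer-specific mortality. This package, written
for epidemiologists and health-service researchers, couples the descriptive
analysis of such monthly shortfalls with a closed-form model of the
resulting excess deaths, and includes a synthetic cohort generator so the
whole pipeline can be validated against known parameters.

## The model

Let `RD` be the baseline probability of dying from the cancer without delay
and `HR` the hazard ratio of cancer death per month of diagnostic delay. An
`n`-month delay scales the cumulative hazard by `HRⁿ`, giving a death rate
under delay of

```
RDdel = 1 − exp(ln(1 − RD) · HRⁿ) = 1 − S^(HRⁿ),   S = 1 − RD
```

If a shortfall month has `N` missing patients who re-enter care `n` months
later, the expected excess deaths for that month are `N · (RDdel − RD)`.
Totals over the shortfall window, hazard-ratio sweeps, sensitivity grids
over additional months of delay and additional percentage points of
reduction, and per-tumor variants (tumor-specific `RD` and `HR`) are sums
of this one expression.

Defaults reflect the French national figures: `RD = 0.41` (157 400 cancer
deaths / 382 000 new solid-tumor diagnoses per year, 2018), `HR = 1.06` per
month of delay, and 31 833 new diagnoses per month nationally.

## Worked example

The embedded network data (17 comprehensive cancer centers, January–July of
2019 and 2020) drive the whole analysis. The numbered scripts under
`analysis/` run it end to end:

```
$ python analysis/01_network_reduction.py
Jan-Jul new diagnoses: 43947 vs 47159 (-6.8%)
Mar-Jul new diagnoses: 29844 vs 33706 (-11.5%), 3862 patients with delayed diagnosis
Per-month reductions: -1.4%, -20.6%, -21.8%, -1.8%, -11.3%
New vs previously diagnosed shift: chi-square p = 1.47e-32
High vs low epidemic-zone centers: U = 18, p = 0.203 (no detectable zone effect)

$ python analysis/02_national_excess.py
National missing patients Mar-Jul: 18113
Per-month excess deaths (HR 1.06): 43, 500, 393, 21, 66
Total excess deaths, base scenario: 1023
  HR 1.02: 338
  HR 1.06: 1023
  HR 1.1: 1713
```

Reading: scaling the March–July reduction fractions to the national monthly
incidence baseline yields ≈18 100 patients with delayed diagnosis. Under
the base scenario (every delayed patient treated by August, so delays run
5…1 months), the model attributes ≈1023 excess cancer deaths to those five
months at HR 1.06 — between ≈338 (optimistic HR 1.02) and ≈1713
(pessimistic HR 1.1). `analysis/03_scenario_grids.py` extends this to the
full sensitivity grids (the pessimistic cell with 4 additional months of
delay and 15 extra percentage points of reduction reaches ≈5783 deaths at
HR 1.06), `analysis/04_tumor_specific.py` compares tumor-specific
parameters against the one-size-fits-all approach for five major tumor
types, and `analysis/05_synthetic_recovery.py` validates parameter recovery
on simulated cohorts.

The same computations are available from the command line
(`oncodelay simulate|describe|estimate|tumor`) or directly from the library:

```python
from oncodelay import RiskParams, build_schedule, excess_deaths_series
from oncodelay.datasets import PUBLISHED_DIP_PROFILE, DEFAULT_RESOLUTION

missing = {m: 31833 * f for m, f in PUBLISHED_DIP_PROFILE.items()}
schedule = build_schedule(missing, DEFAULT_RESOLUTION)
est = excess_deaths_series(schedule, RiskParams(rd=0.41, hr=1.06))
print(round(est.total))  # 1023
```

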
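# Methods

## Problem and data

The package analyses monthly counts of newly diagnosed cancer patients
across a network of 17 comprehensive cancer centers (January–July of a
reference year, 2019, and an observation year, 2020, spanning the first
COVID-19 lockdown), and estimates the long-term excess cancer mortality
implied by the observed shortfall in new diagnoses. Counts are monthly
tallies per center and stratum (patient status, tumor group, sex,
metastatic stage); there is no patient-level data and no day-level timing
anywhere in the pipeline.

Two embedded tables carry the observed data: the per-center monthly counts
and the published network-level monthly totals. They are stored separately
because the source table is internally inconsistent: the seventeen
per-center rows sum to 45 649 (2019) and 42 008 (2020) over January–July,
while the printed network totals — used by every narrative figure — read
47 159 and 43 947. Each series is self-consistent (per-center rows
reproduce their own row totals and ratios; the totals row reproduces every
aggregate quoted in the text), so the package validates each internally
and freezes the gap as a documented constant rather than asserting
cross-consistency that the source itself violates. All descriptive and
model results use the network totals.

## Descriptive statistics

For an observation versus reference year, the per-month reduction fraction
is `f_m = (ref_m − obs_m)/ref_m` (signed; a negative value is an
increase). "Missing" patients — interpreted as patients whose diagnosis
was delayed — are the clamped deficits `max(ref_m − obs_m, 0)`: months
with a net increase contribute zero delayed patients, not negative ones.
Over March–July the observed window has only deficits, so clamping does
not change the total (3862 network-wide).

Hypothesis tests mirror the source analysis: Pearson chi-square on 2×2
tables without continuity correction (all compared counts are in the
thousands), and a two-sided Mann–Whitney rank-sum test for the high- vs
low-epidemic-zone center comparison. The rank-sum test enumerates all
label assignments exactly when the combined sample size is ≤ 12 and
otherwise uses the normal approximation with midranks and tie-corrected
variance, *without* continuity correction — that choice reproduces the
published zone-comparison p-value (0.203) exactly; with continuity the
value would be 0.223. Degenerate inputs (all pooled values identical)
return p = 1 with an explicit flag.

## The excess-mortality model

A month of diagnostic delay is treated as a proportional-hazards shift on
the lifetime probability of cancer death. With baseline death rate `RD`
and hazard ratio `HR` per month of delay, an `n`-month delay multiplies
the cumulative hazard by `HR^n`:

    RDdel(n) = 1 − exp(ln(1 − RD) · HR^n) = 1 − (1 − RD)^(HR^n)

and a shortfall month with `N` missing patients contributes
`N · (RDdel(n) − RD)` expected excess deaths. The delay `n` counts whole
months from the shortfall month to the *resolution month* by which all
delayed patients are assumed to have entered care (August of the
observation year by default, so March–July map to n = 5…1). This
assignment reproduces the published national per-month figures
(42, 502, 393, 20, 67) to within rounding; no other assignment does.

Key assumptions, inherited from the modelling tradition this follows:

- every missing patient eventually re-enters care at the resolution month
  (no compensatory surge and no permanently lost patients);
- the hazard ratio acts multiplicatively and exponentially in months of
  delay (`HR^n`, not a linear approximation), uniformly across ages and
  stages;
- excess deaths are linear in the number of missing patients, so national
  extrapolation can scale reduction *fractions* by a national monthly
  incidence baseline (31 833 new diagnoses/month) rather than raw counts.

No confidence intervals are produced: the model is a deterministic
transformation of point inputs, and its dominant uncertainties (the HR,
the delay distribution, the true national shortfall) are explored by
scenario sweeps instead.

### Scenario grids

The sensitivity grid varies (a) additional months of delay beyond the
resolution month, rows 0–4, and (b) additional reduction percentage
points added to every monthly fraction, columns 0–25%, one panel per HR
in {1.02, 1.06, 1.1}. Months whose shifted fraction is non-positive
contribute zero missing patients (consistent with clamping); a shifted
fraction reaching 100% is a configuration error naming the month. Cells
are nondecreasing along both axes when HR > 1, and the (0, 0) cell equals
the base estimate exactly. The +15-point column corresponds to the
externally reported nationwide reduction (−23.3%, ~15 points below the
network's −8.3% window mean); that national figure is carried as a config
constant with a provenance note and never recomputed.

### Tumor-specific variant

For colorectal, head and neck, bladder, breast and lung cancer, the
tumor's `RD` is its national annual deaths over annual incidence, its `HR`
is delay-literature-specific (1.08 for breast, 1.06 otherwise), and its
missing patients are the window difference of its network counts. Because
per-tumor monthly profiles are not published, each tumor's missing total
is distributed over months proportionally to the network-wide
missing-patient profile (91, 1377, 1454, 111, 829)/3862. Under this
weighting the published lung-specific value (14) is not reachable — the
computation gives ≈7 with RD 0.68 — and the published "missing patients"
row itself disagrees with the difference of the printed yearly rows
(e.g. 176 vs 187 for colorectal). The package uses the differences of the
printed counts, reports its own lung value, and documents the
discrepancy instead of matching it. The five-tumor uniform-parameter
total (≈134 vs published 132) and the breast-specific estimate (≈89 vs
published 88) agree closely; the tumor-specific five-tumor total is ≈114
vs published 120.

Two further source discrepancies are stored rather than resolved: the
narrative breast window counts (10 525 / 8428) differ from the five-tumor
table's (10 115 / 8194), and the previously-diagnosed change is quoted as
+4.5% although the printed counts give +4.15%. Similarly, exact
arithmetic on the breast narrative counts gives −19.92%, printed as
−20.0%.

## Synthetic data generator

`GeneratorConfig`/`generate_cohort` emulate the structure the analysis
assumes: `n_centers` centers (default 17) with `baseline_mean` expected
new patients per center-month (default 395, chosen so the network's
January–July reference-year volume is ≈47 000), `annual_growth` secular
growth (default 3.5%/year, the middle of the observed 2.7–4.6% range), a
dip year in which month `m` loses a fraction `d_m` of expected patients
(default: the observed profile 1.4/20.6/21.8/1.8/11.3%), and independent
Poisson counts per center × month × stratum cell. Stratum cells (sex ×
stage) modulate the dip multiplicatively — deeper for women and for
nonmetastatic disease, as observed — with share-weighted mean modifier
exactly 1, so the aggregate monthly dip equals `d_m` and "parameter
recovery" is well defined. Poisson noise is the minimal count model; the
source gives no information about overdispersion. Aggregate ("all") rows
are sums of their cells by construction.

Determinism: one integer seed feeds a `SeedSequence` split per center
(spawn key = center index); replicate streams in `recovery_report` are
derived as `SeedSequence([seed, replicate])` reduced below 2³¹.

With `noise="none"` the generator emits the exact expected counts, which
are generally non-integral; observed-data ingest still enforces integer
counts, but the in-memory record type accepts non-negative reals so that
the noiseless mode can satisfy "zero bias exactly".

The recovery estimator de-trends the raw year-over-year fraction with the
known growth factor `G = (1+g)^Δyear`: `d̂_m = 1 − (obs_m/ref_m)/G`.
Interval coverage uses a Wilson binomial interval for `q = O/(R+O)`
conditional on the monthly totals, mapped to the dip scale through
`d = 1 − (q/(1−q))/G`. At the default volumes the ratio estimator's
small-sample bias (order `1/μ`) is far below Monte-Carlo error; the test
suite checks that |bias| shrinks as volume grows.

What passing synthetic tests do *not* show about real data: real monthly
counts may be overdispersed, correlated across centers (shared epidemic
shocks), and subject to reporting artefacts; the generator's independence
and Poisson assumptions make recovery easier than it would be in the
field. The synthetic checks validate the estimator and model plumbing,
not the epidemiological assumptions.

## Numerical conventions

- All arithmetic is floating point; rounding to integers is display-only
  (half-up in table outputs; full precision retained in JSON).
- `RDdel` returns `RD` exactly when `HR^n == 1` (n = 0 or HR = 1),
  avoiding the `exp(log(·))` round-trip error.
- Golden comparisons against the published tables use a 1.5% relative
  tolerance for the national estimates and grids (the source computed its
  tables from monthly percentages rounded to one decimal, which alone
  causes drift up to ~0.5%) and 5% for the five-tumor comparison.
- Additional delay (`a`) is restricted to integers 0–12 in the CLI grid
  config but any non-negative real in the library, since the formula does
  not require integrality.
- Problem sizes in the stochastic validation: 200 replicates for dip
  recovery, 60 for the end-to-end total, and 10⁵ Bernoulli draws for the
  Monte-Carlo check of the closed form; at these sizes every Monte-Carlo
  standard error is well below the tolerances being checked.

## Known limitations

- No patient-level survival modelling, stage/age-specific hazards, or
  COVID-infection mortality: the model quantifies only cancer-specific
  deaths attributable to delayed diagnosis.
- The resolution-month assumption is optimistic (no delays beyond it) and
  the network-based reduction is a lower bound on the national one; both
  are explored only through the scenario axes.
- The hazard ratios are inputs taken from the delay literature, not
  estimated by this package.
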
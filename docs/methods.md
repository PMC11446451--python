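# Methods

## Estimand and model

The quantity estimated is the annual incidence of type II diabetes in a fixed
baseline cohort, defined as the year-on-year increase in the cohort's
*cumulative* (ever-diagnosed) prevalence. With a fixed denominator n per
stratum and cumulative case counts C_t over fiscal years t = 0,…,T−1, the
per-stratum estimator is the ordinary least-squares slope of p_t = C_t/n on
t. This is a prevalence-increment estimand, not an at-risk hazard: the
denominator keeps decedents and never removes prevalent cases, so the slope
is interpretable as "percentage points of the baseline cohort newly
diagnosed per year". The slope is invariant to affine recoding of the year
axis (asserted in tests), so the 0-based year index is a pure convention.

Pooling over the 24 sex × age-band strata takes two algebraically linked
forms:

- **Aggregate slope**: sum counts over summed fixed denominators and take
  the slope of the aggregate series. Because each stratum's denominator is
  constant over years, this equals the denominator-weighted mean of the
  per-stratum slopes (identity asserted to 1e-10).
- **Weighted linear model**: weighted least squares (Gaussian error,
  identity link) of the stratum-year proportions on the year index with age
  band, sex and their interaction as intercept shifts and the fixed
  denominators as weights. With a balanced stratum-year table the year
  coefficient equals the aggregate slope exactly; its Wald 95% CI is
  β̂ ± 1.96·SE from the WLS fit. A generalized-linear (e.g. binomial-family)
  alternative is deliberately out of scope: the estimand is a linear annual
  increment. Year × covariate interactions are excluded because a single
  pooled annual increase is the target; factor terms with one observed level
  are dropped automatically (single-sex tables).

The model CI should be read as a soft uncertainty statement. Stratum-year
proportions computed from overlapping cumulative counts are serially
correlated, which a stratum-level WLS does not model; the interval brackets
the point estimate but its exact width depends on specification choices the
method itself leaves open.

## Cohort and ascertainment rules

- Fiscal years run April–March. Continuity is month-resolved: a retained
  person is covered every month from April of the first fiscal year through
  March after the last one, or through an in-window death with no prior gap.
  Classification precedence: late entry, then internal gap, then death, then
  full coverage; truncated coverage without death classifies as "left".
  Re-enrollment after a gap is exclusion, not re-entry.
- "Aged over 40" is implemented as age ≥ 40 at baseline; bands are the
  five-year groups 40–44 … 90–94, 95– and are frozen at the baseline age
  for the whole window (a 63-year-old stays in 60–64).
- Case ascertainment uses diagnosis claims only, matched by ICD-10 category
  prefix (E11–E14, so E11.9 etc. qualify); suspected (rule-out) diagnoses
  never count; prescriptions never set the diagnosis flag. Carry-forward
  (cumulative OR) encodes irreversibility and is idempotent.
- Medication use = any prescription with drug price reference prefix 396
  that year; insulin = membership in an explicit configurable code list,
  because insulin products sit outside prefix 396 and no authoritative list
  ships with the package (the defaults are synthetic placeholder codes with
  prefix 2492). Utilization has no carry-forward — real utilization lapses.
- Two denominators are kept strictly apart: per-fiscal-year tables use the
  open population enrolled in each year; cumulative prevalence and all
  incidence estimates use the fixed baseline cohort.

## Synthetic data generator

The generator emulates the administrative structure the pipeline assumes:
an enrollment ledger covering claim-free persons, irreversible onset,
diagnosis/prescription claim lines, deaths that truncate the spell but stay
in the cohort, and disenrollment that excludes.

Onset is parameterized on the estimand directly: for a not-yet-diagnosed,
alive person-year the onset probability is
`annual_increase / (1 − expected prevalence so far)`, so the expected annual
increase in the fixed cohort's ever-diagnosed fraction equals
`annual_increase` exactly when no one dies. Mortality attenuates the realized
slope (a decedent can no longer convert but stays in the denominator) — this
is a property of the estimand, not a bug, and the default-conditions
end-to-end run therefore sits a few tenths of a point below the configured
per-stratum increases.

Defaults are the study conditions: the 24 strata take their weights,
baseline prevalences and annual increases from the bundled published
cumulative counts (total n = 62,617, baseline cumulative prevalence 25.0%,
increases 1.2–4.6 points/year). Rates the source aggregates do not pin down
were fixed once at realistic municipal-insurer values: annual death
probability 0.03, annual disenrollment 0.02, zero-claims fraction among the
undiagnosed 0.10 (matching the reported ~10% of members using no
healthcare), suspected-only diabetes claim rate 0.01 per person-year,
medication probability 0.45 and insulin probability 0.08 per case-year
(chosen so overall medication/insulin use lands near the reported 12%/2%
against 26% prevalence). Post-onset diagnosis claims are emitted every
enrolled year by default (`claim_emission_prob = 1.0`); the knob exists
because no published value calibrates intermittent coding, and carry-forward
makes the estimates insensitive to it — tests exercise 0.6.

What the generator does **not** emulate: real Japanese receipt-file layouts,
monthly diagnosis dynamics, comorbidity structure, age-dependent mortality
by default, or insurer switching. Passing tests on synthetic data therefore
demonstrate algorithmic correctness under the stated assumptions, not the
accuracy of claims-based ascertainment on real data (misdiagnosis, untreated
diabetes and coding artifacts are outside the simulation).

## Numerical choices

- Slopes use the closed-form normal equations in double precision; tests
  compare against an exact rational-arithmetic oracle at 1e-12 and the
  pooling identities at 1e-10.
- Reported percentages use decimal half-up rounding (1 decimal for
  prevalence/utilization tables, 2 for incidence), matching how such tables
  are conventionally printed.
- Small-cell masking replaces counts 0 < c < 10 and their proportions with
  "―" in rendered tables only; zero counts display, since the rule protects
  small non-zero groups from re-identification. Threshold and marker are
  configurable.
- Degenerate inputs: series shorter than two years, empty strata lists,
  empty insulin code lists, overlapping ledger spells and conflicting
  person attributes all raise typed errors naming the offending field or
  person; an empty claims table yields all-zero series and a zero slope.
- Problem sizes in the test suite and acceptance script (up to 20,000
  simulated persons, 5 seeds for recovery) were chosen as the smallest sizes
  at which binomial noise is well inside the 3-SE recovery bands; the SE of
  a cumulative-series slope accounts for the positive covariance
  Cov(p_i, p_j) = p_i(1 − p_j)/n of overlapping cumulative proportions.

## Known limitations

- The insulin code list is a stand-in; real analyses must supply the
  insurer's actual product codes.
- Whether persons entering the combined insurer system mid-window count as
  continuous is resolved here by treating the ledger as one system
  (month-contiguity is all that matters); other readings would shrink the
  cohort.
- The weighted-model CI understates between-year dependence (see above).
- Incidence-as-slope assumes the cumulative series is close to linear over
  the window; strong curvature (e.g. saturating prevalence in the oldest
  bands) biases the single-slope summary toward the average increment.
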
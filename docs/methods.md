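# Methods

## Model structure and assumptions

The engine is a deterministic (expected-value) Markov cohort model.
States: never smoker, current smoker, former smoker, dead; dead is
absorbing. Cycle length is fixed at 0.5 years. One model instance covers a
single birth-year × gender cohort from entry at age 15 — entirely never
smokers, since the policy acts on uptake and uptake before 15 is folded
into the age-15+ start schedule — to a hard cap at age 100, after which any
survivors are absorbed into dead and accrue nothing. The cap bounds the
state space; at realistic old-age mortality fewer than ~0.5% of a cohort
reach it, so results change negligibly.

Within a cycle the event order is: (1) status-specific death, (2) behaviour
transitions among survivors (start, quit, relapse). The order is a
convention — the data do not identify intra-cycle timing — and it is fixed
and documented so that results are reproducible to the bit. A single
former-smoker state is used (no time-since-quit stratification): relapse is
a long-term rate indexed by age only, matching the four-state design.

A smoke-free-generation policy is a multiplicative reduction of the start
probability for cohorts born after the cutoff (2009): `effectiveness = 1`
is the full ban, 0.9 the imperfect-enforcement variant. With a lag of `L`
years, cohorts born within `(cutoff, cutoff + L]` keep their unreduced
start probability until calendar year `2025 + L` (they are assumed able to
obtain tobacco illegally during the introduction period).

## Calibration

Surveys provide marginal death/disease probabilities, the smoking-status
mix, and relative risks. The status-specific probabilities are the unique
solution of the weighted-marginal constraint (closed form in the README);
a one-dimensional numeric root solve of the same constraint is kept in the
test suite as an independent oracle. The status mix used as weights is the
*input* status prevalence at each age–gender, held fixed — calibration is a
one-shot transform of survey data, not an iterative fit to the simulated
cohort. Outputs are clamped to [0, 1] with a warning (extreme relative
risks at high ages can push a status-specific probability past 1; failing
hard would make PSA sampling brittle). The weighted identity is enforced to
1e-10 pre-clamping.

Lung-cancer prevalence is constructed from annual incidence and mean
survival as the steady-state stock `prevalence = incidence × survival`,
capped at 1. The dimensionally-literal alternative (incidence ÷ survival)
is kept behind `mode="literal_divide"` for comparison but is not used: it
does not have the units of a prevalence.

Mortality calibration is single all-cause: disease-specific deaths are not
removed before applying the relative risks. The relative risks are
all-cause mortality RRs, so no double counting arises.

## Accrual, timing and discounting

Outcomes accrue per cycle with the midpoint convention: a person dying
within a cycle contributes half a cycle of life-years, QALYs, costs, tax
and GDP at the state they died from; survivors contribute a full half-year
at their end-of-cycle state. Smoking-unrelated health care costs (when the
scenario includes them) apply the survivor rate to survivors and the
decedent rate to that cycle's deaths, reflecting the much higher cost of
the last months of life.

Incident disease cases are derived from the prevalence-based model as
`max(0, prevalent_t − prevalent_{t−1} × survival fraction)`; the prevalent
counter is exposed alongside, since a prevalence-based model does not
define incidence uniquely.

Discounting is continuous-in-time at the annual rate (1.5% base):
each cycle's flows are multiplied by `(1+r)^(−t)` with `t` the years from
1 January 2025 (single time-zero for the whole multi-cohort analysis) to
the cycle midpoint (`entry + 0.25 + 0.5k`). Discounting from each cohort's
own entry year is available via `RunOptions(discount_to=None)`.

## Population rollup

A cohort born in year `b` enters in calendar year `b + 15`; its two
half-cycles per year of age fall in consecutive calendar years, so in year
`t` exactly the cohorts born 2010 … `2009 + t − 2024` are active. Because
parameters are stationary, cohorts differing only in birth year share one
unit-size trajectory; `run_all_cohorts` caches that unit run (keyed by
gender and the per-cycle policy profile, which differs within a lag window)
and rebuilds each cohort ledger by linear scaling and re-discounting. This
is an exact optimization, verified against individual runs in the tests,
and is what makes 90-cohort × 2-arm rollups and thousands of PSA
replicates cheap.

Net impacts use fixed reporting signs: QALYs/life-years as gains, health
care costs as amounts averted, tax and GDP as amounts foregone. The
threshold QALY value may be negative when cost savings alone exceed the
offsets; it is undefined (raises) when net QALYs are not positive.

The prevalence projection evolves the standing population (born on or
before the cutoff, permanently on status-quo transitions) together with a
new age-15 entering cohort each year (on the policy, once banned). The
standing population at 2025 is built from the status-prevalence inputs and
a survival-shaped age pyramid; post-2025 immigration is ignored, matching
the single immigration adjustment of the entering-cohort sizes.

## Probabilistic sensitivity analysis

Distribution families follow health-economics convention: Beta for
probabilities, prevalences and utilities; Gamma for costs; Lognormal for
relative risks; all matched by method of moments to (mean, SE) with
SE = dispersion × mean and dispersion 0.1 by default. Where the Beta match
is infeasible (SE too large near the bounds) a clipped normal is drawn with
a warning; means of exactly 0 or 1 stay degenerate. Status-prevalence
shares are renormalized to sum to one after sampling. Structural constants
— cycle length, cohort sizes, discount rate, policy definition — are not
sampled. Sampling happens *before* calibration and calibration is re-run
per replicate, since calibration is a deterministic transform of uncertain
inputs.

Each replicate's stream is `default_rng([seed, replicate_index])`, so
results are independent of execution order and bit-reproducible; a
replicate that fails is recorded and excluded, and more than 1% failing
aborts the analysis.

## Synthetic data

The generator emulates the structure of the real inputs: uptake
concentrated at ages 15–25 (Gaussian bump peaking at 17) and zero after 35;
quit probability increasing with age; relapse declining; Gompertz–Makeham
mortality per gender; disease prevalence rising logistic-ally with age;
utilities declining with age and lower for current than former than never
smokers; the published per-smoker tax/GDP constants. Its status prevalence
is the fixed point of calibrate→propagate→re-read, so the stored mix is
consistent (to well within 20%) with what the model itself produces — this
is what makes the parameter-recovery and equilibrium tests meaningful.
Seeded log-normal jitter (3%) varies levels across seeds while preserving
all validity invariants by construction.

What the generator does *not* emulate: cohort effects (rates frozen at
their current-age profiles), migration, vaping or other nicotine products,
and any correlation structure between parameters. Passing tests on
synthetic data therefore demonstrate correctness of the machinery and the
qualitative mechanics (e.g. that annual health care savings eventually
cross annual tax+GDP losses), not Canadian point estimates.

`canada_synthetic.py` is a separate, deterministic reconstruction anchored
to published aggregates (life-table survival 15→75 of ~0.735 male / ~0.84
female; daily-smoking shares at 18 of 7.5%/4.6%; $1685 tax and $711.25 GDP
per smoker-year; literature-scale relative risks; census-scale cohort
sizes of 201k/191k). Quantities that depend on the detailed unpublished
input table (absolute QALY/cost totals, the exact premature-death
percentages) reproduce the published analysis in shape and magnitude but
not to printed precision; structural quantities (the status-quo vs policy
gap, prevalence-target years) land close.

## Numerical choices and problem sizes

- Conservation of persons is exact by construction (transitions move mass,
  never create it); tests assert ≤1e-9 relative.
- The default test suite runs cohort sets of 2–5 birth years and PSA at
  ≤100 replications; all properties being tested (linearity, ordering,
  reproducibility, coverage) are size-invariant, and full 90-cohort runs
  are exercised by the Canadian reconstruction tests. A full rollup takes
  well under a second; 5000-replication PSA is minutes.
- Exact float round-tripping: YAML uses repr-based floats; CSV export uses
  `%.17g` and import parses with `float_precision="round_trip"`.
- Degenerate inputs: zero-size cohorts, empty cohort lists, all-zero start
  schedules and zero-variance PSA are all defined and tested; a stratum
  whose status shares (weighted by RRs) vanish raises a degenerate-stratum
  error rather than dividing by zero.

## Known limitations

- No individual heterogeneity beyond age, gender and smoking status; no
  smoking-intensity or time-since-quit gradients.
- Incidence is a derived counter in a prevalence-based model (see above).
- The threshold analysis treats tax and GDP losses as societal losses;
  from a welfare perspective taxation is a transfer, so the computed
  thresholds are conservative upper bounds.
- Premature-death fractions depend mainly on the mortality inputs; with
  reconstructed rather than transcribed inputs they carry the
  reconstruction's uncertainty (a point or two of absolute level).
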
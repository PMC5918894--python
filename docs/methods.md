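# Methods

## Model structure and assumptions

The simulation follows the adenoma–carcinoma sequence in continuous time.
People are created with a sex, a birth year, an other-cause death age drawn
from a sex-specific life table (uniform placement within the death year),
and a gamma frailty `z` (mean 1, variance `frailty_variance`, default 1.0)
multiplying their adenoma onset intensity. Multiple simultaneous adenomas
are allowed; each progresses independently.

All dwell and sojourn distributions are exponential with configurable
means. This is a deliberate structural choice: it keeps the model Markovian
in continuous time, makes every unit-test oracle analytic (competing
exponentials, Poisson process means, geometric survival), and leaves the
hazards as a transparent calibration surface. Piecewise-exponential
behaviour can be approximated through the piecewise-constant onset baseline;
non-exponential dwell families are not implemented.

Key default parameters (per year unless noted):

| parameter | default | meaning |
|---|---|---|
| onset baseline (male) | 0.010–0.060 over ages 20–70+ | piecewise-constant adenoma onset intensity |
| onset baseline (female) | 0.6 × male | lower female adenoma risk |
| frailty variance | 1.0 | overdispersion of adenoma counts |
| dwell small→medium / medium→large | 20 y / 18 y | mean size-state dwell times |
| transformation hazard (small/medium/large) | 0.0004 / 0.0015 / 0.015 | malignant transformation per size state |
| preclinical sojourn I→II / II→III / III→IV | 2.5 / 2.0 / 1.5 y | mean stage sojourns |
| symptomatic dx hazard I–IV | 0.05 / 0.20 / 0.45 / 0.90 | diagnosis through symptoms |
| cure fraction I–IV | 0.90 / 0.75 / 0.50 / 0.05 | share never dying of CRC after dx |
| survival mean I–IV (non-cured) | 5 / 4 / 3 / 1.5 y | exponential time to CRC death |
| colon share | 0.65 | location label split |

These natural-history values are structural surrogates chosen to put
lifetime adenoma prevalence at the high levels reported for elevated-risk
European populations (roughly 43 % of men at ages 50–54 rising to ~60 % at
65–69 under the defaults) and lifetime CRC risk in the mid-single-digit
percent range. They are the quantities the calibration module is built to
refit; none of them reproduces any registry's fitted values.

Stage at detection is the stage occupied at the detection instant (no
re-draw). Location (colon/rectum) is a tabulation label only and does not
alter dynamics. Onset intensity starts at age 20, so childhood lesions are
impossible.

## Screening programme

Biennial FIT for ages 50–69, rolled out linearly 2009→2013 (each year
activates a further fifth of the initially eligible strata; the ramp is a
modelling choice, as only the begin and completion years are fixed), with
new cohorts joining at age 50 until 2038 and people already enrolled keeping
their rounds until 69 thereafter. People aged 70+ at programme start are
never invited. Non-participants stay on the biennial clock.

FIT is modelled as class-wise per-lesion sensitivity at the 20 µg/g cut-off
plus a per-test specificity for lesion-free people. The shipped operating
characteristics (sensitivity 0.04/0.12/0.32 by adenoma size, 0.75 for
preclinical CRC; specificity 0.955; colonoscopy sensitivity 0.75/0.85/0.95
and 0.95 for CRC; complication probability 0.0025 per polypectomy
colonoscopy) are **literature surrogates**, not programme-fitted values, and
are expected to be recalibrated for any real application. Participation
defaults (0.60–0.68 first round by age band, slightly higher at successive
rounds, 0.92 colonoscopy compliance) bracket the published 64.3 % overall
participation.

Surveillance follows the size/count partition: >20 mm or ≥5 adenomas →
colonoscopy in 1 year; >10 mm or 3–4 adenomas → 3 years; 1–2 small adenomas
→ FIT in 5 years; clean colonoscopy → routine biennial FIT. Because the
model carries size *classes*, each adenoma receives a representative
diameter drawn within its class (large: 10 mm + exponential(7 mm), capped at
60 mm) solely to apply the millimetre rules. Surveillance colonoscopies
continue past 69 for people already in a surveillance pathway
(`surveillance_after_69`, default on); routine FIT does not.

The correlated false-negative scenario flags a fraction
`systematic_fn_fraction` of adenomas (uniform draw stored at lesion
creation, so natural histories are byte-identical across scenarios) as
persistently FIT-undetectable. The flag applies to the adenoma phase only;
a lesion that has transformed to preclinical CRC is testable with the CRC
sensitivity, since persistent non-bleeding is a lesion property that the
data behind the scenario ties to precursor lesions, not invasive disease.

## Common random numbers and the no-harm floor

Every person owns one substream per concern (population attributes, natural
history, participation, FIT noise, colonoscopy noise), derived from the
master seed by a splitmix64 counter scheme. Toggling any screening
parameter therefore leaves every natural history unchanged, and paired-arm
differences are intervention effects, not sampling noise.

A screen-detected cancer re-evaluates survival at the detected (earlier)
stage using the same uniform draws as the counterfactual. Because lead time
and a longer survival draw can still cross, the screened CRC death age is
additionally floored at the counterfactual death age ("no harm from early
detection"). This makes the per-person guarantee exact: screening can only
preserve or extend each individual's life.

## Economics

Costs are booked in the calendar year of the event, in 2012 euros, with no
inflation adjustment. Discounting is annual at 3 % from base year 2009
(the rate is published; base year and compounding are package choices);
costs and disutilities from pre-2009 events — which are identical in both
arms — are valued at the base year. Day-based disutilities convert at
365 days/year (2 → 0.0055, 14 → 0.0384 QALY at 4-decimal rounding).
Life-years accrue continuously and are discounted by the factor of the
calendar year containing them; a mid-year convention is not applied.

Treatment costing: stages I–III book the initial cost in the diagnosis year
plus €404 for each *completed* survival year up to a configurable cap
(default 5 years — the published follow-up duration is not stated); stage IV
books €24,255 for each *started* year alive with the disease, with no
separate initial cost. The stage-IV amount is the published flat annual
figure; a regression-based stage-IV cost model is deliberately out of
scope. Clinical diagnoses in either arm book one work-up colonoscopy priced
at the without-polypectomy tariff. Per-stage annual utility losses while
living with diagnosed CRC (0.05/0.10/0.15/0.30, capped like follow-up for
stages I–III) are configurable surrogates.

Arms are reduced to per-year event *counts* before pricing, so re-pricing
the same logs (e.g. the invitation-cost sweep) provably cannot change
counts, QALYs or colonoscopy projections.

## Calibration

The objective is a weighted Pearson deviance: squared residuals scaled by
binomial standard errors for prevalence cells and Poisson standard errors
for incidence cells (empty cells fall back to a nominal n of 1000 /
100,000 person-years). Every evaluation simulates a fixed-seed cohort, so
the surface is deterministic and Nelder–Mead applies. Free parameters are
searched on the log scale with an explicit initial simplex (step 0.3 in log
space) because scipy's default simplex collapses when a coordinate starts
at 0 (log of a unit scale). Random restarts are available
(`optimizer_config={"n_restarts": k}`) but default to 0: the shipped
recovery problems are low-dimensional and deterministic under common random
numbers, so restarts only multiply runtime. Sexes are calibrated
independently by freeing the corresponding per-sex onset scales.

## Synthetic data: what it emulates and what it does not

The generators stand in for inputs that cannot be shipped: Gompertz–Makeham
life tables (two to three interpretable parameters suffice to emulate a
2008 European table, with a female survival advantage), a demography
pyramid with a piecewise-linear baby-boom bulge centred near age 40 in 2008
(so the unscreened budget projection shows aging-driven cost growth), and
target tables generated by simulating the natural history with known
parameters. Calibration tests are therefore *parameter recovery*
experiments: passing them shows the machinery can find known truth under
the model's own assumptions. It does not show that the defaults reproduce
any real registry, that real FIT behaviour is class-wise independent per
lesion, or that real dwell times are exponential. Demography counts conserve
totals exactly (largest-remainder rounding; the female total is
round(total × share)).

## Numerical choices and degenerate inputs

- Life-table q values come from the exact integrated Gompertz–Makeham
  hazard per year of age; probabilities numerically reaching 1 before the
  terminal age are clamped with a warning; the terminal age always has q=1.
- Poisson onset counts use Knuth's product method (interval means are ≪10).
- Uniform draws entering logs are floored at 1e-300.
- Zero transformation hazards produce inert adenomas and exactly zero
  incidence; zero participation reproduces the counterfactual arm exactly
  apart from invitation events.
- Ties between a symptomatic diagnosis and a screening contact at the same
  instant resolve in favour of the diagnosis.
- Non-finite calibration objectives are rejected with a large sentinel so
  the simplex retreats.

## Problem sizes

Desk-scale defaults: scenario runs use a population scale such that
~200,000 simulated individuals represent the 2.23 M population
(scale factor ≈ 11.15 applied to outputs), which keeps paired-arm Monte
Carlo error small enough for the directional checks; calibration recovery
uses 50,000 individuals per evaluation; analytic-oracle checks use 10,000
draws against 3-standard-error bands. These sizes are the package's own
defaults for interactive work and are configurable.

## Known limitations

- No migration, no post-2008 birth cohorts, no secular mortality or
  incidence trends.
- No serrated pathway, no adenoma regression, no primary prevention.
- Natural-history and test-characteristic defaults are surrogates; all
  headline economic magnitudes depend on them and should be read as
  model-consistent, not registry-calibrated.
- No probabilistic sensitivity analysis; uncertainty handling is limited to
  the scenario switches and the invitation-cost sweep.
- The 2008 prevalent population is simulated from birth, so pre-2009
  diagnoses exist in both arms; their costs are identical across arms and
  cancel in every incremental result.
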
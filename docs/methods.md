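# Methods

## Model structure and assumptions

Fluoride kinetics are represented as a linear, flow-limited (perfusion
limited) compartmental system frozen at the reference age for the whole
simulation (no growth, no bone resorption — appropriate for a
steady-state analysis in growing children, whose skeletons are net
accumulators of fluoride).

State variables (amounts, mg): liver, kidney, bone tissue, rest-of-body,
blood, bone mineral, cumulative urine.  For each perfused tissue `t`:

    dA_t/dt = Q_t (C_art − A_t / (V_t P_t))        (+ infusion, liver only)

with `C_art = A_blood / V_blood` and venous return mixed
flow-proportionally.  Ingested fluoride from all sources is converted to
an absorbed daily dose via source-specific oral bioavailability (water
0.83, toothpaste 1.0, air 1.0, diet 0.40, soil 0.40) and delivered as a
constant infusion into the liver over 24 h (`rate = dose / 1440` mg/min);
no gastrointestinal compartment is modelled, since no oral absorption
rate constant for fluoride is available at these ages.

Elimination and sequestration both act on the arterial concentration
(configurable to the venous mixture):

- renal: `dU/dt = CL_r · C_art` into cumulative urine;
- bone mineral: `dM/dt = CL_b · C_art − k_ret · M`.

### Bone handling — the central structural choice

Two variants are implemented:

- **`store` (default)** — the bone mineral pool is a reversible, slowly
  equilibrating reservoir with `k_ret = CL_b / (V_bone · P_mineral)`.
  Net bone flux vanishes as the pool fills, so at steady state the entire
  absorbed dose is recovered in urine, and the pool's filling time
  constant (≈ 25 days at age 4 under the default configuration, i.e.
  within 1% of steady state at ≈ 120 days) produces the characteristic
  ~150-day approach of daily urinary excretion to its asymptote.
- **`sink`** — irreversible uptake at `CL_b · C_art` (`k_ret = 0`).  The
  steady-state urinary fraction of the dose is then exactly
  `CL_r / (CL_r + CL_b)`, which the test suite verifies against the
  closed form.

The `store` default is deliberate.  The reported behaviour this package
reproduces — a calibration factor near 0.43 against cohorts whose
measured excretion is ~40% of absorbed intake, scenario urinary
concentrations of ~0.85 mg/L at 0.5 L/day urine output, and a months-long
approach to steady state — is only mutually consistent if nearly the full
absorbed dose reaches urine once steady state is attained.  A pure sink
with the age-appropriate clearance split (bone ≈ 81% at age 4) caps the
urinary fraction at ~19% and cannot reproduce those observations under
any parameter values; an equilibrating store reproduces all of them,
including the signs of the sensitivity indices (renal clearance: negative
on blood AUC, positive on 24-h excretion; bone volume: negative on both).

## Parameters, units, defaults

All values the underlying literature leaves unprinted are explicit
entries in `src/fluokin/data/default_config.yaml`, not constants in code:

| parameter | default | units | rationale |
|---|---|---|---|
| adult reference plasma clearance | 0.09 | L/min at 70 kg | literature-scale adult fluoride plasma clearance; scaled by `(BW/70)^0.75` |
| cardiac output | `0.235·BW^0.81` | L/min | standard pediatric allometric form (≈ 2.2 L/min at 16 kg) |
| blood volume | 7.7% BW | L | reference-child whole blood |
| liver / kidney / bone / rest volumes | 3.2 / 0.6 / 7 / 60 % BW | L | sex-averaged reference-child fractions |
| tissue flows | 25 / 18 / 5 / 52 % CO | L/min | must sum to exactly 1.0 (validated at load) |
| partition coefficients | 0.75 / 0.75 / 1.0 / 0.5 | — | soft-tissue:blood fluoride ratios below unity; bone water ≈ 1 |
| bone mineral partition | 150 | — | operational affinity of the mineral pool; sets the slow time constant to the stated ~150-day steady-state approach |
| daily urine volume | 0.5 (age 4), 0.7 (age 8) | L/day | converts excreted amount to concentration; **calibration-sensitive** — it scales every reported concentration and every inverted dose inversely, and is interpolated linearly between listed ages |
| clearance split vs age | (0,90)→(18,50) bone; (0,10)→(18,50) renal | % | two-point lines; exact age is used, not the age-group midpoint |

The age-4 and age-8 anthropometry (16 kg/103 cm, 25 kg/127 cm) are
growth-chart 50th percentiles; validation-cohort ages 5 and 7 use linear
interpolation between them.

Exposure scenarios: `ontario-s1` uses fluoridated tap water at 0.7 mg/L —
the concentration the scenario is defined by and the one the
water-contribution figure of 25% refers to; an `ontario-population`
preset carries the 0.505 mg/L coverage-weighted equivalent
(0.70·0.7 + 0.30·0.05).  The Quebec presets keep the reported population
equivalent of 0.06 mg/L although the exact weighted mean is 0.06625
(0.025·0.7 + 0.975·0.05); `quebec-s3` removes the dietary source, since
water fluoride reaches food during preparation and double-counts in a
low-fluoridation province.  The aggregate bioavailability used to convert
population intake/TDI values to the absorbed scale is 0.8 (the water/diet
mix implied by 0.04/0.05).

## Calibration

For each validation cohort, the absorbed intake is
`0.40·diet + 1.0·toothpaste + 0.83·water + 1.0·supplement` (supplements
are fully absorbed tablets), simulated to day 150; the adjustment factor
is the arithmetic mean of the per-study measured/modeled ratios
(geometric mean available as an option; arithmetic is the default
reading of "average ratios").  The factor multiplies urinary outputs
exactly once — `CalibratedValue` and the bundle's `calibrated` state
guard against double application — and is *not* applied to absorbed
doses; reverse dosimetry divides by it implicitly through the forward
model.

## Reverse dosimetry

A surveyed concentration (mg/L) is multiplied by the configured daily
urine volume to get a 24-h excreted amount, and the absorbed dose is the
positive root of `calibrated_excretion(dose) − target`, found by Brent's
method on the bracket [1e-6, 1] mg/kg/day (expanded ×10 as needed,
residual tolerance 1e-10 mg/day).  Because the model is linear the
closed-form solution `target / slope` exists; it is computed as a
cross-check (`linear_dose_estimate`) but the bracketed solver remains the
primary path, mirroring the constrained single-unknown solver procedure
the analysis is defined by.  The same machinery inverts 95th-percentile
concentrations.  Because forward and inverse share one configuration, the
round trip is exact regardless of the absolute urine-volume values.

## Sensitivity analysis

The index is a one-sided normalized finite difference: each parameter is
reduced by exactly 2% of its initial value and

    SI_P = ((O_2 − O_i) / (P_2 − P_i)) · (P_i / O_i)

for the 24-h steady-state urinary excretion and the 24-h venous AUC at
day 150.  Every perturbable quantity is a multiplicative knob on an
immutable model bundle, so the index reduces to an elasticity and is
invariant to parameter units; a central-difference elasticity at ±1% is
used as a test-only cross-check.  The screen reports parameters whose
|SI| reaches 0.05 for any (age, metric) pair.  The "oral absorption
fraction" is a single global multiplier on the absorbed dose (lumped
bioavailability), and its index is exactly 1 — a built-in check of dose
linearity.

## Synthetic data

The lognormal spot-urine generator draws from
`exp(N(ln GM, ln GSD))` (so the 95th percentile is `GM · GSD^1.645`,
asserted in closed form against the distribution quantile).  The
synthetic validation cohorts draw per-source intakes uniformly from
ranges spanning the published cohorts, compute the model's own
prediction, and set `measured = bias · noise · prediction` with
lognormal multiplicative noise of **unit arithmetic mean**
(`mu = −ln²(GSD)/2`), so the arithmetic-mean ratio estimator of the
calibration stage is unbiased for the true factor; recovery to within 5%
at 200 studies (GSD 1.3) is part of the acceptance suite.

What the generators emulate: the GM/GSD reporting convention of
biomonitoring surveys, and cohort-level multiplicative measurement error.
What they do not: survey weights and sampling design, within-person
spot-to-24h variability, creatinine correction, or correlated intake
errors across sources — so passing recovery tests demonstrate estimator
correctness under the stated noise model, not robustness to real survey
artefacts.

## Numerical choices

- Default propagation is an exact augmented matrix exponential per
  checkpoint step (the system is linear time-invariant with constant
  forcing); mass balance holds to ~1e-12 relative and results are
  independent of step size.  A stiff BDF path (rtol 1e-8, atol 1e-12 mg)
  is retained and agrees with the exact path to 1e-6 in tests.
- Checkpoints default to 60 min and must divide 1440 so day boundaries
  are exact grid points; the daily excretion series is differenced
  cumulative urine at day boundaries.
- AUC is trapezoidal on the checkpoint grid; at steady state the
  integrand is nearly constant and halving the step moves the value by
  far less than 0.1%.
- Time to steady state: first day from which the daily-excretion series
  stays within the stated tolerance of the final simulated day through
  the end of the span; a band entered only on the final day itself
  returns "not converged" (steady state cannot be certified at the
  edge).
- Degenerate inputs are rejected loudly (negative states and NaNs name
  the offending compartment; zero urine volume, empty study lists,
  unbracketable inversion targets and malformed configurations raise
  typed errors).

## Problem sizes

Default analyses simulate 150 days per run (300 for the steady-state
timing), six validation simulations for the calibration factor, and
~5–10 forward runs per inversion; the full pipeline completes in a few
seconds on one core, and the statistical acceptance checks use 200
synthetic cohorts and 10,000 lognormal draws.

## Known limitations

- The default compartment fractions, partition coefficients and the
  adult reference clearance are reference-child stand-ins, not values
  transcribed from the original model; headline full-model outputs
  therefore carry the configuration's uncertainty (the package's own
  runs land within a few percent of the reported values, but this is a
  property of the documented defaults).
- Deterministic only: no inter-individual variability or Monte-Carlo
  population layer.
- The daily urine volumes are the single most calibration-sensitive
  entries; alternative values rescale concentrations and inverted doses
  exactly inversely.
- No creatinine correction or spot-sample variability: spot
  concentrations are interpreted strictly under the steady-state
  assumption.
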
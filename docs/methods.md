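# Methods

## Overview

`bonebridge` implements a bridging simulation: a treatment effect on
femoral-neck bone mineral density (BMD), estimated in premenopausal trial
participants, is applied to the observed BMD of a postmenopausal population
and propagated through a 10-year fracture-risk engine. Because the drug
effect and the outcome window are separated by decades, the question —
does premenopausal BMD loss under a GnRH antagonist meaningfully raise
postmenopausal fracture risk? — cannot be answered by follow-up; it is
answered by composing three fitted/calibrated components:

1. a **BMD trajectory model** (treatment reduction and post-treatment
   recovery),
2. a **synthetic postmenopausal cohort** with the marginal structure of a
   US DXA survey sample of women aged 50–79, and
3. a **surrogate 10-year fracture-risk engine** in the style of FRAX,
   calibrated to published untreated stratum medians.

Each subject serves as her own referent: the treated arm differs only in
BMD, shifted by the modeled treatment effect, so every per-subject risk
difference is attributable to the BMD shift alone.

## BMD trajectory model

The trajectory model is linear in treatment duration `t` (years), recovery
duration `r` (years), and regimen:

```
dBMD(t, r) = b1·t + b2·t·r + 1[BID]·(b3·t + b4·t·r)        [g/cm²]
```

with defaults `b1 = −0.0051`, `b2 = −0.0003`, `b3 = −0.0188`,
`b4 = 0.0086` — the published fixed-effect estimates of a longitudinal
mixed-effects model (subject random intercepts) fitted to phase-III visit
data. Assumptions inherited from that model:

- the effect is **additive in g/cm²** (the outcome of the fitted model is
  BMD itself, not log-BMD or percent of baseline); the printed estimates
  carry no units, and g/cm² is the interpretation adopted here;
- every term is proportional to `t`, so zero treatment implies exactly zero
  effect regardless of recovery time;
- demographic covariates of the original model (age, weight, race,
  medications, blood disease, ovary lesion) shift a subject's *level*, not
  the treatment contrast, so they cancel in treated-vs-untreated
  differences and are deliberately not part of `delta_bmd`.

The two base-case scenarios are 150 mg QD for 12 months and 200 mg BID for
3 months (half of the respective approved maxima, reflecting real-world
average durations), both followed by 6 months of recovery. Months convert
to years as `months/12` exactly.

`simulate_trial` emulates the generating design: 3:2:2 randomisation to
placebo/QD/BID, placebo re-randomised 1:1 to the active doses at month 6,
treatment through month 12, recovery visits afterwards; subject baselines
are normal (default mean 0.84, SD 0.11 g/cm², premenopausal scale) and
visit noise has SD 0.02 g/cm². `fit_trajectory` recovers the four
coefficients by the within-subject (fixed-effects) estimator: demeaning
every subject's design rows and outcomes absorbs the subject intercepts
exactly, after which ordinary least squares with intercept-corrected
degrees of freedom estimates the treatment terms. This is equivalent to
the mixed model for the fixed effects under the random-intercept
assumption and is exact in the noise-free limit; a random-intercept mixed
model (statsmodels `MixedLM`) serves as an independent cross-check in the
test suite.

## Synthetic cohort

`CohortSpec` defaults encode the study sample (n = 2303):

| quantity | default | note |
|---|---|---|
| age | observed mean 63, SD 8, range 50–79 | truncated normal, integer ages |
| race | white 1339/2303, black 507/2303, hispanic 457/2303 | exact category counts; printed 3-decimal proportions sum to 0.999 |
| BMI | mean 29.05, SD 5.99 kg/m² | normal, clipped to a plausible range |
| T-score | pooled mean −0.96, SD 1.12 | linear age trend + normal residual |
| T-score age slope | −0.045 / year, centered at 63 | see below |
| flag prevalences | 3.6 / 21.7 / 16.8 / 4.6 / 9.4 / 6.9 % | drawn independently |

Two calibration details matter:

- **Truncation-aware age moments.** A normal law with mean 63 and SD 8
  truncated to [50, 79] no longer has mean 63 or SD 8. The generator
  solves for the parent-normal parameters whose *truncated* moments equal
  the requested ones (≈ N(55.3, 19.9) for the defaults; the resulting
  median ≈ 62 matches the reported sample median). Spec moments are thus
  the observed moments of the generated cohort, which is what downstream
  stratum sizes and risk gradients depend on.
- **Pooled T-score moments are exact in expectation.** The mean T-score at
  age `a` is `−0.96 − 0.045·(a − 63)` (after re-centering for the achieved
  mean age); the residual SD is shrunk so that slope²·Var(age) + residual
  variance equals 1.12² (including the 1/12 variance of integer rounding).
  The slope itself follows the well-documented postmenopausal femoral-neck
  decline of roughly half a T-score per decade and gives the oldest
  stratum the low BMD the published stratum medians require.

The generator draws the six clinical risk factors independently, because
only marginal prevalences are published; a `flag_sampler` hook accepts a
user-supplied joint sampler. The synthetic cohort reproduces marginals and
the BMD–age gradient; it does **not** reproduce real-data features such as
risk-factor clustering, race-specific BMD distributions, survey weighting,
or heavy BMD tails. Passing tests therefore demonstrate fidelity of the
pipeline's mechanics and of population-level medians, not individual-level
realism. Weight, needed only by interfaces that take weight rather than
BMI, derives from BMI at a fixed 1.60 m height.

## Surrogate risk engine

US FRAX coefficients are proprietary, so 10-year probabilities come from a
documented surrogate with the same architecture. For each outcome (hip,
major osteoporotic fracture) the fracture hazard at age `u` is

```
lam(u) = a·exp(b·u) · G^(−T) · Π RR_flag · RR_race · RR_bmi^(BMI − 25)
```

— a Gompertz baseline, a gradient of risk `G` per SD decrease in
femoral-neck BMD (`T` the T-score), multiplicative clinical risk factors,
race multipliers (white = 1), and a residual BMI term. The 10-year
probability of *first* fracture with competing death is

```
P = ∫₀¹⁰ lam(age+u) · exp(−∫₀ᵘ [lam + mu] dv) du ,
```

with `mu` a female all-cause Gompertz mortality hazard
(`2.0e−5·exp(0.098·age)` per year). The integral is evaluated by
fixed-step midpoint quadrature (default step 0.01 y, O(step²) accurate;
halving the step moves risks by far less than 0.01 percentage points).
Default multipliers are literature-typical (hip gradient 2.4, MOF 1.45;
prior fracture 1.8; parental history 2.3 hip / 1.5 MOF; smoking 1.3;
glucocorticoids 1.6; rheumatoid arthritis 1.4; alcohol 1.4; race black
0.45, hispanic 0.55; BMI 0.97 hip / 0.99 MOF per unit). Hip and MOF are
calibrated independently; no hip-within-MOF consistency is imposed, since
the two outcomes are anchored to separate published columns.

### Calibration

`calibrate` adjusts `(log a, b)` per outcome (optionally also `log G`
within literature bounds) by least squares in log-median space so the
cohort's untreated stratum medians approach the published anchors (hip
0.18 / 0.49 / 2.14 %, MOF 4.70 / 6.97 / 10.68 % for ages 50–59 / 60–69 /
70–79), then re-solves the level `a` exactly (Brent root find) so the
**oldest stratum matches its target to numerical precision**. The oldest
stratum is the anchor because absolute harms, threshold crossings, and NNH
all concentrate there.

A structural limitation is documented rather than hidden: with a Gompertz
baseline and a linear BMD–age trend, the model's log stratum medians are
nearly linear in age, while the published hip medians are super-exponential
(decade ratios ≈ 2.7 then ≈ 4.4). No (a, b, G) choice can reproduce all
three hip medians simultaneously — `b` and `log G` are almost collinear
across strata — so after anchoring the oldest stratum the younger hip
strata retain residuals on the order of tens of percent of their small
absolute values (MOF, being nearly log-linear, calibrates to ~1%).
`calibrate` records the residuals for all six targets in its result and
the CLI logs them per stratum.

## Bridging outputs

- **Paired risks**: untreated risk from observed BMD, treated risk from
  the shifted BMD, all other inputs identical; deltas are exact
  differences. With any BMD-lowering scenario and the monotone engine,
  deltas are non-negative and the treated threshold set contains the
  untreated one by construction.
- **Strata and bands**: age strata 50–59 / 60–69 / 70–79; BMD percentile
  bands cut on untreated BMD *within* each age stratum (keeping bands
  age-comparable; the alternative whole-cohort convention would mix age
  and BMD effects), `<p25` strict, `[p25, p75]` closed, `>p75` strict,
  linear percentile interpolation. Medians use the standard midpoint
  convention. Empty strata yield `n = 0` rows with null statistics.
- **Treatment thresholds**: 10-year hip risk ≥ 3% or MOF risk ≥ 20%,
  both boundaries inclusive.
- **NNH**: reciprocal of the *unrounded* mean risk difference on the
  proportion scale, reported raw and rounded to the nearest integer
  (rounding the difference first would corrupt the reciprocal); a
  non-positive difference is reported as "not defined (no harm)".
- **Sensitivity analyses**: (i) 50/50 random assignment to the two
  regimens, with a dedicated assignment seed separate from the cohort
  seed; (ii) rheumatoid arthritis forced absent, which under the
  multiplicative hazard lowers absolute risks while leaving
  treated-untreated contrasts nearly unchanged.
- **Age at threshold**: smallest age on a 0.1-year grid (50–90) at which
  a reference woman — white, cohort-median BMI 28.49, no risk factors,
  fixed BMD — reaches the 3% hip threshold; monotone in BMD.

## Problem sizes and randomness

The base-case cohort is n = 2303 with three ~600–860-subject strata; trial
simulations use 764 subjects × 7 visits, matching the scale of the
generating study. Every stochastic step takes an explicit integer seed
(cohort seed, trial seed, mixed-dosing assignment seed) through
`numpy.random.default_rng`; identical seeds give byte-identical outputs,
which the CLI manifest records alongside input hashes.

## Known limitations

- The surrogate is calibrated, not FRAX: absolute risks away from the
  anchored medians (especially younger-stratum hip risks, means, and tail
  quantities such as NNH and threshold counts) carry the structural error
  described above and should be read as order-of-magnitude companions to
  the published values, not replications.
- Risk factors are independent in the generator; real clustering would
  mostly widen the risk distribution's tails.
- The trajectory model is population-level and linear; it is not an
  individual prediction tool, and durations beyond the trial experience
  (12 months treatment, ~6 months recovery) extrapolate linearly.
- No survey weights, no trabecular bone score, no antiresorptive
  treatment effects, women 50–79 only.
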
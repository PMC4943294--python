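# Methods

## Blood-loss estimation chain

The estimator converts a pre-to-post hematocrit shift into a
whole-blood-equivalent loss. Body surface area follows the power-law
`0.0235·H^0.42246·W^0.51456` (height in cm, weight in kg); estimated
blood volume (EBV) is BSA times a sex-specific factor, 2430 mL/m² for
women and 2530 mL/m² for men. Red-cell volume at each draw is
`EBV × Hct`; the difference between the pre-operative and 72-hour
post-operative draws is the *uncompensated* red-cell loss, transfused
red cells are the *compensated* loss, and their sum divided by the mean
of the two hematocrits is total blood loss (TBL). The 72-hour endpoint
deliberately lets intravenous hydration and retroperitoneal fluid
re-equilibrate; the 12/24/36-hour draws are carried for trajectory QC
but never enter TBL.

Assumptions worth stating explicitly:

* EBV is constant over the window — the model accounts for hemodilution
  through the mean-hematocrit denominator, not through volume dynamics;
* hematocrits are stored as fractions in (0, 1). The chain is only
  dimensionally consistent on that scale once transfused volumes (mL)
  enter the numerator; CSV I/O accepts the clinical percent convention
  and converts at the boundary;
* the transfused red-cell volume is product volume × `product_hct`.
  The default `product_hct = 1.0` treats recorded product volumes as
  red-cell volume outright, which matches the operational definition of
  compensated loss used in hematocrit-balance audits of whole-blood
  transfusion; lowering it (e.g. to ≈ 0.6) gives packed-cell
  accounting;
* a hematocrit *rise* yields a negative uncompensated loss, which is
  propagated, not clamped. Reports show the raw value; only the
  adequacy classifier (below) floors it at zero.

A patient missing the endpoint draw is excluded from estimation
(complete-case design), never imputed, and listed in the exclusion log.

## Transfusion audit

The cross-match-to-transfusion (CT) ratio pools cross-matched volume
over *all* patients — including those never transfused, which is the
point of the metric — against total transfused volume; it is undefined
for an all-untransfused cohort and reported as such. Adequacy compares
each patient's transfused volume with their estimated TBL: deviation
beyond ±15% of TBL (configurable) is under-/over-transfusion. The
threshold is read as a symmetric band; a literal "deficit less than
15%" rule would label a perfectly matched transfusion inadequate. For a
patient whose estimated loss is zero or negative, no transfusion is
adequate and any transfusion is over-transfusion. Adequacy counts are
reported both over transfused patients and over the whole cohort — on
the whole-cohort reading, untransfused patients with substantial
estimated loss appear as under-transfused, which is informative about
triggers rather than an error.

## Predictive modelling

Candidates are screened one at a time against TBL with Pearson
(approximately normal variables: baseline hematocrit, age) or Spearman
(skewed ones: stone burden, counts, chemistries) correlation; p < 0.25
admits a candidate to a forward-stepwise OLS with entry α = 0.05 and
removal α = 0.10. The liberal screen is deliberate — bivariate
filtering at conventional α discards jointly informative predictors —
while the stepwise thresholds are ordinary epidemiological practice.
Both are configurable; p-values are two-sided and uncorrected. A rank-
deficient candidate design is rejected up front with the offending
variables named.

The fixed published predictor
`TBL = −153.379 + 0.229·stone_burden + 0.203·baseline_hct` takes stone
burden in mm² and hematocrit in *percent*. Because the estimation chain
works in fractions, `predict_published` rejects a hematocrit in (0, 1)
as a probable unit mistake rather than silently predicting nonsense;
exactly 0 is accepted as out-of-domain extrapolation (the intercept).
Full precision is returned and rounding to 2 decimals happens at
reporting.

## Synthetic cohort generator

The generator emulates the marginal structure of an 85-patient adult
PCNL cohort: 46 men / 39 women; age 50.96 ± 11.87 y truncated at 18;
sex-stratified heights and weights (165 ± 6.5 / 154 ± 6 cm, 65 ± 10 /
58 ± 9 kg — plausible adult Southeast-Asian values that influence
nothing downstream except through BSA); log-normal stone burden with
median 900 mm²; 50.6% staghorn; cross-matched volumes 435.29 ± 114.13
mL; transfused volumes 356.00 ± 145.88 mL split intra-only : post-only
: both at 3 : 6 : 2.

Each patient's *true* TBL is built from the published slopes (0.229
mL/mm², 0.203 mL per hematocrit percentage point) plus Gaussian noise
(sd 400 mL by default), and the 72-hour hematocrit is then obtained by
exactly inverting the estimation chain:

```
hf = (EBV·h0 + T − TBL·h0/2) / (TBL/2 + EBV)
```

so with zero noise and no transfusion the generator and the estimator
are exact inverses — the basis of the chain-inversion test.

Two calibrations reconcile the published affine part with the cohort's
aggregate behaviour:

* **Intercept offset.** The published slopes with their own intercept
  imply a mean loss near 90 mL, which is inconsistent with a ~5-point
  mean hematocrit drop at ~4 L blood volume (≈ 550 mL). The generator
  therefore treats the slopes as the covariate-effect truth and shifts
  the intercept once per cohort — before any noise is drawn — so the
  *expected* observed drop equals the configured target of 5.20
  percentage points. The expectation over the noise is computed with
  41-node Gauss–Hermite quadrature (including the transfusion-recovery
  term below) and the offset solved by bisection.
* **Baseline hematocrit.** Transfusion is triggered when the
  untransfused 72-h hematocrit would fall below 30%, reflecting common
  hematocrit-based transfusion policy; this is a simulation assumption.
  With the drop calibrated to 5.20 points, a baseline of 40 ± 4% would
  push roughly a third of patients below that trigger; the default
  baseline is therefore 42.0 ± 4% (clinically plausible for a
  54%-male adult cohort), under which the transfusion incidence
  emerges at ≈ 12%, the drop target and the 30% trigger both intact.

Transfused patients' final hematocrits are recomputed with the
transfused red-cell volume in the inversion, so transfusion visibly
blunts their observed drop, as in real data. Intermediate 12/24/36-h
hematocrits are linear interpolations with small jitter (sd 0.4
points), for QC only.

What the generator does **not** emulate: joint structure between
covariates (independence by default — no joint moments are available
to target), measurement error in the hematocrits entering TBL, surgeon
or access-tract effects, and any relation between stone type and blood
loss beyond stone burden itself. Tests passing on synthetic cohorts
therefore validate the pipeline's arithmetic, inference and plumbing —
not the clinical transportability of the predictor.

`generate_regression_fixture` is the stripped-down counterpart for
inference studies: covariates from the same marginals, TBL exactly
affine plus noise, with the generating truth returned alongside. OLS on
such fixtures (n = 85, noise sd 400 mL) recovers the stone-burden slope
with |mean bias| well under 0.01 mL/mm² and 95% CI coverage compatible
with nominal over 500 independent replicate streams
(`SeedSequence.spawn`).

## Numerical choices and degenerate inputs

* Truncated normals are drawn by resampling (deterministic under the
  seeded generator), not clipping, so moments are not distorted at the
  bounds; the final hematocrit alone is clipped to [0.08, 0.92] as a
  guard against extreme noise draws.
* Determinism contract: identical (seed, config) → identical cohort,
  via `numpy.random.default_rng` throughout.
* CSV round-trips preserve numerics to better than 1e-9 (pandas default
  float repr).
* Constant screening variables raise a named undefined-correlation
  error; zero transfused volume makes the CT ratio undefined rather
  than infinite; adequacy at exactly the threshold counts as adequate.
* Simulation sizes in the test suite (500 replicates for
  coverage/bias, 200 seeds for the drop calibration check, 60 for
  screening power) are chosen so each Monte-Carlo check resolves its
  tolerance band with ~3σ margin at single-CPU-seconds cost.

## Known limitations

The chain attributes every red-cell-mass change to surgical loss;
phlebotomy, hemolysis and ongoing occult bleeding after 72 h are
invisible to it. The published predictor's inference (its p-values,
R²) is not reproducible from summary data and is not claimed by this
package; the shipped coefficients are used for prediction only. The
stepwise procedure inherits the usual caveats of data-driven selection
(optimistic R², post-selection p-values); the screening-then-stepwise
workflow is provided for fidelity to clinical practice, not as a
recommendation.
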
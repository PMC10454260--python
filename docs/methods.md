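# Methods

## Measurement model

The CNC scale's items are ordinal: three response categories per item,
rescored so 0 < 1 < 2 orders increasing neurobehavioral function. The
package models them with the Andrich rating-scale model (RSM), a polytomous
Rasch model in which all items share one set of category thresholds:

    P(X_ni = k) = exp( Σ_{j≤k} (θ_n − δ_i − τ_j) ) / γ_ni,   k = 0..m

with person ability θ_n, item difficulty δ_i, thresholds τ_1..τ_m (τ_0 ≡ 0
by convention, the sum over j ≤ 0 empty), and γ_ni the normalizing sum over
categories. The RSM (rather than a partial-credit model with item-specific
thresholds) is appropriate because every CNC item uses the same 3-point
rating structure. Identification: δ's centered at mean 0, τ's summing to
0; the person scale is left free (no further rescaling), so measures are
logits in an item-centered frame.

The model's assumptions — unidimensionality, local independence, equal
item discrimination — are taken as given for the CNC without pain items,
which prior psychometric work supports; the package does not test them
(no infit/outfit or DIF machinery, which the responsiveness computations
do not need).

## Estimation

Joint maximum likelihood (JMLE): PROX starting values (empirical logits of
person and item proportions), then alternating damped Newton–Raphson
sweeps over person abilities, item difficulties, and thresholds. Each
threshold τ_j is updated against its sufficient statistic, the count of
responses in category ≥ j. Updates are clipped to ±1 logit per sweep and
parameters to ±12 logits for numerical safety; convergence is declared
when the largest absolute update falls below `tol = 1e-4` logits, with a
cap of 200 iterations (non-convergence returns a flagged result and a
warning rather than an exception). Recentering of τ's is compensated in
the δ's, and recentering of δ's in the θ's, so sweeps never fight the
identification constraints.

Persons with extreme raw totals (0 or the maximum) carry no likelihood
information about items and are excluded from item estimation. Estimation
requires every category to be observed at least once overall; an unused
category makes the shared thresholds unidentifiable and raises a
structured error naming the category.

**Finite-length bias.** JMLE is inconsistent at fixed test length: with
L items the estimated spread of δ's and τ's is inflated by roughly
L/(L−1). We verified this in simulation (threshold RMSE ≈ 0.20 at n = 500
*and* ≈ 0.22 at n = 5000 — bias, not noise; ≤ 0.07 after correction). The
`JMLEConfig.bias_correction` flag applies the standard (L−1)/L shrinkage.
The default is off, matching the default behavior of the widely used
Rasch software this estimator mirrors; recovery experiments in the test
suite and acceptance script turn it on, since their question is closeness
to generating values.

## Person measurement and conversion tables

In a Rasch model the raw total is sufficient for θ, so every person with
the same set of answered items and the same total gets the same measure:
the solution of `expected_score(θ) = raw` (test characteristic curve
inversion, Newton–Raphson with a logit-scale start). The standard error is
`1/√(test information)` at the solution. Extreme totals would solve at
±∞; they are pulled inward by `extreme_adjust = 0.3` score points
(configurable) before inversion, yielding finite extrapolated measures.
The exact adjustment used for the published conversion table is not
recoverable from the table alone, so endpoint equality with it is not
asserted anywhere; the published table ships as a packaged fixture, and
`conversion_table()` regenerates the same *structure* (m·L + 1 rows,
strictly monotone measures, original-scale mapping
`original = 2·(m·L − rescored)`) from any fitted parameters.

Both timepoints are calibrated in one stacked run (one row per
person-timepoint) so baseline and follow-up measures share a single frame;
an anchored two-step calibration would be the alternative, but with the
same items and a two-week interval a common calibration is the simpler
defensible default.

Wright's person separation reliability is
`R = (Var_obs − mean(SE²))/Var_obs`, floored at 0, over non-extreme
persons by default (extrapolated extreme measures would distort both
terms); `include_extreme=True` is available.

## Responsiveness indices

With paired measures (complete pairs only, n ≥ 2):

* `SD_pooled = √((SD_bl² + SD_fu²)/2)` — the equal-n form, since the same
  cohort is measured twice.
* `SEM = SD_pooled·√(1 − r)`, with r the person separation reliability.
* `MDC95 = 1.96·√2·SEM`. The √2 carries the variance of a difference of
  two measurements; the published panel values are numerically consistent
  with this form and are regression-tested at 2 decimals.
* Distribution-based MCIDs `k·SD_pooled` for k = 0.20, 0.33, 0.50 —
  group-level benchmarks (small / minimally important / medium).
* Effect size `(mean_fu − mean_bl)/SD_pooled`; standardized response mean
  `mean(Δ)/SD(Δ)` with the n−1 SD (undefined at zero variance → error).
* Effect-size CI: normal approximation
  `es ± 1.96·√(1/n + es²/(2n))`. This is an approximation documented as
  such; published CI cells are not regression targets (the source panel's
  10-item CI cells are internally inconsistent, lower > upper).

Report rounding is half-away-from-zero to 2 decimals (so 0.625 prints as
0.63). Individual change is classified strictly: beyond +MDC95 improved,
beyond −MDC95 declined, ties within error — the conservative clinical
reading of "beyond measurement error".

Because `MDC95/MCID_050 = 1.96·√2·√(1−r)/0.5`, the MDC95 exceeds the
medium MCID exactly when r < 0.967; the property test asserts the ordering
under that condition.

## Synthetic cohorts

`generate_cohort` draws baseline abilities θ ~ Normal(−0.8, 1.25) logits
and an additive, baseline-independent latent shift Δ ~ Normal(0.35, 0.9)
at follow-up, then samples item responses independently from the RSM at
each timepoint. Defaults emulate the two-timepoint study cohort the
package targets: n = 40 persons, 8 items (10 optional), 3 categories,
cohort location/scale matching the published summaries. The true item
difficulty spread of the CNC is unpublished, so items default to an even
spread over ±1 logit (configurable, including explicit δ's); thresholds
default to (−1, 1). Missingness is completely at random at a configurable
rate, with a guard keeping at least one response per person and item.

What the generator does *not* emulate: diagnosis subgroups, rater effects,
item-specific thresholds, informative missingness, or correlation between
baseline ability and change (no data to support one). Passing recovery
tests therefore show the estimator and index pipeline are self-consistent
under the stated model, not that real CNC data satisfy that model.

**Detection benchmark caveat.** With 8 three-category items the model SE
per measure is ≈ 0.6–0.7 logits, so the observed `SD_pooled`
(≈ √(θ_sd² + Δ_sd²/2 + SE²) ≈ 1.65) exceeds the generating ability SD
(1.25). A true mean improvement of 0.5 ability-SD (0.625 logits) therefore
sits *between* the 0.33·SD and 0.50·SD benchmarks of the observed
distribution in expectation, and a comparison against MCID_050 is a
knife-edge rather than a property. The end-to-end recovery test
accordingly asserts that a 0.5-ability-SD change is detected as exceeding
the small and minimally-important benchmarks (0.20 and 0.33 SD) at
n = 1000, and that the pipeline's reliability matches the generating value
within ±0.05.

## Problem sizes and determinism

Recovery experiments use n = 500 for calibration (RMSE ≤ 0.15 logits on
δ's and τ's with bias correction), n = 1000–2000 for cohort-level means
and reliability — sizes at which sampling noise is comfortably inside the
asserted tolerances. All simulations take explicit seeds; property tests
are seeded or derandomized. `scripts/acceptance.py` derives every stream
from its `--seed` argument.

## Known limitations

* JMLE (even corrected) is not bit-compatible with any specific commercial
  implementation; published calibrations are fixtures, not targets.
* The effect-size CI is a large-sample approximation.
* Distribution-based MCIDs are sample-dependent by construction; they are
  benchmarks, not anchor-based thresholds of perceived importance.
* The stacked calibration assumes item difficulties are stable across the
  two-week interval.
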
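# cncrasch

Rasch measurement and responsiveness analysis for the **Coma/Near-Coma
(CNC) scale**, a bedside assessment of neurobehavioral function in people
with disorders of consciousness after severe brain injury. The package is
for clinicians and rehabilitation researchers who need to decide, from two
CNC assessments a couple of weeks apart, whether an individual patient has
truly changed — and for trialists who need group-level change benchmarks.

CNC items are rated on a 3-point ordinal scale (original codes 0/2/4, lower
= better; rescored here to 0/1/2 with higher = better). Ordinal totals are
not interval quantities, so the package first converts them to logit person
measures with the Andrich **rating-scale Rasch model**,

    P(X_ni = k) ∝ exp( Σ_{j≤k} (θ_n − δ_i − τ_j) ),   k = 0..m,  τ_0 ≡ 0,

where θ_n is person ability, δ_i item difficulty (centered at 0), and
τ_1..τ_m category thresholds shared across items (summing to 0). Parameters
are estimated by joint maximum likelihood (PROX start, alternating
Newton–Raphson); person measures invert the test characteristic curve at
the raw total, with extreme totals pulled inward by 0.3 score points so
their measures stay finite.

On the logit measures it computes the standard responsiveness panel:

* Wright's person separation reliability `r = (Var_obs − mean(SE²)) / Var_obs`
* `SD_pooled = √((SD_bl² + SD_fu²)/2)`
* standard error of measurement `SEM = SD_pooled·√(1 − r)`
* minimal detectable change `MDC95 = 1.96·√2·SEM`
* distribution-based MCIDs at 0.20 / 0.33 / 0.50 SD
* effect size `(mean_fu − mean_bl)/SD_pooled` and the standardized response
  mean `mean(Δ)/SD(Δ)`

and classifies each person's change against the MDC95 (`improved`,
`declined`, or `within_error`; a tie stays within error). A synthetic-data
module simulates two-timepoint CNC-like cohorts from the same model for
validation, and packaged reference tables carry the published 8- and
10-item score-to-measure conversions and index panels.

## Worked example

```bash
python examples/04_worked_clinical_example.py
```

```
raw score 28 (8-item scale) -> measure -1.86 logits
ability range (measure +/- SEM): -2.31 to -1.41 logits
true improvement requires a measure of -0.61 logits or greater
```

A patient scoring 28 (original scale) on the 8-item CNC measures −1.86
logits; given the SEM of 0.45 their ability plausibly lies between −2.31
and −1.41, and only on reaching −0.61 logits (raw score 20 or lower) has
the patient improved beyond measurement error.

The other examples show the index panel, model calibration, and the full
pipeline:

```bash
python examples/01_responsiveness_panel.py   # SEM/MDC95/MCID panel per version
python examples/02_fit_rasch_model.py        # JMLE calibration + conversion table
python examples/03_classify_change.py        # simulate -> fit -> classify, n=40
```

For instance the 8-item panel prints `SEM = 0.45`, `MDC95 = 1.25` and
MCIDs `0.25 / 0.41 / 0.63` logits: a group mean change above 0.25 logits
clears the small benchmark, while an individual needs more than 1.25 logits
to clear measurement error.

The same steps are available from the shell:

```bash
cncrasch simulate /tmp/cohort --seed 9 --n-persons 40
cncrasch fit /tmp/cohort.csv --params-out /tmp/params.json --measures-out /tmp/measures.csv
cncrasch convert /tmp/params.json --out /tmp/conversion.csv
cncrasch responsiveness --summary-version 8item
cncrasch example
```

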
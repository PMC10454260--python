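"""Bedside interpretation of one CNC assessment.

Looks up the published measure for an original-scale raw score of 28 on
the 8-item version, brackets it with the SEM, and computes the measure the
patient must reach for improvement beyond measurement error.
"""

from cncrasch import measure_band, true_change_threshold
from cncrasch.io import load_conversion_fixture, lookup_measure

SEM_8ITEM = 0.45   # logits, 8-item version
MDC95_8ITEM = 1.25

table = load_conversion_fixture()
measure = lookup_measure(table, 28, version=8)
lo, hi = measure_band(measure, SEM_8ITEM)
target = true_change_threshold(measure, MDC95_8ITEM, "improvement")

print(f"raw score 28 (8-item scale) -> measure {measure:.2f} logits")
print(f"ability range (measure +/- SEM): {lo:.2f} to {hi:.2f} logits")
print(f"true improvement requires a measure of {target:.2f} logits or greater")
print(
    "\nThe band shows where the patient's ability plausibly lies; crossing "
    "the threshold marks recovery beyond what measurement error explains."
)
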
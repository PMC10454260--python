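"""End-to-end convenience: calibrate, measure, pair, and summarize.

The default analysis stacks both timepoints into a single calibration
(one row per person-timepoint) so baseline and follow-up measures share one
measurement frame, then pairs the per-timepoint measures for the
responsiveness panel.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import TIMEPOINTS, stack_timepoints
from .model import (
    JMLEConfig,
    PersonMeasure,
    ResponseMatrix,
    RSMParams,
    fit_jmle,
    wright_psr,
)
from .responsiveness import (
    ChangeSummary,
    PairedMeasures,
    ResponsivenessIndices,
    compute_indices,
    summarize_change,
)

__all__ = ["CohortAnalysis", "analyze_cohort", "pair_measures"]


@dataclass
class CohortAnalysis:
    """Everything the pipeline computes for one two-timepoint cohort."""

    params: RSMParams
    measures: dict[str, list[PersonMeasure]]
    paired: PairedMeasures
    reliability: float
    indices: ResponsivenessIndices
    changes: ChangeSummary


def pair_measures(
    measures: dict[str, list[PersonMeasure]],
    timepoints: tuple[str, str] = TIMEPOINTS,
) -> PairedMeasures:
    """Pair per-timepoint measures by person id (complete pairs only)."""
    t1, t2 = timepoints
    bl = {pm.person_id: pm.measure for pm in measures[t1]}
    fu = {pm.person_id: pm.measure for pm in measures[t2]}
    ids = [pid for pid in bl if pid in fu]
    return PairedMeasures(
        person_ids=ids,
        baseline=[bl[pid] for pid in ids],
        followup=[fu[pid] for pid in ids],
    )


def analyze_cohort(
    matrices: dict[str, ResponseMatrix],
    config: JMLEConfig | None = None,
    timepoints: tuple[str, str] = TIMEPOINTS,
) -> CohortAnalysis:
    """Stacked calibration, person measurement, and the responsiveness panel."""
    stacked, keys = stack_timepoints(
        {tp: matrices[tp] for tp in timepoints}
    )
    params, stacked_measures = fit_jmle(stacked, config)
    per_tp: dict[str, list[PersonMeasure]] = {tp: [] for tp in timepoints}
    for (pid, tp), pm in zip(keys, stacked_measures):
        pm.person_id = pid
        pm.timepoint = tp
        per_tp[tp].append(pm)
    paired = pair_measures(per_tp, timepoints)
    r = wright_psr(stacked_measures)
    indices = compute_indices(paired, r)
    changes = summarize_change(paired, indices.mdc95)
    return CohortAnalysis(
        params=params,
        measures=per_tp,
        paired=paired,
        reliability=r,
        indices=indices,
        changes=changes,
    )
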
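"""File formats and packaged reference tables.

Assessment files are UTF-8 CSV with header ``person_id,timepoint,
item_1..item_L``.  Cells hold either original CNC codes {0, 2, 4} or
rescored scores {0, 1, 2} depending on the declared scoring convention;
empty cells are missing responses.  Readers always return rescored
matrices (higher = better function).

The packaged reference tables transcribe the published CNC score-to-measure
conversion (8-item and 10-item), the responsiveness summary panel, and the
MDC/MCID panel; they serve as fixtures and as inputs to the worked-example
command.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError, InvalidArgumentError
from .model import ConversionTable, PersonMeasure, ResponseMatrix, RSMParams
from .responsiveness import PairedMeasures
from .simulate import CohortSample, rescore_cnc

__all__ = [
    "read_assessments",
    "write_assessments",
    "write_cohort",
    "read_paired_measures",
    "write_measures",
    "write_params",
    "read_params",
    "write_conversion_table",
    "load_conversion_fixture",
    "load_responsiveness_fixture",
    "load_mdc_mcid_fixture",
    "lookup_measure",
    "stack_timepoints",
]

logger = logging.getLogger(__name__)

TIMEPOINTS = ("baseline", "followup")


# ---------------------------------------------------------------------------
# assessment files
# ---------------------------------------------------------------------------


def read_assessments(
    path,
    scoring: str = "rescored",
    timepoints: tuple[str, str] = TIMEPOINTS,
) -> dict[str, ResponseMatrix]:
    """Read an assessment CSV into one rescored ResponseMatrix per timepoint.

    ``scoring='original'`` declares 0/2/4 codes, which are rescored on read;
    ``scoring='rescored'`` declares 0/1/2 scores used as-is.
    """
    if scoring not in ("original", "rescored"):
        raise InvalidArgumentError(
            f"scoring must be 'original' or 'rescored', got {scoring!r}"
        )
    df = pd.read_csv(path, dtype={"person_id": str, "timepoint": str})
    required = ["person_id", "timepoint"]
    if list(df.columns[:2]) != required:
        raise DataValidationError(
            f"{path}: header must start with {required}, "
            f"got {list(df.columns[:2])}"
        )
    item_cols = list(df.columns[2:])
    if not item_cols:
        raise DataValidationError(f"{path}: no item columns found")

    bad_tp = sorted(set(df["timepoint"]) - set(timepoints))
    if bad_tp:
        raise DataValidationError(
            f"{path}: unknown timepoint labels {bad_tp}; "
            f"expected {list(timepoints)}"
        )
    dup = df.duplicated(subset=["person_id", "timepoint"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        line = int(df[dup].index[0]) + 2  # header is line 1
        raise DataValidationError(
            f"{path}: duplicate (person, timepoint) "
            f"({row['person_id']!r}, {row['timepoint']!r}) at line {line}"
        )

    out: dict[str, ResponseMatrix] = {}
    for tp in timepoints:
        sub = df[df["timepoint"] == tp]
        if sub.empty:
            continue
        scores = sub[item_cols].to_numpy(dtype=float)
        if scoring == "original":
            try:
                scores = rescore_cnc(scores)
            except InvalidArgumentError as exc:
                raise DataValidationError(
                    f"{path}, timepoint {tp!r}: {exc}"
                ) from exc
        else:
            obs = scores[~np.isnan(scores)]
            if obs.size and (obs.min() < 0 or obs.max() > 2
                             or (obs != np.round(obs)).any()):
                raise DataValidationError(
                    f"{path}, timepoint {tp!r}: rescored values must be "
                    f"integers in [0, 2]"
                )
        out[tp] = ResponseMatrix(
            person_ids=list(sub["person_id"]),
            item_ids=item_cols,
            scores=scores,
        )
        logger.info(
            "read %d persons x %d items at timepoint %r from %s",
            out[tp].n_persons, out[tp].n_items, tp, path,
        )
    if not out:
        raise DataValidationError(f"{path}: no rows for any known timepoint")
    return out


def write_assessments(
    path, matrices: dict[str, ResponseMatrix]
) -> None:
    """Write rescored matrices per timepoint to the assessment CSV format."""
    frames = []
    for tp, mat in matrices.items():
        frame = pd.DataFrame(mat.scores, columns=mat.item_ids)
        frame.insert(0, "timepoint", tp)
        frame.insert(0, "person_id", mat.person_ids)
        frames.append(frame)
    df = pd.concat(frames, ignore_index=True)
    item_cols = df.columns[2:]
    df[item_cols] = df[item_cols].astype("Int64")  # empty cell for missing
    df.to_csv(path, index=False)


def write_cohort(prefix, cohort: CohortSample) -> dict[str, Path]:
    """Write a simulated cohort: assessment CSV plus a truth sidecar CSV."""
    prefix = Path(prefix)
    paths = {
        "assessments": prefix.with_suffix(".csv"),
        "truth": prefix.parent / (prefix.name + "_truth.csv"),
    }
    write_assessments(
        paths["assessments"],
        {"baseline": cohort.baseline, "followup": cohort.followup},
    )
    pd.DataFrame(
        {
            "person_id": cohort.baseline.person_ids,
            "true_theta": cohort.true_theta,
            "true_change": cohort.true_change,
        }
    ).to_csv(paths["truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# measures and parameters
# ---------------------------------------------------------------------------


def write_measures(path, measures: list[PersonMeasure]) -> None:
    pd.DataFrame(
        [
            {
                "person_id": pm.person_id,
                "timepoint": pm.timepoint,
                "raw_score": pm.raw_score,
                "max_score": pm.max_score,
                "measure": pm.measure,
                "se": pm.se,
                "extreme": pm.extreme,
            }
            for pm in measures
        ]
    ).to_csv(path, index=False)


def read_paired_measures(path) -> PairedMeasures:
    """Read a paired-measures CSV (person_id, baseline, followup)."""
    df = pd.read_csv(path, dtype={"person_id": str})
    for col in ("person_id", "baseline", "followup"):
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    df = df.dropna(subset=["baseline", "followup"])
    return PairedMeasures(
        person_ids=list(df["person_id"]),
        baseline=df["baseline"].to_numpy(),
        followup=df["followup"].to_numpy(),
    )


def write_params(path, params: RSMParams, item_ids=None) -> None:
    payload = {
        "deltas": params.deltas.tolist(),
        "taus": params.taus.tolist(),
        "n_categories": params.n_categories,
        "item_ids": list(item_ids) if item_ids is not None else None,
        "fit_meta": {
            "iterations": int(params.fit_meta.iterations),
            "max_update": float(params.fit_meta.max_update),
            "converged": bool(params.fit_meta.converged),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params(path) -> RSMParams:
    payload = json.loads(Path(path).read_text())
    return RSMParams(
        deltas=np.asarray(payload["deltas"], dtype=float),
        taus=np.asarray(payload["taus"], dtype=float),
        n_categories=int(payload["n_categories"]),
    )


def write_conversion_table(path, table: ConversionTable) -> None:
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("cncrasch.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_conversion_fixture() -> pd.DataFrame:
    """Published score-to-measure conversion for the 8- and 10-item CNC."""
    return _fixture("table1_conversion.csv")


def load_responsiveness_fixture() -> pd.DataFrame:
    """Published cohort summary panel (means, SDs, pooled SD, reliability)."""
    return _fixture("table2_responsiveness.csv")


def load_mdc_mcid_fixture() -> pd.DataFrame:
    """Published MDC95 and distribution-based MCID panel."""
    return _fixture("table3_mdc_mcid.csv")


def lookup_measure(
    table: pd.DataFrame, original_total: int, version: int
) -> float:
    """Look up the published person measure for an original-scale total."""
    if version not in (8, 10):
        raise InvalidArgumentError("version must be 8 or 10")
    col = f"measure_{version}item"
    sub = table.dropna(subset=[col])
    row = sub[sub["original_total"] == original_total]
    if row.empty:
        valid = sorted(int(t) for t in sub["original_total"])
        raise InvalidArgumentError(
            f"total {original_total} not in the {version}-item table; "
            f"valid totals: {valid}"
        )
    return float(row[col].iloc[0])


# ---------------------------------------------------------------------------
# timepoint stacking
# ---------------------------------------------------------------------------


def stack_timepoints(
    matrices: dict[str, ResponseMatrix]
) -> tuple[ResponseMatrix, list[tuple[str, str]]]:
    """Stack per-timepoint matrices into one calibration matrix.

    Each person-timepoint becomes one row; returns the stacked matrix and
    the (person_id, timepoint) key for each row.
    """
    first = next(iter(matrices.values()))
    keys: list[tuple[str, str]] = []
    blocks = []
    for tp, mat in matrices.items():
        if mat.item_ids != first.item_ids:
            raise DataValidationError(
                "timepoints disagree on item columns"
            )
        keys.extend((pid, tp) for pid in mat.person_ids)
        blocks.append(mat.scores)
    stacked = ResponseMatrix(
        person_ids=[f"{pid}@{tp}" for pid, tp in keys],
        item_ids=first.item_ids,
        scores=np.vstack(blocks),
        n_categories=first.n_categories,
    )
    return stacked, keys
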
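"""Synthetic two-timepoint cohorts drawn from the rating-scale Rasch model.

The study cohort this generator emulates is ~40 adults with severe brain
injury assessed twice, about two weeks apart, on 8 or 10 three-category
items.  Baseline abilities are Normal(theta_mean, theta_sd) on the logit
scale (defaults -0.8 and 1.25, matching the published cohort summaries);
follow-up ability adds an independent Normal(change_mean, change_sd) latent
shift (defaults 0.35 and 0.9).  Responses at each timepoint are drawn
independently from the rating-scale model given the person's ability, the
item difficulties and the shared thresholds; the generating truth is
returned alongside the data so recovery experiments can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError
from .model import ResponseMatrix, _prob_grid

__all__ = [
    "SimulationConfig",
    "CohortSample",
    "generate_cohort",
    "rescore_cnc",
    "original_total",
]

CNC_ORIGINAL_CODES = (0, 2, 4)
# original 0/2/4 codes (lower = better) -> rescored 0/1/2 (higher = better)
RESCORE_MAP = {0: 2, 2: 1, 4: 0}


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic two-timepoint cohort."""

    n_persons: int = 40
    n_items: int = 8
    n_categories: int = 3
    theta_mean: float = -0.8   # baseline ability, logits
    theta_sd: float = 1.25
    change_mean: float = 0.35  # latent improvement at follow-up, logits
    change_sd: float = 0.9
    deltas: np.ndarray | None = None
    delta_spread: float = 2.0  # even spacing width when deltas not given
    taus: tuple = (-1.0, 1.0)
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_persons < 2 or self.n_items < 2:
            raise InvalidArgumentError("need >= 2 persons and >= 2 items")
        if self.theta_sd <= 0 or self.change_sd < 0:
            raise InvalidArgumentError(
                "theta_sd must be > 0 and change_sd >= 0"
            )
        if not 0 <= self.missing_rate < 1:
            raise InvalidArgumentError("missing_rate must be in [0, 1)")
        taus = np.asarray(self.taus, dtype=float)
        if len(taus) != self.n_categories - 1:
            raise InvalidArgumentError(
                f"expected {self.n_categories - 1} thresholds"
            )
        if abs(taus.sum()) > 1e-8:
            raise InvalidArgumentError("thresholds must sum to zero")
        if self.deltas is not None:
            d = np.asarray(self.deltas, dtype=float)
            if len(d) != self.n_items:
                raise InvalidArgumentError("deltas length must equal n_items")
            if abs(d.mean()) > 1e-8:
                raise InvalidArgumentError("deltas must have mean zero")

    def resolved_deltas(self) -> np.ndarray:
        if self.deltas is not None:
            return np.asarray(self.deltas, dtype=float)
        d = np.linspace(-self.delta_spread / 2, self.delta_spread / 2,
                        self.n_items)
        return d - d.mean()


@dataclass
class CohortSample:
    """A simulated cohort with its generating truth."""

    baseline: ResponseMatrix
    followup: ResponseMatrix
    true_theta: np.ndarray       # baseline abilities
    true_change: np.ndarray      # latent follow-up shifts
    deltas: np.ndarray
    taus: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)


def _draw_matrix(
    rng: np.random.Generator,
    thetas: np.ndarray,
    deltas: np.ndarray,
    taus: np.ndarray,
    n_categories: int,
    missing_rate: float,
    person_ids: list,
    item_ids: list,
) -> ResponseMatrix:
    probs = _prob_grid(thetas, deltas, taus)
    u = rng.random(probs.shape[:2])
    scores = (u[:, :, None] > np.cumsum(probs, axis=2)).sum(axis=2).astype(float)
    if missing_rate > 0:
        # keep one response per person and per item so the matrix validates
        miss = rng.random(scores.shape) < missing_rate
        for i in range(scores.shape[0]):
            if miss[i].all():
                miss[i, rng.integers(scores.shape[1])] = False
        for j in range(scores.shape[1]):
            if miss[:, j].all():
                miss[rng.integers(scores.shape[0]), j] = False
        scores = np.where(miss, np.nan, scores)
    return ResponseMatrix(
        person_ids=person_ids,
        item_ids=item_ids,
        scores=scores,
        n_categories=n_categories,
    )


def generate_cohort(config: SimulationConfig) -> CohortSample:
    """Draw a two-timepoint cohort from the rating-scale model.

    Reproducible for a fixed ``config.seed``; the same seed always yields
    identical matrices.
    """
    rng = np.random.default_rng(config.seed)
    deltas = config.resolved_deltas()
    taus = np.asarray(config.taus, dtype=float)
    theta = rng.normal(config.theta_mean, config.theta_sd, config.n_persons)
    change = (
        rng.normal(config.change_mean, config.change_sd, config.n_persons)
        if config.change_sd > 0
        else np.full(config.n_persons, config.change_mean)
    )
    person_ids = [f"p{i + 1:03d}" for i in range(config.n_persons)]
    item_ids = [f"item_{j + 1}" for j in range(config.n_items)]
    t1 = _draw_matrix(rng, theta, deltas, taus, config.n_categories,
                      config.missing_rate, person_ids, item_ids)
    t2 = _draw_matrix(rng, theta + change, deltas, taus, config.n_categories,
                      config.missing_rate, person_ids, item_ids)
    return CohortSample(
        baseline=t1, followup=t2, true_theta=theta, true_change=change,
        deltas=deltas, taus=taus, config=config,
    )


def rescore_cnc(original_codes) -> np.ndarray:
    """Rescore original CNC item codes 0/2/4 to 0/1/2 with reversed polarity.

    On the original scale a lower code means better function; after
    rescoring (0 -> 2, 2 -> 1, 4 -> 0) a higher score means better
    neurobehavioral function.  Missing values (NaN) pass through.
    """
    arr = np.asarray(original_codes, dtype=float)
    out = np.full(arr.shape, np.nan)
    valid = np.isnan(arr)
    for code, rescored in RESCORE_MAP.items():
        hit = arr == code
        out[hit] = rescored
        valid |= hit
    if not valid.all():
        bad = np.argwhere(~valid)[0]
        idx = tuple(int(b) for b in bad)
        raise InvalidArgumentError(
            f"invalid CNC code {arr[tuple(bad)]!r} at position {idx}; "
            f"expected one of {CNC_ORIGINAL_CODES}"
        )
    return out if out.ndim else out[()]


def original_total(rescored_total: int, n_items: int) -> int:
    """Map a rescored total back to the published 0/2/4 total score scale."""
    top = 2 * n_items
    if not 0 <= rescored_total <= top:
        raise InvalidArgumentError(
            f"rescored total {rescored_total} outside [0, {top}]"
        )
    return 2 * (top - rescored_total)
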
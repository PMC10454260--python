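"""Andrich rating-scale Rasch model: probabilities, JMLE, person measurement.

The rating-scale model (RSM) expresses the probability that person ``n``
responds in category ``k`` of item ``i`` (categories ``0..m``) as

    P(X_ni = k) = exp(sum_{j<=k} (theta_n - delta_i - tau_j)) / gamma_ni

where ``theta_n`` is the person ability, ``delta_i`` the item difficulty,
``tau_1..tau_m`` the category thresholds shared by all items (``tau_0 = 0``),
and ``gamma_ni`` normalizes over categories.  Abilities, difficulties and
thresholds all live on one logit scale; items are centered at zero and the
thresholds sum to zero for identification.

Estimation is joint maximum likelihood (JMLE): PROX starting values, then
alternating damped Newton-Raphson sweeps over persons, items and thresholds
until the largest parameter update falls below tolerance.  Persons with
extreme raw totals (0 or the maximum) carry no information about the items;
they are excluded from item estimation and afterwards measured by pulling
the extreme total inward by a configurable fraction of a score point before
inverting the test characteristic curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    EstimationError,
    InvalidArgumentError,
    UnobservedCategoryError,
)

__all__ = [
    "ResponseMatrix",
    "RSMParams",
    "PersonMeasure",
    "ConversionTable",
    "JMLEConfig",
    "category_probabilities",
    "expected_score",
    "fit_jmle",
    "person_measure_from_raw",
    "conversion_table",
    "wright_psr",
]

logger = logging.getLogger(__name__)

_THETA_BOUND = 12.0  # logit clamp keeping exponentials well-conditioned


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ResponseMatrix:
    """Persons x items ordinal category scores.

    ``scores`` is a float array of shape ``(n_persons, n_items)`` holding
    integer categories ``0..m`` with ``NaN`` for missing responses.
    """

    person_ids: list
    item_ids: list
    scores: np.ndarray
    n_categories: int = 3

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n, L = self.scores.shape if self.scores.ndim == 2 else (0, 0)
        if self.scores.ndim != 2:
            raise InvalidArgumentError("scores must be a 2-D array")
        if len(self.person_ids) != n or len(self.item_ids) != L:
            raise InvalidArgumentError(
                f"id lengths ({len(self.person_ids)}, {len(self.item_ids)}) "
                f"do not match scores shape {self.scores.shape}"
            )
        if n < 2 or L < 2:
            raise InvalidArgumentError("need at least 2 persons and 2 items")
        m = self.n_categories - 1
        observed = self.scores[~np.isnan(self.scores)]
        if observed.size and (
            (observed != np.round(observed)).any()
            or observed.min() < 0
            or observed.max() > m
        ):
            raise InvalidArgumentError(
                f"scores must be integers in [0, {m}] or missing"
            )
        answered = ~np.isnan(self.scores)
        if not answered.any(axis=1).all():
            raise InvalidArgumentError("every person needs >= 1 response")
        if not answered.any(axis=0).all():
            raise InvalidArgumentError("every item needs >= 1 response")

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def max_category(self) -> int:
        return self.n_categories - 1

    def raw_scores(self) -> np.ndarray:
        """Per-person total of non-missing responses."""
        return np.nansum(self.scores, axis=1)

    def max_scores(self) -> np.ndarray:
        """Per-person maximum achievable total (missing items excluded)."""
        answered = (~np.isnan(self.scores)).sum(axis=1)
        return self.max_category * answered


@dataclass
class FitMeta:
    iterations: int = 0
    max_update: float = float("inf")
    converged: bool = False


@dataclass
class RSMParams:
    """Fitted rating-scale model: item difficulties and shared thresholds."""

    deltas: np.ndarray
    taus: np.ndarray
    n_categories: int = 3
    fit_meta: FitMeta = field(default_factory=FitMeta)

    def __post_init__(self) -> None:
        self.deltas = np.asarray(self.deltas, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        if not (np.isfinite(self.deltas).all() and np.isfinite(self.taus).all()):
            raise InvalidArgumentError("parameters must be finite")
        if len(self.taus) != self.n_categories - 1:
            raise InvalidArgumentError(
                f"expected {self.n_categories - 1} thresholds, "
                f"got {len(self.taus)}"
            )
        if abs(self.deltas.mean()) > 1e-6:
            raise InvalidArgumentError("item difficulties must be centered")
        if abs(self.taus.sum()) > 1e-6:
            raise InvalidArgumentError("thresholds must sum to zero")

    @property
    def n_items(self) -> int:
        return len(self.deltas)


@dataclass
class PersonMeasure:
    """One person-timepoint: raw total, logit measure and its standard error."""

    person_id: object
    raw_score: float
    max_score: float
    measure: float
    se: float
    extreme: bool
    timepoint: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.raw_score <= self.max_score:
            raise InvalidArgumentError(
                f"raw score {self.raw_score} outside [0, {self.max_score}]"
            )
        if not (np.isfinite(self.measure) and self.se > 0):
            raise InvalidArgumentError("measure must be finite with se > 0")


@dataclass
class ConversionTable:
    """Score-to-measure table: one row per achievable rescored total.

    ``original_total`` maps the rescored total back onto the published
    0/2/4 scale (lower original score = better function), via
    ``original = 2 * (m*L - rescored)``.
    """

    rescored_total: np.ndarray
    original_total: np.ndarray
    measure: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        if not (np.diff(self.measure) > 0).all():
            raise InvalidArgumentError(
                "measures must strictly increase with rescored total"
            )

    def __len__(self) -> int:
        return len(self.rescored_total)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rescored_total": self.rescored_total,
                "original_total": self.original_total,
                "measure": self.measure,
                "se": self.se,
            }
        )


@dataclass
class JMLEConfig:
    """Estimation settings for :func:`fit_jmle`."""

    tol: float = 1e-4            # convergence: max |update| in logits
    max_iter: int = 200
    extreme_adjust: float = 0.3  # score points pulled inward for extremes
    bias_correction: bool = False  # (L-1)/L shrinkage of item estimates


# ---------------------------------------------------------------------------
# model kernel
# ---------------------------------------------------------------------------


def category_probabilities(
    theta: float, delta: float, taus: Sequence[float]
) -> np.ndarray:
    """Rating-scale category probabilities for one person-item encounter.

    Returns a vector of length ``m + 1``; component ``k`` is proportional to
    ``exp(sum_{j=1..k} (theta - delta - tau_j))`` with the empty sum for
    ``k = 0``.
    """
    taus = np.asarray(taus, dtype=float)
    if not (np.isfinite(theta) and np.isfinite(delta) and np.isfinite(taus).all()):
        raise InvalidArgumentError("theta, delta and taus must be finite")
    psi = np.concatenate(([0.0], np.cumsum(theta - delta - taus)))
    psi -= psi.max()  # log-sum-exp stabilization
    expo = np.exp(psi)
    return expo / expo.sum()


def _prob_grid(thetas: np.ndarray, deltas: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Probabilities of shape (n_persons, n_items, m+1), vectorized."""
    adv = thetas[:, None] - deltas[None, :]                  # (n, L)
    steps = adv[:, :, None] - taus[None, None, :]            # (n, L, m)
    psi = np.concatenate(
        (np.zeros(adv.shape + (1,)), np.cumsum(steps, axis=2)), axis=2
    )
    psi -= psi.max(axis=2, keepdims=True)
    expo = np.exp(psi)
    return expo / expo.sum(axis=2, keepdims=True)


def _moments(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected item score and its variance from a probability grid."""
    cats = np.arange(probs.shape[-1], dtype=float)
    mean = probs @ cats
    var = probs @ cats**2 - mean**2
    return mean, var


def expected_score(
    theta: float,
    params: RSMParams,
    item_subset: Sequence[int] | None = None,
) -> float:
    """Expected raw total at ability ``theta`` (test characteristic curve)."""
    deltas = _subset_deltas(params, item_subset)
    probs = _prob_grid(np.atleast_1d(float(theta)), deltas, params.taus)
    mean, _ = _moments(probs)
    return float(mean.sum())


def _subset_deltas(
    params: RSMParams, item_subset: Sequence[int] | None
) -> np.ndarray:
    if item_subset is None:
        return params.deltas
    idx = np.asarray(list(item_subset), dtype=int)
    if idx.size == 0:
        raise InvalidArgumentError("item subset must be non-empty")
    return params.deltas[idx]


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def _prox_persons(raw: np.ndarray, mx: np.ndarray) -> np.ndarray:
    p = np.clip(raw / mx, 0.02, 0.98)
    return np.log(p / (1 - p))


def fit_jmle(
    matrix: ResponseMatrix, config: JMLEConfig | None = None
) -> tuple[RSMParams, list[PersonMeasure]]:
    """Joint maximum likelihood estimation of the rating-scale model.

    Alternates damped Newton-Raphson updates of person abilities, item
    difficulties and shared thresholds until the largest absolute update
    drops below ``config.tol``.  Persons with extreme raw totals are held
    out of item estimation and measured afterwards by test-characteristic-
    curve inversion with the extreme-score adjustment.

    Returns the fitted parameters and one :class:`PersonMeasure` per person,
    in input order.
    """
    config = config or JMLEConfig()
    m = matrix.max_category
    X = matrix.scores
    answered = ~np.isnan(X)

    for k in range(m + 1):
        if not (X[answered] == k).any():
            raise UnobservedCategoryError(k)

    raw = matrix.raw_scores()
    mx = matrix.max_scores()
    nonextreme = (raw > 0) & (raw < mx)
    if nonextreme.sum() < 2:
        raise EstimationError(
            "fewer than 2 persons with non-extreme raw scores; "
            "items are not estimable"
        )

    Xe = X[nonextreme]
    ans = ~np.isnan(Xe)
    Xz = np.where(ans, Xe, 0.0)

    # PROX starting values
    thetas = _prox_persons(raw[nonextreme], mx[nonextreme])
    item_p = np.clip(
        np.nansum(Xe, axis=0) / (m * ans.sum(axis=0)), 0.02, 0.98
    )
    deltas = np.log((1 - item_p) / item_p)
    deltas -= deltas.mean()
    taus = np.zeros(m)

    # sufficient statistics
    s_item = np.nansum(Xe, axis=0)                     # per-item score total
    r_person = np.nansum(Xe, axis=1)                   # per-person total
    T = np.array(
        [(Xe[ans] >= j).sum() for j in range(1, m + 1)], dtype=float
    )                                                  # threshold counts

    max_update = np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        probs = _prob_grid(thetas, deltas, taus)
        mean, var = _moments(probs)
        mean = np.where(ans, mean, 0.0)
        var = np.where(ans, var, 0.0)

        # persons
        dtheta = np.clip(
            (r_person - mean.sum(axis=1)) / np.maximum(var.sum(axis=1), 1e-10),
            -1.0, 1.0,
        )
        thetas = np.clip(thetas + dtheta, -_THETA_BOUND, _THETA_BOUND)

        # items
        probs = _prob_grid(thetas, deltas, taus)
        mean, var = _moments(probs)
        mean = np.where(ans, mean, 0.0)
        var = np.where(ans, var, 0.0)
        ddelta = np.clip(
            (mean.sum(axis=0) - s_item) / np.maximum(var.sum(axis=0), 1e-10),
            -1.0, 1.0,
        )
        deltas = np.clip(deltas + ddelta, -_THETA_BOUND, _THETA_BOUND)
        shift = deltas.mean()
        deltas -= shift
        thetas -= shift  # keep person frame consistent with centered items

        # thresholds
        if m > 1:
            probs = _prob_grid(thetas, deltas, taus)
            cum = np.cumsum(probs[:, :, ::-1], axis=2)[:, :, ::-1]
            dtau = np.zeros(m)
            for j in range(1, m + 1):
                pj = np.where(ans, cum[:, :, j], 0.0)
                g = pj.sum() - T[j - 1]
                gp = (pj * (1 - pj) * ans).sum()
                dtau[j - 1] = np.clip(g / max(gp, 1e-10), -1.0, 1.0)
            taus = taus + dtau
            tshift = taus.mean()
            taus -= tshift
            deltas = deltas + tshift  # tau recentering compensated by items
            shift = deltas.mean()
            deltas -= shift
            thetas -= shift
        else:
            dtau = np.zeros(1)

        max_update = max(
            np.abs(dtheta).max(), np.abs(ddelta).max(), np.abs(dtau).max()
        )
        logger.debug("JMLE iter %d: max update %.6f", it, max_update)
        if max_update < config.tol:
            break

    converged = bool(max_update < config.tol)
    if not converged:
        logger.warning(
            "JMLE did not converge in %d iterations (max update %.5f)",
            config.max_iter, max_update,
        )

    if config.bias_correction:
        L = matrix.n_items
        deltas = deltas * (L - 1) / L
        deltas -= deltas.mean()
        taus = taus * (L - 1) / L
        taus -= taus.mean()

    params = RSMParams(
        deltas=deltas - deltas.mean(),
        taus=taus - taus.mean(),
        n_categories=matrix.n_categories,
        fit_meta=FitMeta(iterations=it, max_update=float(max_update),
                         converged=converged),
    )

    measures: list[PersonMeasure] = []
    for i, pid in enumerate(matrix.person_ids):
        subset = np.flatnonzero(answered[i])
        meas, se = person_measure_from_raw(
            raw[i], params, item_subset=subset,
            extreme_adjust=config.extreme_adjust,
        )
        measures.append(
            PersonMeasure(
                person_id=pid,
                raw_score=float(raw[i]),
                max_score=float(mx[i]),
                measure=meas,
                se=se,
                extreme=bool(~nonextreme[i]),
            )
        )
    return params, measures


# ---------------------------------------------------------------------------
# person measurement and conversion
# ---------------------------------------------------------------------------


def person_measure_from_raw(
    raw: float,
    params: RSMParams,
    item_subset: Sequence[int] | None = None,
    extreme_adjust: float = 0.3,
) -> tuple[float, float]:
    """Measure and SE for a raw total by inverting the test characteristic curve.

    Solves ``expected_score(theta) = raw'`` by Newton-Raphson, where ``raw'``
    equals ``raw`` except that extreme totals (0 or the maximum) are pulled
    inward by ``extreme_adjust`` score points so the measure stays finite.
    The standard error is ``1 / sqrt(test information)`` at the solution.
    """
    deltas = _subset_deltas(params, item_subset)
    taus = params.taus
    m = params.n_categories - 1
    top = m * len(deltas)
    if not 0 <= raw <= top:
        raise InvalidArgumentError(f"raw score {raw} outside [0, {top}]")

    target = float(raw)
    if target == 0:
        target = extreme_adjust
    elif target == top:
        target = top - extreme_adjust

    p = min(max(target / top, 1e-6), 1 - 1e-6)
    theta = float(np.log(p / (1 - p)))
    for _ in range(100):
        probs = _prob_grid(np.atleast_1d(theta), deltas, taus)
        mean, var = _moments(probs)
        resid = target - mean.sum()
        info = max(var.sum(), 1e-12)
        step = np.clip(resid / info, -2.0, 2.0)
        theta += step
        if abs(step) < 1e-12:
            break
    probs = _prob_grid(np.atleast_1d(theta), deltas, taus)
    _, var = _moments(probs)
    se = 1.0 / np.sqrt(max(var.sum(), 1e-12))
    return float(theta), float(se)


def conversion_table(
    params: RSMParams,
    L: int | None = None,
    extreme_adjust: float = 0.3,
) -> ConversionTable:
    """Score-to-measure conversion for every achievable rescored total.

    Produces ``m*L + 1`` rows; the original-scale total column maps each
    rescored total back to the published 0/2/4 coding.
    """
    if L is None:
        L = params.n_items
    if L != params.n_items:
        raise InvalidArgumentError(
            f"L={L} does not match the {params.n_items} fitted items"
        )
    m = params.n_categories - 1
    totals = np.arange(m * L + 1)
    rows = [
        person_measure_from_raw(t, params, extreme_adjust=extreme_adjust)
        for t in totals
    ]
    measures = np.array([r[0] for r in rows])
    ses = np.array([r[1] for r in rows])
    return ConversionTable(
        rescored_total=totals,
        original_total=2 * (m * L - totals),
        measure=measures,
        se=ses,
    )


def wright_psr(
    measures: Sequence[PersonMeasure], include_extreme: bool = False
) -> float:
    """Wright's person separation reliability.

    ``R = (Var_obs - mean(se^2)) / Var_obs`` over the included persons,
    floored at zero.  Persons with extreme raw totals are excluded by
    default because their measures are extrapolated.
    """
    kept = [
        pm for pm in measures if include_extreme or not pm.extreme
    ]
    if len(kept) < 2:
        raise InvalidArgumentError(
            "need >= 2 included persons to compute reliability"
        )
    vals = np.array([pm.measure for pm in kept])
    errs = np.array([pm.se for pm in kept])
    var_obs = vals.var(ddof=1)
    if var_obs <= 0:
        return 0.0
    return float(max(0.0, (var_obs - np.mean(errs**2)) / var_obs))
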
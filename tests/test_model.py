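"""Rating-scale model kernel, JMLE estimation and person measurement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cncrasch.errors import (
    EstimationError,
    InvalidArgumentError,
    UnobservedCategoryError,
)
from cncrasch.model import (
    JMLEConfig,
    PersonMeasure,
    ResponseMatrix,
    RSMParams,
    category_probabilities,
    conversion_table,
    expected_score,
    fit_jmle,
    person_measure_from_raw,
    wright_psr,
)
from cncrasch.simulate import SimulationConfig, generate_cohort


def pcm_probabilities(theta, delta, taus):
    """Brute-force partial-credit formula with shared thresholds (oracle)."""
    m = len(taus)
    numerators = []
    for k in range(m + 1):
        s = math.fsum(theta - delta - taus[j] for j in range(k))
        numerators.append(math.exp(s))
    total = math.fsum(numerators)
    return np.array([v / total for v in numerators])


class TestCategoryProbabilities:
    def test_full_symmetry_gives_uniform(self):
        p = category_probabilities(0.0, 0.0, (0.0, 0.0))
        assert np.allclose(p, 1 / 3, atol=1e-12)

    def test_hand_expanded_example(self):
        # unnormalized terms 1, e^2, e^2 for theta=1, delta=0, taus=(-1, 1)
        p = category_probabilities(1.0, 0.0, (-1.0, 1.0))
        assert np.round(p, 4).tolist() == [0.0634, 0.4683, 0.4683]

    @given(
        theta=st.floats(-6, 6),
        delta=st.floats(-4, 4),
        t1=st.floats(-3, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalization_and_oracle(self, theta, delta, t1):
        taus = (t1, -t1)
        p = category_probabilities(theta, delta, taus)
        assert p.min() >= 0
        assert abs(p.sum() - 1) < 1e-12
        assert np.allclose(p, pcm_probabilities(theta, delta, taus), atol=1e-12)

    def test_thousand_random_draws_normalize(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            theta, delta = rng.normal(0, 2, 2)
            taus = rng.normal(0, 1, 2)
            p = category_probabilities(theta, delta, taus)
            assert abs(p.sum() - 1) < 1e-12
            assert (p >= 0).all()

    def test_nonfinite_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            category_probabilities(np.inf, 0.0, (0.0, 0.0))
        with pytest.raises(InvalidArgumentError):
            category_probabilities(0.0, 0.0, (np.nan, 0.0))


class TestExpectedScore:
    def test_asymptotes(self, symmetric_params_8):
        assert expected_score(-20, symmetric_params_8) <= 1e-6
        assert abs(expected_score(20, symmetric_params_8) - 16) <= 1e-6

    def test_symmetry_midpoint(self, flat_params_8):
        assert expected_score(0.0, flat_params_8) == pytest.approx(8.0)

    def test_strictly_increasing(self, symmetric_params_8):
        grid = np.linspace(-6, 6, 61)
        vals = [expected_score(t, symmetric_params_8) for t in grid]
        assert (np.diff(vals) > 0).all()

    def test_empty_subset_rejected(self, symmetric_params_8):
        with pytest.raises(InvalidArgumentError):
            expected_score(0.0, symmetric_params_8, item_subset=[])


class TestPersonMeasureFromRaw:
    def test_symmetric_midscore_measures_zero(self, flat_params_8):
        measure, se = person_measure_from_raw(8, flat_params_8)
        assert measure == pytest.approx(0.0, abs=1e-6)
        assert se > 0

    def test_measures_strictly_increasing(self, symmetric_params_8):
        ms = [person_measure_from_raw(r, symmetric_params_8)[0]
              for r in range(17)]
        assert (np.diff(ms) > 0).all()

    def test_tcc_inversion_round_trip(self, symmetric_params_8):
        for raw in range(1, 16):  # non-extreme totals
            theta, _ = person_measure_from_raw(raw, symmetric_params_8)
            assert expected_score(theta, symmetric_params_8) == pytest.approx(
                raw, abs=1e-6
            )

    def test_extreme_scores_finite_and_adjusted(self, symmetric_params_8):
        lo, _ = person_measure_from_raw(0, symmetric_params_8)
        hi, _ = person_measure_from_raw(16, symmetric_params_8)
        assert np.isfinite(lo) and np.isfinite(hi)
        # the adjusted targets are 0.3 and 15.7 score points
        assert expected_score(lo, symmetric_params_8) == pytest.approx(
            0.3, abs=1e-6
        )
        assert expected_score(hi, symmetric_params_8) == pytest.approx(
            15.7, abs=1e-6
        )

    def test_out_of_range_rejected(self, symmetric_params_8):
        with pytest.raises(InvalidArgumentError):
            person_measure_from_raw(17, symmetric_params_8)


class TestConversionTable:
    def test_row_counts_8_and_10_items(self, symmetric_params_8):
        assert len(conversion_table(symmetric_params_8)) == 17
        d10 = np.linspace(-1, 1, 10)
        params10 = RSMParams(deltas=d10 - d10.mean(),
                             taus=np.array([-1.0, 1.0]))
        assert len(conversion_table(params10)) == 21

    def test_monotone_and_original_total_mapping(self, symmetric_params_8):
        table = conversion_table(symmetric_params_8)
        assert (np.diff(table.measure) > 0).all()
        assert (table.original_total == 2 * (16 - table.rescored_total)).all()
        assert table.original_total[0] == 32 and table.original_total[-1] == 0


class TestJMLE:
    def test_parameter_recovery(self, large_cohort):
        params, _ = fit_jmle(
            large_cohort.baseline, JMLEConfig(bias_correction=True)
        )
        rmse_d = np.sqrt(np.mean((params.deltas - large_cohort.deltas) ** 2))
        rmse_t = np.sqrt(np.mean((params.taus - large_cohort.taus) ** 2))
        assert params.fit_meta.converged
        assert rmse_d <= 0.15
        assert rmse_t <= 0.15

    def test_identification_constraints(self, large_cohort):
        params, _ = fit_jmle(large_cohort.baseline)
        assert abs(params.deltas.mean()) < 1e-6
        assert abs(params.taus.sum()) < 1e-6

    def test_identical_items_get_equal_difficulty(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 3, size=(80, 4)).astype(float)
        scores[:, 1] = scores[:, 0]  # duplicate column
        mat = ResponseMatrix(
            person_ids=[f"p{i}" for i in range(80)],
            item_ids=["a", "b", "c", "d"],
            scores=scores,
        )
        params, _ = fit_jmle(mat)
        assert abs(params.deltas[0] - params.deltas[1]) <= 1e-3

    def test_all_extreme_persons_rejected(self):
        scores = np.array([[0, 0, 0], [2, 2, 2], [0, 0, 0], [2, 2, 2]],
                          dtype=float)
        mat = ResponseMatrix(
            person_ids=list("wxyz"), item_ids=list("abc"), scores=scores
        )
        with pytest.raises(EstimationError):
            fit_jmle(mat)

    def test_unobserved_category_named(self):
        scores = np.array([[0, 2, 0], [2, 0, 2], [0, 0, 2], [2, 2, 0]],
                          dtype=float)
        mat = ResponseMatrix(
            person_ids=list("wxyz"), item_ids=list("abc"), scores=scores
        )
        with pytest.raises(UnobservedCategoryError, match="category 1"):
            fit_jmle(mat)

    def test_translation_invariance_of_items(self):
        """Shifting all true abilities leaves centered item estimates alone
        and shifts person measures by about the same constant."""
        shift = 1.0
        base = SimulationConfig(n_persons=1500, seed=99)
        shifted = SimulationConfig(
            n_persons=1500, theta_mean=base.theta_mean + shift, seed=99
        )
        c0, c1 = generate_cohort(base), generate_cohort(shifted)
        p0, m0 = fit_jmle(c0.baseline)
        p1, m1 = fit_jmle(c1.baseline)
        assert np.allclose(p0.deltas, p1.deltas, atol=0.15)
        mean0 = np.mean([pm.measure for pm in m0 if not pm.extreme])
        mean1 = np.mean([pm.measure for pm in m1 if not pm.extreme])
        assert mean1 - mean0 == pytest.approx(shift, abs=0.15)

    def test_person_measures_round_trip_raw_scores(self, study_cohort):
        params, measures = fit_jmle(study_cohort.baseline)
        for pm in measures:
            if not pm.extreme:
                # stacked frame: measure inverts the TCC at the raw total
                assert expected_score(pm.measure, params) == pytest.approx(
                    pm.raw_score, abs=1e-5
                )


class TestWrightPSR:
    @staticmethod
    def _measures(values, ses):
        return [
            PersonMeasure(i, 1.0, 2.0, v, s, False)
            for i, (v, s) in enumerate(zip(values, ses))
        ]

    def test_error_free_limit(self):
        vals = [-1.0, 0.0, 1.0, 2.0]
        r = wright_psr(self._measures(vals, [1e-6] * 4))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_all_noise_limit(self):
        vals = np.array([-1.0, 0.0, 1.0, 2.0])
        se = np.sqrt(vals.var(ddof=1))
        assert wright_psr(self._measures(vals, [se] * 4)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_analytic_expectation_at_study_scale(self):
        """True SD 1.25 with SE 0.45 gives reliability near 0.87."""
        rng = np.random.default_rng(11)
        theta = rng.normal(-0.8, 1.25, 2000)
        observed = theta + rng.normal(0, 0.45, 2000)
        r = wright_psr(self._measures(observed, [0.45] * 2000))
        assert r == pytest.approx((1.25**2 - 0.45**2) / 1.25**2, abs=0.05)

    def test_extremes_excluded_by_default(self):
        pms = self._measures([-1.0, 0.0, 1.0], [0.3] * 3)
        pms.append(PersonMeasure("x", 0.0, 2.0, 5.0, 1.5, True))
        assert wright_psr(pms) != wright_psr(pms, include_extreme=True)

    def test_too_few_persons_rejected(self):
        with pytest.raises(InvalidArgumentError):
            wright_psr(self._measures([0.5], [0.3]))


class TestResponseMatrixValidation:
    def test_score_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ResponseMatrix(["a", "b"], ["i", "j"],
                           np.array([[0.0, 3.0], [1.0, 2.0]]))

    def test_person_with_no_responses_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ResponseMatrix(["a", "b"], ["i", "j"],
                           np.array([[np.nan, np.nan], [1.0, 2.0]]))

    def test_missing_shrinks_max_score(self):
        mat = ResponseMatrix(["a", "b"], ["i", "j", "k"],
                             np.array([[1.0, np.nan, 2.0], [0.0, 1.0, 2.0]]))
        assert mat.max_scores().tolist() == [4, 6]
        assert mat.raw_scores().tolist() == [3, 3]
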
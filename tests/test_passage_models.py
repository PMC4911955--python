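"""Candidate model bases, through-origin OLS, AICc and LOOCV.

The least-squares and cross-validation routines are checked against
brute-force oracles: normal equations solved directly, and an explicit
refit-with-one-deleted loop.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import streampass as sp
from streampass import passage_models as pm

from conftest import make_signed_frame

ALL_FORMS = [
    pm.FIRST_ORDER,
    pm.POLYNOMIAL,
    pm.SEGMENTED_FIRST,
    pm.SEGMENTED_POLY_SHARED,
    pm.SEGMENTED_POLY_ANTISYM,
]


def normal_equations_fit(X, y):
    """Brute-force OLS oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestBasis:
    @pytest.mark.parametrize(
        "form,x,expected",
        [
            (pm.SEGMENTED_FIRST, 5, [5.0, 0.0]),
            (pm.SEGMENTED_FIRST, -3, [0.0, -3.0]),
            (pm.SEGMENTED_POLY_SHARED, -2, [0.0, -2.0, 4.0]),
            (pm.SEGMENTED_POLY_ANTISYM, -2, [0.0, -2.0, -4.0]),
            (pm.FIRST_ORDER, 7, [7.0]),
            (pm.POLYNOMIAL, 3, [3.0, 9.0]),
        ],
    )
    def test_basis_vectors(self, form, x, expected):
        assert form.basis(x).tolist() == [expected]

    @pytest.mark.parametrize("form", ALL_FORMS, ids=lambda f: f"{f.name}-{f.terms[-1]}")
    def test_basis_at_zero_is_zero(self, form):
        assert np.all(form.basis(0.0) == 0.0)

    def test_unknown_form_rejected(self):
        with pytest.raises(pm.ModelSpecError):
            pm.get_form("cubic")

    def test_seg_poly_basis_selectable(self):
        shared = pm.get_form("segmented_poly")
        anti = pm.get_form("segmented_poly", "antisymmetric")
        assert shared.terms[-1] == "x^2"
        assert anti.terms[-1] == "x|x|"


class TestFitModel:
    def test_exact_line_recovers_slope_with_zero_rss(self, exact_line_sample):
        fit = pm.fit_model(exact_line_sample, pm.FIRST_ORDER)
        assert fit.coefficients == pytest.approx([2.0])
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_segmented_four_point_hand_solution(self):
        # y = b+ x+ + b- x-  on x=(1,-1,2,-2), y=(3,-2,6,-4):
        # branches decouple -> b+ = (3+12)/5 = 3, b- = (2+8)/5 = 2
        sample = make_signed_frame([1, -1, 2, -2, 3, -3], [3, -2, 6, -4, 9, -6])
        fit = pm.fit_model(sample, pm.SEGMENTED_FIRST)
        assert fit.coefficients == pytest.approx([3.0, 2.0])

    @pytest.mark.parametrize("form", ALL_FORMS, ids=lambda f: f"{f.name}-{f.terms[-1]}")
    def test_fit_matches_normal_equations_oracle(self, form, rng):
        x = np.concatenate([rng.integers(1, 60, 25), -rng.integers(1, 60, 25)])
        y = 16.0 * x + rng.normal(0, 20, x.size)
        sample = make_signed_frame(x, y)
        fit = pm.fit_model(sample, form)
        oracle = normal_equations_fit(form.basis(x.astype(float)), y)
        np.testing.assert_allclose(fit.coefficients, oracle, rtol=1e-9)

    def test_one_sided_sample_names_empty_branch(self):
        sample = make_signed_frame([1, 2, 3, 4, 5, 6], [2, 4, 6, 8, 10, 12])
        with pytest.raises(pm.FitError, match="x-"):
            pm.fit_model(sample, pm.SEGMENTED_FIRST)

    def test_too_few_observations_rejected(self):
        sample = make_signed_frame([1, -1, 2], [2.0, -2.0, 4.0])
        with pytest.raises(pm.FitError, match="at least"):
            pm.fit_model(sample, pm.SEGMENTED_FIRST)

    @pytest.mark.parametrize("form", ALL_FORMS, ids=lambda f: f"{f.name}-{f.terms[-1]}")
    def test_fitted_models_pass_through_origin(self, segmented_sample, form):
        fit = pm.fit_model(segmented_sample, form)
        assert fit.predict(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_equal_true_slopes_converge_as_noise_vanishes(self, rng):
        x = np.concatenate([rng.integers(1, 50, 30), -rng.integers(1, 50, 30)])
        gaps = []
        for noise in (10.0, 1.0, 0.01):
            y = 17.0 * x + rng.normal(0, noise, x.size)
            fit = pm.fit_model(make_signed_frame(x, y), pm.SEGMENTED_FIRST)
            gaps.append(abs(fit.coefficients[0] - fit.coefficients[1]))
        assert gaps[2] < gaps[0]
        assert gaps[2] < 0.01


class TestAICc:
    def test_hand_formula(self):
        # n=10, rss=10, K=2: 10 ln(1) + 10 ln(2pi) + 10 + 4 + 12/7
        expected = 10 * math.log(2 * math.pi) + 10 + 4 + 12 / 7
        assert pm.gaussian_aicc(10.0, 10, 2) == pytest.approx(expected)

    def test_penalty_is_strictly_increasing_in_parameter_count(self):
        vals = [pm.gaussian_aicc(25.0, 30, K) for K in (1, 2, 3, 4)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(pm.ModelSpecError):
            pm.gaussian_aicc(10.0, 4, 3)

    @settings(deadline=None, max_examples=40)
    @given(
        rss=st.floats(0.5, 1e6),
        n=st.integers(8, 200),
        k=st.integers(1, 4),
    )
    def test_extra_parameter_never_wins_at_equal_rss(self, rss, n, k):
        assert pm.gaussian_aicc(rss, n, k) < pm.gaussian_aicc(rss, n, k + 1)


class TestLOOCV:
    def test_perfect_fit_has_zero_error(self, exact_line_sample):
        cv = pm.loocv(exact_line_sample, pm.FIRST_ORDER)
        assert cv.accuracy_pct == pytest.approx(0.0, abs=1e-9)
        assert cv.mse == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(
            cv.predictions, exact_line_sample["video_signed"], rtol=1e-12
        )

    @pytest.mark.parametrize("form", ALL_FORMS, ids=lambda f: f"{f.name}-{f.terms[-1]}")
    def test_hat_matrix_loocv_equals_refit_oracle(self, form, rng):
        x = np.concatenate([rng.integers(1, 40, 8), -rng.integers(1, 40, 8)])
        y = 14.0 * x + rng.normal(0, 25, x.size)
        sample = make_signed_frame(x, y)
        cv = pm.loocv(sample, form)
        X = form.basis(x.astype(float))
        oracle = np.empty(len(x))
        for i in range(len(x)):
            keep = np.arange(len(x)) != i
            coef = normal_equations_fit(X[keep], y[keep])
            oracle[i] = X[i] @ coef
        np.testing.assert_allclose(cv.predictions, oracle, rtol=1e-9, atol=1e-9)

    def test_deletion_induced_rank_loss_is_named(self):
        # only one downstream observation: deleting it empties the branch
        sample = make_signed_frame([1, 2, 3, 4, 5, -1], [2, 4, 6, 8, 10, -2])
        with pytest.raises(pm.FitError, match="observation 5"):
            pm.loocv(sample, pm.SEGMENTED_FIRST)


class TestSelectModel:
    def test_distinct_slopes_prefer_segmented_first(self, segmented_sample):
        fits = pm.select_model(segmented_sample)
        names = [f.form.name for f in fits]
        assert names[0] == "segmented_first"
        assert names.index("segmented_first") < names.index("first_order")

    def test_single_slope_prefers_parsimony(self, rng):
        x = np.concatenate([rng.integers(1, 60, 35), -rng.integers(1, 60, 35)])
        y = 16.0 * x + rng.normal(0, 10, x.size)
        fits = pm.select_model(make_signed_frame(x, y))
        names = [f.form.name for f in fits]
        assert names.index("first_order") < names.index("segmented_first")

    def test_all_fits_carry_loocv_metrics(self, segmented_sample):
        fits = pm.select_model(segmented_sample)
        assert all(f.loocv_accuracy_pct is not None for f in fits)
        assert all(f.loocv_mse is not None and f.loocv_mse >= 0 for f in fits)

    def test_override_forces_named_form_to_top(self, segmented_sample):
        fits = pm.select_model(segmented_sample, override="polynomial")
        assert fits[0].form.name == "polynomial"

    def test_one_sided_sample_still_ranks_unsegmented_forms(self):
        x = np.arange(1, 21)
        sample = make_signed_frame(x, 12.0 * x + 0.5)
        fits = pm.select_model(sample)
        assert {f.form.name for f in fits} == {"first_order", "polynomial"}

    def test_report_mirrors_ranking(self, segmented_sample):
        fits = pm.select_model(segmented_sample)
        report = pm.model_report(fits)
        assert list(report["model"]) == [f.form.name for f in fits]
        assert report["aicc"].is_monotonic_increasing
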
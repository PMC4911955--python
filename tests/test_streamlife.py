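"""Weighted stream life, morphology regression, and survival curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import streampass as sp
from streampass import streamlife as sl


def make_records(depths, widths, lives):
    return pd.DataFrame(
        {
            "stream": [f"s{i}" for i in range(len(depths))],
            "width_m": widths,
            "depth_cm": depths,
            "stream_life": lives,
        }
    )


class TestWeightedStreamLife:
    def test_equal_weights_average(self):
        assert sl.weighted_stream_life([4, 6], [10, 10]) == pytest.approx(5.0)

    def test_hand_computed_weights(self):
        assert sl.weighted_stream_life([10, 2, 6], [1, 3, 0]) == pytest.approx(4.0)

    def test_single_mechanism_is_identity(self):
        assert sl.weighted_stream_life([7.3], [12]) == pytest.approx(7.3)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            sl.weighted_stream_life([4, 6], [0, 0])

    @settings(deadline=None, max_examples=50)
    @given(
        means=st.lists(st.floats(0.1, 30), min_size=2, max_size=5),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_weighted_mean_is_between_extremes(self, means, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 50, len(means))
        w = sl.weighted_stream_life(means, counts)
        assert min(means) - 1e-9 <= w <= max(means) + 1e-9


class TestStreamLifeRegression:
    def test_exact_line_recovered(self):
        depths = np.array([5.0, 8.0, 11.0, 14.0, 20.0, 26.0])
        records = make_records(depths, depths / 3.0, 2.0 + 0.4 * depths)
        model = sl.fit_streamlife_model(records, predictor="depth_cm")
        assert model.intercept == pytest.approx(2.0, abs=1e-9)
        assert model.slope == pytest.approx(0.4, abs=1e-10)
        assert model.rss == pytest.approx(0.0, abs=1e-16)

    def test_matches_normal_equations_oracle(self, rng):
        depths = rng.uniform(5, 30, 7)
        lives = 3.0 + 0.3 * depths + rng.normal(0, 1, 7)
        records = make_records(depths, depths / 3.0 + rng.normal(0, 0.3, 7), lives)
        model = sl.fit_streamlife_model(records, predictor="depth_cm")
        X = np.column_stack([np.ones(7), depths])
        beta = np.linalg.solve(X.T @ X, X.T @ lives)
        assert model.intercept == pytest.approx(beta[0], rel=1e-9)
        assert model.slope == pytest.approx(beta[1], rel=1e-9)

    def test_depth_generated_data_selects_depth(self, rng):
        depths = rng.uniform(5, 30, 8)
        widths = rng.uniform(2, 8, 8)  # unrelated to stream life
        lives = 2.0 + 0.4 * depths + rng.normal(0, 0.4, 8)
        model = sl.fit_streamlife_model(make_records(depths, widths, lives))
        assert model.predictor == "depth_cm"
        assert (
            model.aicc_by_predictor["depth_cm"] < model.aicc_by_predictor["width_m"]
        )

    def test_collinearity_is_reported(self, rng):
        depths = np.linspace(5, 30, 6)
        records = make_records(depths, depths / 3.0, 2 + 0.4 * depths)
        model = sl.fit_streamlife_model(records, predictor="depth_cm")
        assert model.predictor_correlation == pytest.approx(1.0)

    def test_streamlife_records_from_long_table(self):
        table = pd.DataFrame(
            {
                "stream": ["a", "a", "b"],
                "width_m": [4.0, 4.0, 6.0],
                "depth_cm": [10.0, 10.0, 20.0],
                "mech": ["senescence", "predation", "senescence"],
                "mean_days": [10.0, 2.0, 8.0],
                "n_dead": [1, 3, 5],
            }
        )
        records = sl.streamlife_records(table)
        assert records.loc[records.stream == "a", "stream_life"].iloc[0] == pytest.approx(4.0)
        assert records.loc[records.stream == "b", "stream_life"].iloc[0] == pytest.approx(8.0)


class TestPredictStreamLife:
    def _model(self, intercept, slope):
        depths = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        records = make_records(depths, depths / 3, intercept + slope * depths)
        return sl.fit_streamlife_model(records, predictor="depth_cm")

    def test_mean_and_ratio_sd(self):
        model = self._model(0.0, 0.5)
        pred = sl.predict_stream_life(model, 10.0)
        assert pred.mean == pytest.approx(5.0, abs=1e-9)
        assert pred.sd == pytest.approx(2.495, abs=1e-9)

    def test_sd_ratio_on_published_mean(self):
        # mean 7.1 days -> ratio-based SD 3.543 (to printed precision)
        assert 0.499 * 7.1 == pytest.approx(3.543, abs=5e-4)

    def test_flat_model_is_depth_independent(self):
        depths = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        records = make_records(depths, depths / 3, np.full(6, 6.0))
        model = sl.fit_streamlife_model(records, predictor="depth_cm")
        a = sl.predict_stream_life(model, 5.0)
        b = sl.predict_stream_life(model, 50.0)
        assert a.mean == pytest.approx(b.mean)

    def test_negative_predicted_mean_raises(self):
        model = self._model(-10.0, 0.1)
        with pytest.raises(ValueError, match="non-positive"):
            sl.predict_stream_life(model, 5.0)

    def test_out_of_range_depth_warns(self):
        model = self._model(1.0, 0.5)
        with pytest.warns(UserWarning, match="sanity range"):
            sl.predict_stream_life(model, 300.0)


class TestSurvivalCurve:
    def test_degenerate_sd_is_a_step(self):
        curve = sl.survival_curve(3.0, 0.0)
        np.testing.assert_allclose(curve.S, [1.0, 1.0, 1.0, 0.5, 0.0])
        assert curve.N == 4

    def test_truncnorm_matches_quadrature_oracle(self):
        mean, sd = 5.0, 2.495
        curve = sl.survival_curve(mean, sd)

        def density(x):
            return stats.norm.pdf(x, mean, sd)

        norm_const, _ = integrate.quad(density, 0, np.inf)
        for t in (1, 3, 5, 8):
            tail, _ = integrate.quad(density, t, np.inf)
            assert curve.S[t] == pytest.approx(tail / norm_const, rel=1e-6)
        # truncation raises S_5 slightly above the untruncated 0.5
        assert curve.S[5] > 0.5

    def test_monotone_and_anchored(self):
        for mean, sd in [(2.0, 0.5), (7.1, 3.543), (15.0, 7.0), (1.0, 4.0)]:
            for family in sl.SURVIVAL_FAMILIES:
                curve = sl.survival_curve(mean, sd, family=family)
                assert curve.S[0] == 1.0
                assert np.all(np.diff(curve.S) <= 1e-12)
                assert curve.S[curve.N] < curve.eps
                assert np.all((curve.S >= 0) & (curve.S <= 1))

    def test_longer_mean_dominates_pointwise(self):
        short = sl.survival_curve(5.0, 2.0)
        long = sl.survival_curve(8.0, 2.0)
        t = np.arange(short.N + 1)
        assert np.all(long.S[t] >= short.S[t] - 1e-12)

    def test_horizon_grows_with_mean_and_sd(self):
        base = sl.survival_curve(5.0, 2.0).N
        assert sl.survival_curve(8.0, 2.0).N >= base
        assert sl.survival_curve(5.0, 3.5).N >= base

    @settings(deadline=None, max_examples=30)
    @given(
        mean=st.floats(0.5, 20.0),
        ratio=st.floats(0.05, 1.0),
    )
    def test_property_sweep_monotonicity(self, mean, ratio):
        curve = sl.survival_curve(mean, ratio * mean)
        assert curve.S[0] == 1.0
        assert np.all(np.diff(curve.S) <= 1e-12)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            sl.survival_curve(5.0, 2.0, family="weibull")

    def test_round_trip_csv(self, tmp_path):
        curve = sl.survival_curve(7.1, 3.543)
        path = tmp_path / "surv.csv"
        sl.write_survival_curve(curve, path)
        back = pd.read_csv(path)
        np.testing.assert_allclose(back["S"], curve.S)
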
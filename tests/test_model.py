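"""Naka-Rushton evaluation, bound derivation, and multistart fitting."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crfdk import (
    CRFPoints,
    FitBounds,
    NakaRushtonModel,
    NRParams,
    TooFewPointsError,
    derive_bounds,
    evaluate_nre,
    fit_crf,
)

params_strategy = st.builds(
    NRParams,
    r_max=st.floats(0.5, 40.0),
    c50=st.floats(5.0, 100.0),
    n=st.floats(0.3, 6.0),
    b=st.floats(0.0, 5.0),
)


class TestEvaluate:
    def test_zero_contrast_returns_baseline(self, demo_params):
        assert evaluate_nre(demo_params, 0.0) == demo_params.b

    def test_half_saturation_identity(self, demo_params):
        expected = demo_params.r_max / 2 + demo_params.b
        assert evaluate_nre(demo_params, demo_params.c50) == pytest.approx(expected)

    def test_hand_computed_value(self):
        # Rmax=15, C50=20, n=2, B=1 at c=100: 15*10000/10400 + 1
        p = NRParams(r_max=15, c50=20, n=2, b=1)
        assert evaluate_nre(p, 100.0) == pytest.approx(15 * 10000 / 10400 + 1, abs=1e-9)
        assert evaluate_nre(p, 100.0) == pytest.approx(15.423, abs=1e-3)

    @pytest.mark.parametrize("bad", [-1.0, 101.0, np.nan])
    def test_invalid_contrast_rejected(self, demo_params, bad):
        with pytest.raises(ValueError):
            evaluate_nre(demo_params, bad)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NRParams(r_max=-1, c50=20, n=2, b=0)
        with pytest.raises(ValueError):
            NRParams(r_max=1, c50=0, n=2, b=0)
        with pytest.raises(ValueError):
            NRParams(r_max=1, c50=np.inf, n=2, b=0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(params=params_strategy)
    def test_monotone_nondecreasing_and_bounded(self, params):
        grid = np.linspace(0, 100, 101)
        r = evaluate_nre(params, grid)
        assert np.all(np.diff(r) >= -1e-12)
        assert np.all(r >= params.b - 1e-12)
        assert np.all(r < params.r_max + params.b + 1e-12)


class TestBounds:
    def test_max_plus_two_sds(self):
        pts = CRFPoints([0, 10, 50, 100], [1, 5, 15, 20], [0.5, 1, 1.5, 2])
        b = derive_bounds(pts)
        assert b.r_max_hi == pytest.approx(24.0)  # MAX=20 + 2*SD(2)
        assert b.b_hi == b.r_max_hi
        assert b.c50_hi == 100.0 and b.n_hi == 6.0

    def test_noiseless_single_trial_sd_zero(self):
        pts = CRFPoints([0, 10, 50, 100], [1, 5, 15, 20])
        assert derive_bounds(pts).r_max_hi == pytest.approx(20.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            CRFPoints([], [])


class TestFit:
    def test_noiseless_recovery(self, demo_params):
        c = np.array([0, 3, 8, 15, 30, 50, 75, 100], dtype=float)
        pts = CRFPoints(c, evaluate_nre(demo_params, c), np.zeros(8))
        res = fit_crf(pts, FitBounds(40, 40), n_restarts=10, seed=0)
        rel = np.abs(res.params.as_vector() - demo_params.as_vector()) / demo_params.as_vector()
        assert np.max(rel) < 1e-4
        assert res.converged

    def test_too_few_points_rejected(self, demo_params):
        pts = CRFPoints([0, 50, 100], evaluate_nre(demo_params, [0, 50, 100]))
        with pytest.raises(TooFewPointsError):
            fit_crf(pts, n_restarts=5, seed=0)

    def test_params_within_bounds(self, noisy_spikes):
        from crfdk import mean_firing_rates

        pts = mean_firing_rates(noisy_spikes)
        bounds = derive_bounds(pts)
        res = fit_crf(pts, bounds, n_restarts=20, seed=3)
        assert bounds.contains(res.params)

    def test_seed_reproducibility(self, noisy_spikes):
        from crfdk import mean_firing_rates

        pts = mean_firing_rates(noisy_spikes)
        r1 = fit_crf(pts, n_restarts=15, seed=99)
        r2 = fit_crf(pts, n_restarts=15, seed=99)
        assert r1.params == r2.params
        assert r1.sse == r2.sse

    def test_more_repetitions_reduce_parameter_error(self, demo_params):
        """Median SSE-fitted parameter error shrinks from 2 to 64 repetitions."""
        from crfdk.scales import generate_scale
        from crfdk.simulate import rates_from_counts, simulate_counts

        contrasts = generate_scale(1, 6)
        errs = {2: [], 64: []}
        rng = np.random.default_rng(1234)
        for _ in range(25):
            for reps in errs:
                counts = simulate_counts(demo_params, contrasts, 2.0, reps, rng)
                y, sd = rates_from_counts(counts, 2.0)
                pts = CRFPoints(contrasts, y, sd)
                res = fit_crf(pts, derive_bounds(pts), n_restarts=5, seed=rng)
                errs[reps].append(
                    np.linalg.norm(res.params.as_vector() - demo_params.as_vector())
                )
        assert np.median(errs[64]) < np.median(errs[2])


class TestResultsObject:
    def test_summary_and_serialization(self, noisy_spikes):
        model = NakaRushtonModel.from_spikes(noisy_spikes)
        res = model.fit(n_restarts=15, seed=5)
        text = res.summary()
        assert "Rmax" in text and "C50" in text
        d = json.loads(res.to_json())
        assert set(d["params"]) == {"r_max", "c50", "n", "b"}
        assert d["sse"] == pytest.approx(res.sse)

    def test_predict_matches_evaluate(self, noisy_spikes):
        model = NakaRushtonModel.from_spikes(noisy_spikes)
        res = model.fit(n_restarts=10, seed=5)
        grid = np.linspace(0, 100, 11)
        np.testing.assert_allclose(res.predict(grid), evaluate_nre(res.params, grid))

    def test_csv_round_trip(self, tmp_path):
        pts = CRFPoints([0, 10, 50, 100], [1.0, 5.0, 15.0, 20.0], [0.5, 1.0, 1.5, 2.0])
        path = tmp_path / "crf.csv"
        pts.to_csv(path)
        back = CRFPoints.from_csv(path)
        np.testing.assert_allclose(back.contrasts, pts.contrasts)
        np.testing.assert_allclose(back.mean_rates, pts.mean_rates)
        np.testing.assert_allclose(back.rate_sds, pts.rate_sds)
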
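"""Poisson cascade simulator: counts, rates, PSTH, round trips."""

import numpy as np
import pytest

from crfdk import (
    NRParams,
    SpikeTrainSet,
    StimulusProtocol,
    mean_firing_rates,
    psth,
    simulate_experiment,
)


@pytest.fixture(scope="module")
def flat10():
    """Degenerate curve with r(c) = 10 spikes/s everywhere above threshold."""
    return NRParams(r_max=10.0, c50=1e-3, n=2.0, b=0.0)


class TestSimulateExperiment:
    def test_mean_count_matches_rate(self, flat10):
        protocol = StimulusProtocol(contrasts=(50.0,), trial_length=2.0, n_repetitions=1000)
        spikes = simulate_experiment(flat10, protocol, seed=0)
        counts = spikes.counts()[0]
        lam = 20.0  # r*T
        se = np.sqrt(lam / 1000)
        assert abs(counts.mean() - lam) < 3 * se

    def test_silent_params_produce_no_spikes(self):
        silent = NRParams(r_max=0.0, c50=50.0, n=2.0, b=0.0)
        protocol = StimulusProtocol(contrasts=(0.0, 50.0, 100.0), trial_length=2.0, n_repetitions=20)
        assert simulate_experiment(silent, protocol, seed=1).total_spikes() == 0

    def test_fano_factor_near_one(self, flat10):
        protocol = StimulusProtocol(contrasts=(80.0,), trial_length=2.0, n_repetitions=1000)
        counts = simulate_experiment(flat10, protocol, seed=2).counts()[0]
        fano = counts.var(ddof=1) / counts.mean()
        # 95% CI of the Fano factor at n=1000: ~1 +/- 2*sqrt(2/999)
        assert abs(fano - 1.0) < 2 * np.sqrt(2 / 999)

    def test_seeded_determinism(self, demo_params):
        protocol = StimulusProtocol(contrasts=(0.0, 30.0, 100.0), trial_length=1.0, n_repetitions=5)
        a = simulate_experiment(demo_params, protocol, seed=42)
        b = simulate_experiment(demo_params, protocol, seed=42)
        for ta, tb in zip(a.trains, b.trains):
            for ra, rb in zip(ta, tb):
                np.testing.assert_array_equal(ra, rb)

    def test_spike_times_sorted_within_window(self, noisy_spikes):
        for reps in noisy_spikes.trains:
            for times in reps:
                assert np.all(np.diff(times) >= 0)
                assert np.all((times >= 0) & (times < noisy_spikes.trial_length))


class TestMeanFiringRates:
    def test_rate_arithmetic_from_known_counts(self):
        # 6 contrasts, 2 s trials, 10 repetitions: rate = total / (2 * 10)
        contrasts = np.array([0.0, 10, 20, 40, 70, 100])
        trains = [
            [np.linspace(0.0, 1.9, k, endpoint=True) for _ in range(10)]
            for k in [2, 4, 8, 12, 16, 20]
        ]
        spikes = SpikeTrainSet(contrasts, 2.0, 10, trains)
        pts = mean_firing_rates(spikes)
        np.testing.assert_allclose(pts.mean_rates, np.array([2, 4, 8, 12, 16, 20]) / 2.0)
        np.testing.assert_allclose(pts.rate_sds, 0.0)

    def test_empty_spikes_zero_rates(self):
        trains = [[np.array([]) for _ in range(3)] for _ in range(4)]
        spikes = SpikeTrainSet(np.array([0.0, 10, 50, 100]), 2.0, 3, trains)
        np.testing.assert_allclose(mean_firing_rates(spikes).mean_rates, 0.0)

    def test_half_window_same_expected_rate(self, flat10):
        protocol = StimulusProtocol(contrasts=(60.0,), trial_length=2.0, n_repetitions=2000)
        spikes = simulate_experiment(flat10, protocol, seed=3)
        full = mean_firing_rates(spikes).mean_rates[0]
        half = mean_firing_rates(spikes, window=1.0).mean_rates[0]
        se = np.sqrt(10.0 / (1.0 * 2000))
        assert abs(half - full) < 4 * se

    def test_bad_window_rejected(self, noisy_spikes):
        with pytest.raises(ValueError):
            mean_firing_rates(noisy_spikes, window=0.0)
        with pytest.raises(ValueError):
            noisy_spikes.counts(window=noisy_spikes.trial_length + 1)


class TestPSTH:
    def test_flat_for_constant_rate(self, flat10):
        protocol = StimulusProtocol(contrasts=(90.0,), trial_length=2.0, n_repetitions=500)
        spikes = simulate_experiment(flat10, protocol, seed=4)
        h = psth(spikes, bin_width=0.25)[90.0]
        # each bin estimates 10 sp/s from 500 reps * 0.25 s
        se = np.sqrt(10.0 / (500 * 0.25))
        assert np.all(np.abs(h - 10.0) < 5 * se)

    def test_count_conservation(self, noisy_spikes):
        h = psth(noisy_spikes, bin_width=0.1)
        total = h.to_numpy().sum() * 0.1 * noisy_spikes.n_repetitions
        assert total == pytest.approx(noisy_spikes.total_spikes())

    def test_adaptation_yields_decreasing_psth(self, flat10):
        from crfdk import AdaptationSpec

        profile = AdaptationSpec(tau=0.5, floor=0.2).profile
        protocol = StimulusProtocol(contrasts=(100.0,), trial_length=2.0, n_repetitions=800)
        spikes = simulate_experiment(flat10, protocol, seed=5, rate_profile=profile)
        h = psth(spikes, bin_width=0.5)[100.0].to_numpy()
        assert np.all(np.diff(h) < 0)

    def test_bad_bin_rejected(self, noisy_spikes):
        with pytest.raises(ValueError):
            psth(noisy_spikes, bin_width=0.0)
        with pytest.raises(ValueError):
            psth(noisy_spikes, bin_width=0.73)


class TestSpikeTable:
    def test_round_trip(self, noisy_spikes):
        table = noisy_spikes.to_table(unit_id=3, direction_deg=30.0)
        assert set(table.columns) == {
            "unit_id", "direction_deg", "contrast_pct", "trial_idx", "spike_time_s",
        }
        back = SpikeTrainSet.from_table(
            table,
            trial_length=noisy_spikes.trial_length,
            n_repetitions=noisy_spikes.n_repetitions,
            contrasts=noisy_spikes.contrasts,
        )
        assert back.total_spikes() == noisy_spikes.total_spikes()
        for ta, tb in zip(noisy_spikes.trains, back.trains):
            for ra, rb in zip(ta, tb):
                np.testing.assert_allclose(ra, rb)
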
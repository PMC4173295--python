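"""Monitoring statistics: histogram, Omega, phi, k(tau)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gammaring.metrics import (MetricsConfig, compute_metrics,
                               mean_firing_rate, oscillation_frequency,
                               population_histogram, sync_coefficient)
from gammaring.simulator import SpikeData

from conftest import random_spike_data


def periodic_raster(n_cells=200, period=50.0, run_length=1000.0, jitter=0.0,
                    seed=0, phase=None):
    """In-phase volleys every `period` ms with optional Gaussian jitter.
    `phase` defaults to period/2; pick a value away from multiples of
    the k(tau) bin width to keep volleys inside single bins."""
    rng = np.random.default_rng(seed)
    trains = []
    base = np.arange(period / 2 if phase is None else phase, run_length,
                     period)
    for _ in range(n_cells):
        t = base + (jitter * rng.standard_normal(base.size) if jitter else 0.0)
        trains.append(np.unique(np.clip(t, 0.0, run_length - 1e-6)))
    return SpikeData(n_cells=n_cells, run_length=run_length,
                     trains=tuple(trains))


class TestHistogram:
    def test_empty_raster_gives_zero_series(self):
        spk = SpikeData(2, 1000.0, (np.empty(0), np.empty(0)))
        counts, _ = population_histogram(spk, (0.0, 1000.0), 1.0)
        assert counts.sum() == 0

    def test_counts_conserve_total_spikes(self):
        spk = random_spike_data(20, 1000.0, 30.0, seed=1)
        counts, _ = population_histogram(spk, (0.0, 1000.0), 1.0)
        assert counts.sum() == spk.n_spikes

    def test_in_phase_raster_has_periodic_peaks(self):
        counts, _ = population_histogram(periodic_raster(), (0.0, 1000.0), 1.0)
        peaks = np.nonzero(counts == 200)[0]
        assert len(peaks) == 20
        assert np.all(np.diff(peaks) == 50)

    def test_empty_window_rejected(self):
        spk = random_spike_data(2, 100.0, 10.0, seed=0)
        with pytest.raises(ValueError):
            population_histogram(spk, (50.0, 50.0), 1.0)


class TestOscillationFrequency:
    def test_periodic_raster_recovers_20_hz(self):
        counts, _ = population_histogram(periodic_raster(), (0.0, 1000.0), 1.0)
        assert oscillation_frequency(counts, 1.0) == pytest.approx(20.0, abs=1.0)

    def test_sinusoidally_modulated_poisson_recovers_20_hz(self):
        rng = np.random.default_rng(0)
        t = np.arange(1000)
        lam = 20.0 * (1.0 + 0.8 * np.sin(2 * np.pi * 20.0 * t / 1000.0))
        series = rng.poisson(lam)
        assert oscillation_frequency(series, 1.0) == pytest.approx(20.0, abs=1.0)

    def test_flat_series_rejected(self):
        with pytest.raises(ValueError):
            oscillation_frequency(np.zeros(1000), 1.0)
        with pytest.raises(ValueError):
            oscillation_frequency(np.full(1000, 7.0), 1.0)

    def test_white_noise_has_low_spectral_contrast(self):
        rng = np.random.default_rng(1)
        noise = rng.poisson(20.0, size=1000).astype(float)
        _, c_noise = oscillation_frequency(noise, 1.0, return_contrast=True)
        counts, _ = population_histogram(periodic_raster(jitter=2.0, seed=2),
                                         (0.0, 1000.0), 1.0)
        _, c_signal = oscillation_frequency(counts, 1.0, return_contrast=True)
        assert c_signal > 10 * c_noise

    def test_band_limit_excludes_out_of_band_peak(self):
        t = np.arange(1000)
        series = (10.0 * np.sin(2 * np.pi * 150.0 * t / 1000.0)
                  + 4.0 * np.sin(2 * np.pi * 20.0 * t / 1000.0))
        assert oscillation_frequency(series, 1.0) == pytest.approx(150.0)
        assert oscillation_frequency(series, 1.0,
                                     band=(2.0, 100.0)) == pytest.approx(20.0)


class TestMeanFiringRate:
    def test_empty_raster(self):
        spk = SpikeData(200, 1000.0, tuple(np.empty(0) for _ in range(200)))
        phi, rates, n_silent = mean_firing_rate(spk, (0.0, 1000.0))
        assert phi == 0.0 and n_silent == 200

    def test_uniform_rate(self):
        spk = periodic_raster()  # 20 spikes per cell per second
        phi, rates, n_silent = mean_firing_rate(spk, (0.0, 1000.0))
        assert phi == pytest.approx(20.0)
        assert n_silent == 0

    def test_removing_one_cell_lowers_phi_linearly(self):
        spk = random_spike_data(10, 1000.0, 30.0, seed=3)
        phi, rates, _ = mean_firing_rate(spk, (0.0, 1000.0))
        trains = list(spk.trains)
        removed = trains[4].size
        trains[4] = np.empty(0)
        spk2 = SpikeData(10, 1000.0, tuple(trains))
        phi2, _, _ = mean_firing_rate(spk2, (0.0, 1000.0))
        assert phi - phi2 == pytest.approx(removed / 10.0, abs=1e-12)


def brute_force_k(spikes, omega, window, tau_fraction=0.1):
    """Naive double-loop oracle for the pairwise coincidence measure."""
    t0, t1 = window
    tau = 1000.0 * tau_fraction / omega
    n_bins = int((t1 - t0) / tau)
    binary = []
    for tr in spikes.trains:
        b = np.zeros(n_bins)
        for x in tr:
            m = int((x - t0) / tau)
            if 0 <= m < n_bins:
                b[m] = 1.0
        binary.append(b)
    vals = []
    for i in range(spikes.n_cells):
        for j in range(i + 1, spikes.n_cells):
            X, Y = binary[i], binary[j]
            sx, sy = X.sum(), Y.sum()
            if sx > 0 and sy > 0:
                vals.append((X * Y).sum() / np.sqrt(sx * sy))
    return float(np.mean(vals)) if vals else float("nan")


class TestSyncCoefficient:
    def test_identical_trains_give_unity(self):
        tr = np.sort(1000.0 * np.random.default_rng(0).random(40))
        spk = SpikeData(3, 1000.0, (tr.copy(), tr.copy(), tr.copy()))
        k, K, _ = sync_coefficient(spk, 20.0, (0.0, 1000.0))
        assert k == pytest.approx(1.0)

    def test_disjoint_trains_give_zero(self):
        a = np.arange(10.0, 500.0, 25.0)
        b = np.arange(510.0, 990.0, 25.0)
        spk = SpikeData(2, 1000.0, (a, b))
        k, _, _ = sync_coefficient(spk, 20.0, (0.0, 1000.0))
        assert k == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        spk = random_spike_data(8, 1000.0, 25.0, seed=seed)
        k, _, _ = sync_coefficient(spk, 20.0, (0.0, 1000.0))
        assert k == pytest.approx(brute_force_k(spk, 20.0, (0.0, 1000.0)),
                                  abs=1e-14)

    def test_independent_bernoulli_expectation(self):
        # p=0.5, N=1000 bins -> E[k] ~ 0.5
        rng = np.random.default_rng(5)
        n_bins, tau = 1000, 1.0
        trains = []
        for _ in range(10):
            occupied = np.nonzero(rng.random(n_bins) < 0.5)[0]
            trains.append(occupied * tau + tau / 2)
        spk = SpikeData(10, 1000.0, tuple(t.astype(float) for t in trains))
        # tau = 1 ms corresponds to tau_fraction 0.1 at omega = 100 Hz
        k, _, _ = sync_coefficient(spk, 100.0, (0.0, 1000.0))
        assert k == pytest.approx(0.5, abs=0.03)

    def test_silent_pairs_excluded(self):
        a = np.arange(10.0, 990.0, 25.0)
        spk = SpikeData(3, 1000.0, (a, np.empty(0), a.copy()))
        k, K, n_excl = sync_coefficient(spk, 20.0, (0.0, 1000.0))
        assert n_excl == 2
        assert k == pytest.approx(1.0)

    def test_relabelling_invariance(self):
        spk = random_spike_data(6, 1000.0, 25.0, seed=9)
        k1, _, _ = sync_coefficient(spk, 20.0, (0.0, 1000.0))
        perm = [3, 1, 5, 0, 4, 2]
        spk2 = SpikeData(6, 1000.0, tuple(spk.trains[i] for i in perm))
        k2, _, _ = sync_coefficient(spk2, 20.0, (0.0, 1000.0))
        assert k1 == pytest.approx(k2, abs=1e-14)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), rate=st.floats(5.0, 80.0),
           omega=st.floats(5.0, 60.0))
    def test_bounds_always_hold(self, seed, rate, omega):
        spk = random_spike_data(5, 800.0, rate, seed=seed)
        k, K, _ = sync_coefficient(spk, omega, (0.0, 800.0))
        if not np.isnan(k):
            assert 0.0 <= k <= 1.0
        finite = K[~np.isnan(K)]
        assert np.all((finite >= 0.0) & (finite <= 1.0 + 1e-12))


def test_compute_metrics_on_synthetic_synchronous_raster():
    # volleys centred inside the 5 ms coincidence bins (tau = 0.1/20 Hz)
    spk = periodic_raster(jitter=1.0, seed=4, phase=27.5)
    m = compute_metrics(spk, MetricsConfig(analysis_window=(0.0, 1000.0)))
    assert m.omega == pytest.approx(20.0, abs=1.0)
    assert m.phi == pytest.approx(20.0, rel=0.05)
    assert m.k_tau > 0.7
    assert m.n_silent == 0


def test_compute_metrics_handles_empty_raster():
    spk = SpikeData(5, 1000.0, tuple(np.empty(0) for _ in range(5)))
    m = compute_metrics(spk, MetricsConfig(analysis_window=(0.0, 1000.0)))
    assert np.isnan(m.omega) and m.phi == 0.0 and m.n_silent == 5
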
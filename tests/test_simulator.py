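"""Network integration: determinism, delays, physiological sanity."""

import numpy as np
import pytest
from dataclasses import replace

from gammaring import _kernel
from gammaring.metrics import (MetricsConfig, compute_metrics,
                               population_histogram, sync_coefficient)
from gammaring.simulator import (RunConfig, SpikeData, derive_subseeds,
                                 load_spikes, run, save_spikes, save_voltage)
from gammaring.synapses import GABA_DEFAULT, EPSC_DEFAULT, SynapseParams

from conftest import random_spike_data


def test_zero_drive_zero_gaba_means_no_spikes(small_ring_config):
    cfg = small_ring_config(
        run_length=300.0, warmup=0.0,
        gaba=replace(GABA_DEFAULT, peak_conductance=0.0))
    cfg = replace(cfg, drive=replace(cfg.drive, base_frequency=0.0))
    res = run(cfg)
    assert res.spikes.n_spikes == 0


def test_identical_seeds_give_identical_output(small_ring_config, tmp_path):
    cfg = small_ring_config(run_length=400.0, master_seed=7)
    a, b = run(cfg), run(cfg)
    assert all(np.array_equal(x, y)
               for x, y in zip(a.spikes.trains, b.spikes.trains))
    save_spikes(a.spikes, tmp_path / "a.tsv")
    save_spikes(b.spikes, tmp_path / "b.tsv")
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_different_seeds_differ(small_ring_config):
    a = run(small_ring_config(run_length=400.0, master_seed=1))
    b = run(small_ring_config(run_length=400.0, master_seed=2))
    assert any(not np.array_equal(x, y)
               for x, y in zip(a.spikes.trains, b.spikes.trains))


def test_subseed_derivation_is_stable_and_bounded():
    s = derive_subseeds(123)
    assert s == derive_subseeds(123)
    assert set(s) == {"topology", "drive", "protocol"}
    assert all(0 <= v < 2 ** 31 for v in s.values())
    assert derive_subseeds(124) != s


def test_single_spike_delivered_after_edge_delay():
    """Two-cell toy network, event-queue oracle: the postsynaptic
    conductance starts to act exactly one edge delay after the
    presynaptic spike."""
    from gammaring.cell import CellParams, steady_state
    dt = 0.01
    n_steps = 3000
    delay_ms = 3.0
    p = CellParams()
    tabs = _kernel.build_gating_tables(dt, p.gating_rate_scale)
    st0 = steady_state(p, -65.0)
    v = np.array([-65.0, -65.0])
    h = np.full(2, float(st0.gating[0]))
    n_g = np.full(2, float(st0.gating[1]))
    zeros = lambda: np.zeros(2)
    # drive: a burst of strong EPSC events onto cell 0 only, at 5 ms
    ev_cell = np.zeros(40, dtype=np.int64)
    ev_step = np.full(40, 500, dtype=np.int64)
    step_start = np.searchsorted(ev_step, np.arange(n_steps + 1)).astype(np.int64)
    # one edge 0 -> 1 with 3 ms delay; hyperpolarizing reversal so the
    # postsynaptic deflection is visible in voltage
    out_ptr = np.array([0, 1, 1], dtype=np.int64)
    out_post = np.array([1], dtype=np.int64)
    out_delay = np.array([int(round(delay_ms / dt))], dtype=np.int64)
    L = out_delay[0] + 1
    inh_buf = np.zeros((L, 2))
    spike_cell = np.empty(1000, dtype=np.int64)
    spike_step = np.empty(1000, dtype=np.int64)
    last_spike = np.full(2, -10 ** 9, dtype=np.int64)
    v_rec = np.empty((n_steps, 2))
    import math
    g = GABA_DEFAULT
    e = EPSC_DEFAULT
    n_spk, status = _kernel.integrate(
        n_steps, dt, v, h, n_g, *tabs,
        p.specific_capacitance, p.na_conductance, p.na_reversal,
        p.k_conductance, p.k_reversal, p.leak_conductance, p.leak_reversal,
        zeros(), zeros(), e.reversal,
        zeros(), zeros(), -80.0,   # hyperpolarizing for visibility
        math.exp(-dt / e.tau_rise), math.exp(-dt / e.tau_decay),
        math.exp(-dt / g.tau_rise), math.exp(-dt / g.tau_decay),
        1e-6 / p.area_cm2,
        ev_cell, step_start, 3.0 * e.norm,
        out_ptr, out_post, out_delay, 5.0 * g.norm,
        inh_buf, int(round(2.0 / dt)),
        spike_cell, spike_step, last_spike, v_rec, 1)
    assert status == _kernel.STATUS_OK
    assert n_spk >= 1 and np.all(spike_cell[:n_spk] == 0)
    t_spike = spike_step[0] * dt  # first presynaptic spike
    v1 = v_rec[:, 1]
    moved = np.nonzero(np.abs(v1 - (-65.0)) > 1e-9)[0]
    assert moved.size > 0
    onset_ms = moved[0] * dt
    expected = t_spike + delay_ms
    # conductance is zero at the arrival instant and acts from the next
    # step onward
    assert expected <= onset_ms <= expected + 3 * dt


def test_no_inhibition_sits_at_independent_poisson_floor():
    """Removing GABA leaves only the stochastic drive: pairwise
    synchrony equals that of independent Poisson trains with matched
    rates, while the inhibited network sits clearly above its floor."""
    window = (300.0, 1100.0)
    mc = MetricsConfig(analysis_window=window)

    def floor_ratio(res):
        m = compute_metrics(res.spikes, mc)
        rng = np.random.default_rng(0)
        ks = []
        for s in range(3):
            trains = []
            for r in m.per_cell_rates:
                n = rng.poisson(r * (window[1] - window[0]) / 1000.0)
                trains.append(np.unique(np.sort(
                    window[0] + (window[1] - window[0]) * rng.random(n))))
            surr = SpikeData(res.spikes.n_cells, res.spikes.run_length,
                             tuple(trains))
            ks.append(sync_coefficient(surr, m.omega, window)[0])
        return m.k_tau / np.mean(ks)

    base = run(RunConfig(run_length=1100.0, master_seed=3))
    nogaba = run(RunConfig(
        run_length=1100.0, master_seed=3,
        gaba=replace(GABA_DEFAULT, peak_conductance=0.0)))
    assert floor_ratio(nogaba) < 1.25
    assert floor_ratio(base) > 1.3


def test_voltage_snapshots(small_ring_config):
    cfg = small_ring_config(run_length=600.0, record_voltage=True,
                            voltage_stride=1.0, master_seed=2)
    res = run(cfg)
    snap0 = res.population_voltage_snapshot(0.0)
    assert np.allclose(snap0, -65.0)
    assert np.all(np.isfinite(res.voltage))
    assert res.voltage.min() > -90.0 and res.voltage.max() < 60.0
    with pytest.raises(ValueError):
        res.population_voltage_snapshot(1e9)
    # depolarization clusters in time (population spikes): the most
    # depolarized snapshot holds several times the average share of
    # cells above -40 mV
    fracs = np.mean(res.voltage > -40.0, axis=1)
    assert fracs.max() >= 2.0 * fracs.mean()


def test_snapshot_requires_recording(small_ring_config):
    res = run(small_ring_config(run_length=300.0))
    with pytest.raises(ValueError):
        res.population_voltage_snapshot(100.0)
    with pytest.raises(ValueError):
        save_voltage(res, "/dev/null")


def test_voltage_trace_export(small_ring_config, tmp_path):
    res = run(small_ring_config(run_length=300.0, record_voltage=True,
                                voltage_stride=5.0, master_seed=1))
    path = tmp_path / "v.tsv"
    save_voltage(res, path)
    back = np.loadtxt(path, skiprows=1)
    assert back.shape == (res.voltage.shape[0], res.voltage.shape[1] + 1)
    assert np.allclose(back[:, 1:], res.voltage, atol=1e-4)


def test_spike_tsv_roundtrip(small_ring_config, tmp_path):
    res = run(small_ring_config(run_length=400.0, master_seed=5))
    path = tmp_path / "spikes.tsv"
    save_spikes(res.spikes, path)
    back = load_spikes(path)
    assert back.n_cells == res.spikes.n_cells
    for a, b in zip(back.trains, res.spikes.trains):
        assert np.allclose(a, b, atol=5e-7)


def test_invalid_run_config_rejected():
    with pytest.raises(ValueError):
        RunConfig(dt=0.0)
    with pytest.raises(ValueError):
        RunConfig(run_length=100.0, warmup=100.0)


def test_spike_trains_strictly_increasing_and_in_range(small_ring_config):
    res = run(small_ring_config(run_length=500.0, master_seed=11))
    assert res.spikes.n_spikes > 0
    for tr in res.spikes.trains:
        if tr.size:
            assert np.all(np.diff(tr) > 0)
            assert tr[0] >= 0 and tr[-1] <= 500.0
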
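"""Fixed-step integration kernel for the delayed ring network.

All cells share one parameter set; each cell carries (v, h, n) plus two
lumped dual-exponential synapse state pairs (excitatory drive, GABA).
Voltage-dependent gating quantities are read from dense lookup tables
(0.01 mV grid, linear interpolation) built once per run, which keeps the
inner loop free of transcendental calls; the table spacing contributes
errors orders of magnitude below the integration error at dt = 0.01 ms.

Presynaptic spikes are queued in a ring buffer of per-step delivery
weights, so a spike of cell i at step s adds to the GABA state of each
target exactly delay/dt steps later (delays are pre-rounded to the grid).

The kernel is deterministic: identical inputs give bit-identical output.
Compiled with numba when available; the pure-Python path is only
practical for the tiny networks used in unit tests.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_SPIKE_OVERFLOW = 2

TABLE_V_MIN = -120.0
TABLE_V_MAX = 80.0
TABLE_DV = 0.01


def build_gating_tables(dt: float, phi: float):
    """Lookup tables (m_inf, h_inf, h step factor, n_inf, n step factor).

    The step factors are exp(-(dt/2) * phi * (alpha + beta)), the exact
    exponential decay toward the steady state over HALF a step: the
    integrator applies the gating update twice per step (Strang
    splitting around the Heun voltage update).
    """
    v = np.arange(TABLE_V_MIN, TABLE_V_MAX + TABLE_DV / 2, TABLE_DV)
    x = v + 35.0
    am = np.where(np.abs(x) < 1e-7, 1.0, 0.1 * x / (1.0 - np.exp(-x / 10.0)))
    bm = 4.0 * np.exp(-(v + 60.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 28.0) / 10.0))
    xn = v + 34.0
    an = np.where(np.abs(xn) < 1e-7, 0.1,
                  0.01 * xn / (1.0 - np.exp(-xn / 10.0)))
    bn = 0.125 * np.exp(-(v + 44.0) / 80.0)
    return (am / (am + bm),
            ah / (ah + bh), np.exp(-0.5 * dt * phi * (ah + bh)),
            an / (an + bn), np.exp(-0.5 * dt * phi * (an + bn)))


@njit(cache=True)
def _interp(tab, v):
    pos = (v - TABLE_V_MIN) / TABLE_DV
    if pos <= 0.0:
        return tab[0]
    if pos >= len(tab) - 1:
        return tab[len(tab) - 1]
    k = int(pos)
    f = pos - k
    return tab[k] * (1.0 - f) + tab[k + 1] * f


@njit(cache=True)
def integrate(n_steps, dt,
              v, h, n,                       # (n_cells,) state, in place
              minf_tab, hinf_tab, hdec_tab, ninf_tab, ndec_tab,
              cm, gna, ena, gk, ek, gl, el,
              exc_rise, exc_fall, e_exc,     # (n_cells,) lumped EPSC state
              inh_rise, inh_fall, e_inh,     # (n_cells,) lumped GABA state
              exc_dec_r, exc_dec_f, inh_dec_r, inh_dec_f,  # scalars
              ns_to_density,                 # 1e-6 / area_cm2
              ev_cell, step_start, w_exc_inc,  # drive events grouped by step
              out_ptr, out_post, out_delay_steps, w_inh_inc,  # CSR topology
              inh_buf,                       # (L, n_cells) delivery queue
              refrac_steps,
              spike_cell, spike_step, last_spike,
              v_record, record_stride):
    n_cells = v.shape[0]
    L = inh_buf.shape[0]
    n_spikes = 0
    max_spikes = spike_cell.shape[0]
    for s in range(n_steps):
        if record_stride > 0 and s % record_stride == 0:
            r0 = s // record_stride
            for i in range(n_cells):
                v_record[r0, i] = v[i]
        # deliver queued GABA events due this step
        row = s % L
        for i in range(n_cells):
            w = inh_buf[row, i]
            if w != 0.0:
                inh_rise[i] += w
                inh_fall[i] += w
                inh_buf[row, i] = 0.0
        # deliver drive events due this step
        for p in range(step_start[s], step_start[s + 1]):
            c = ev_cell[p]
            exc_rise[c] += w_exc_inc
            exc_fall[c] += w_exc_inc
        # advance cells: half-step gating, Heun voltage, half-step gating
        for i in range(n_cells):
            vi = v[i]
            g_e = (exc_fall[i] - exc_rise[i]) * ns_to_density
            g_i = (inh_fall[i] - inh_rise[i]) * ns_to_density
            hs = _interp(hinf_tab, vi)
            hi = hs + (h[i] - hs) * _interp(hdec_tab, vi)
            ns_ = _interp(ninf_tab, vi)
            ni = ns_ + (n[i] - ns_) * _interp(ndec_tab, vi)

            mi = _interp(minf_tab, vi)
            n4 = ni * ni * ni * ni
            k1 = (-(gna * mi * mi * mi * hi * (vi - ena)
                    + gk * n4 * (vi - ek) + gl * (vi - el))
                  - g_e * (vi - e_exc) - g_i * (vi - e_inh)) / cm
            vp = vi + dt * k1
            mp = _interp(minf_tab, vp)
            k2 = (-(gna * mp * mp * mp * hi * (vp - ena)
                    + gk * n4 * (vp - ek) + gl * (vp - el))
                  - g_e * (vp - e_exc) - g_i * (vp - e_inh)) / cm
            v_new = vi + dt * 0.5 * (k1 + k2)
            if not np.isfinite(v_new) or v_new > 200.0 or v_new < -200.0:
                return n_spikes, STATUS_BLOWUP
            hs2 = _interp(hinf_tab, v_new)
            h[i] = hs2 + (hi - hs2) * _interp(hdec_tab, v_new)
            ns2 = _interp(ninf_tab, v_new)
            n[i] = ns2 + (ni - ns2) * _interp(ndec_tab, v_new)
            # spike: upward crossing of 0 mV with refractory lockout
            if v_new >= 0.0 and vi < 0.0 and (s + 1 - last_spike[i]) > refrac_steps:
                last_spike[i] = s + 1
                if n_spikes >= max_spikes:
                    return n_spikes, STATUS_SPIKE_OVERFLOW
                spike_cell[n_spikes] = i
                spike_step[n_spikes] = s + 1
                n_spikes += 1
                for e in range(out_ptr[i], out_ptr[i + 1]):
                    tgt = (s + 1 + out_delay_steps[e]) % L
                    inh_buf[tgt, out_post[e]] += w_inh_inc
            v[i] = v_new
        # synaptic decay over the step (exact)
        for i in range(n_cells):
            exc_rise[i] *= exc_dec_r
            exc_fall[i] *= exc_dec_f
            inh_rise[i] *= inh_dec_r
            inh_fall[i] *= inh_dec_f
    return n_spikes, STATUS_OK
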
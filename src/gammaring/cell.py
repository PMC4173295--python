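"""Single-compartment fast-spiking interneuron.

The cell is a cylinder (length = diameter = 62 um) with Hodgkin-Huxley
sodium and potassium currents using the classic fast-spiking basket-cell
kinetics of the Wang-Buzsaki lineage: instantaneous sodium activation
(m = m_inf(V)), inactivation h and delayed-rectifier activation n with a
gating rate scale factor phi = 5 that makes the kinetics fast enough for
high-frequency firing.  The leak reversal is calibrated so that the
resting potential is exactly -65 mV (the sodium/potassium window currents
would otherwise shift rest a little above the nominal leak reversal).

Units convention
----------------
voltage mV, time ms, specific conductance mS/cm^2, specific capacitance
uF/cm^2, current density uA/cm^2.  With these units dV/dt = -I/Cm comes
out directly in mV/ms.  Injected currents quoted in pA are converted to
densities through the membrane area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CellParams",
    "MembraneState",
    "MembraneRates",
    "steady_state",
    "derivatives",
    "ramp_threshold",
    "simulate_current_clamp",
    "NoThresholdError",
]

# Action-potential initiation on a current ramp is marked where dV/dt
# first exceeds this multiple of the passive quasi-static ramp slope
# (ramp_rate / input conductance), i.e. where the active inward current
# contributes three times the passive displacement.  For a type-I
# (saddle-node) neuron a fixed large dV/dt criterion would read out the
# spike upstroke, well above initiation; the slope-multiple criterion
# tracks the escape from the passive trajectory and is only weakly
# ramp-rate dependent.  Kept fixed; see docs/methods.md.
SPIKE_INITIATION_SLOPE_MULTIPLE = 4.0


class NoThresholdError(RuntimeError):
    """Raised when a ramp protocol produces no action potential."""


def _alpha_m(v: float) -> float:
    x = v + 35.0
    if abs(x) < 1e-9:
        return 1.0  # limit of 0.1*x/(1-exp(-x/10)) at x=0
    return 0.1 * x / (1.0 - math.exp(-x / 10.0))


def _beta_m(v: float) -> float:
    return 4.0 * math.exp(-(v + 60.0) / 18.0)


def _alpha_h(v: float) -> float:
    return 0.07 * math.exp(-(v + 58.0) / 20.0)


def _beta_h(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 28.0) / 10.0))


def _alpha_n(v: float) -> float:
    x = v + 34.0
    if abs(x) < 1e-9:
        return 0.1
    return 0.01 * x / (1.0 - math.exp(-x / 10.0))


def _beta_n(v: float) -> float:
    return 0.125 * math.exp(-(v + 44.0) / 80.0)


def m_inf(v: float) -> float:
    """Instantaneous sodium activation."""
    a = _alpha_m(v)
    return a / (a + _beta_m(v))


def h_inf(v: float) -> float:
    a = _alpha_h(v)
    return a / (a + _beta_h(v))


def n_inf(v: float) -> float:
    a = _alpha_n(v)
    return a / (a + _beta_n(v))


def _ionic_current_at_steady_gating(v: float, gna: float, ena: float,
                                    gk: float, ek: float) -> float:
    """Na + K current density with all gating at steady state for v."""
    ina = gna * m_inf(v) ** 3 * h_inf(v) * (v - ena)
    ik = gk * n_inf(v) ** 4 * (v - ek)
    return ina + ik


def _calibrate_leak_reversal(v_rest: float, gna: float, ena: float,
                             gk: float, ek: float, gl: float) -> float:
    """Leak reversal that makes v_rest an exact fixed point."""
    return v_rest + _ionic_current_at_steady_gating(v_rest, gna, ena, gk, ek) / gl


@dataclass(frozen=True)
class CellParams:
    """Passive and active properties of one basket cell.

    ``axial_resistance`` is carried for fidelity to the published cell
    geometry but has no effect on a single-compartment model.
    ``leak_reversal=None`` requests calibration such that
    ``resting_potential`` is an exact fixed point of the full dynamics.
    """

    length: float = 62.0                 # um
    diameter: float = 62.0               # um
    axial_resistance: float = 100.0      # ohm*cm (unused: single compartment)
    specific_capacitance: float = 1.0    # uF/cm^2
    resting_potential: float = -65.0     # mV
    leak_conductance: float = 0.1        # mS/cm^2
    leak_reversal: float | None = None   # mV; None -> calibrated
    na_conductance: float = 35.0         # mS/cm^2
    na_reversal: float = 55.0            # mV
    k_conductance: float = 9.0           # mS/cm^2
    k_reversal: float = -90.0            # mV
    gating_rate_scale: float = 5.0       # dimensionless phi

    def __post_init__(self) -> None:
        for name in ("leak_conductance", "na_conductance", "k_conductance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.leak_reversal is None:
            el = _calibrate_leak_reversal(
                self.resting_potential, self.na_conductance, self.na_reversal,
                self.k_conductance, self.k_reversal, self.leak_conductance)
            object.__setattr__(self, "leak_reversal", el)

    @property
    def area_cm2(self) -> float:
        """Lateral cylinder area pi*d*L (the convention of compartmental
        simulators: end caps are not counted)."""
        return math.pi * self.diameter * self.length * 1e-8  # um^2 -> cm^2

    def pa_to_density(self, i_pa: float) -> float:
        """Convert an injected current in pA to a density in uA/cm^2."""
        return i_pa * 1e-6 / self.area_cm2


@dataclass(frozen=True)
class MembraneState:
    """Voltage plus the non-instantaneous gating variables (h, n)."""

    v: float
    gating: np.ndarray  # (h, n)

    def __post_init__(self) -> None:
        g = np.asarray(self.gating, dtype=float)
        object.__setattr__(self, "gating", g)
        if not np.isfinite(self.v):
            raise ValueError("membrane voltage must be finite")
        if g.shape != (2,):
            raise ValueError("gating vector must be (h, n)")
        if np.any(g < -1e-12) or np.any(g > 1 + 1e-12):
            raise ValueError("gating variables must lie in [0, 1]")


@dataclass(frozen=True)
class MembraneRates:
    """Time derivatives of a MembraneState (dV/dt in mV/ms, gating in
    1/ms); unlike a state, gating entries may be negative."""

    v: float
    gating: np.ndarray


def steady_state(params: CellParams, v: float) -> MembraneState:
    """Membrane state with all gating at its steady value for voltage v."""
    if not np.isfinite(v):
        raise ValueError("v must be finite")
    return MembraneState(v=v, gating=np.array([h_inf(v), n_inf(v)]))


def derivatives(state: MembraneState, params: CellParams,
                syn_current: float = 0.0, t: float = 0.0) -> MembraneRates:
    """Time derivatives (dV/dt in mV/ms, dh/dt, dn/dt in 1/ms).

    ``syn_current`` is the total synaptic + injected current density in
    uA/cm^2 with the inward-positive sign convention (positive values
    depolarize).
    """
    v = state.v
    if not np.isfinite(v) or not np.all(np.isfinite(state.gating)):
        raise FloatingPointError("non-finite membrane state (numerical blow-up)")
    h, n = float(state.gating[0]), float(state.gating[1])
    p = params
    ina = p.na_conductance * m_inf(v) ** 3 * h * (v - p.na_reversal)
    ik = p.k_conductance * n ** 4 * (v - p.k_reversal)
    il = p.leak_conductance * (v - p.leak_reversal)
    dv = (-(ina + ik + il) + syn_current) / p.specific_capacitance
    phi = p.gating_rate_scale
    dh = phi * (_alpha_h(v) * (1.0 - h) - _beta_h(v) * h)
    dn = phi * (_alpha_n(v) * (1.0 - n) - _beta_n(v) * n)
    return MembraneRates(v=dv, gating=np.array([dh, dn]))


def _gate_half(v: float, h: float, n: float, phi: float,
               half_dt: float) -> tuple[float, float]:
    """Exponential gating update over half a step, rates frozen at v."""
    ah, bh = _alpha_h(v), _beta_h(v)
    an, bn = _alpha_n(v), _beta_n(v)
    h_ss = ah / (ah + bh)
    n_ss = an / (an + bn)
    h = h_ss + (h - h_ss) * math.exp(-half_dt * phi * (ah + bh))
    n = n_ss + (n - n_ss) * math.exp(-half_dt * phi * (an + bn))
    return h, n


def _step(v: float, h: float, n: float, p: CellParams, i_ext: float,
          dt: float) -> tuple[float, float, float]:
    """One fixed step: Strang splitting with exponential gating updates
    (half step before and after) and an explicit Heun update for the
    voltage using midpoint gating.  Second-order accurate; the same
    scheme is used by the network kernel."""
    phi = p.gating_rate_scale
    h, n = _gate_half(v, h, n, phi, dt / 2.0)

    def dv(vv: float) -> float:
        ina = p.na_conductance * m_inf(vv) ** 3 * h * (vv - p.na_reversal)
        ik = p.k_conductance * n ** 4 * (vv - p.k_reversal)
        il = p.leak_conductance * (vv - p.leak_reversal)
        return (-(ina + ik + il) + i_ext) / p.specific_capacitance

    k1 = dv(v)
    k2 = dv(v + dt * k1)
    v_new = v + dt * 0.5 * (k1 + k2)
    h, n = _gate_half(v_new, h, n, phi, dt / 2.0)
    return v_new, h, n


def simulate_current_clamp(params: CellParams, i_pa: np.ndarray, dt: float,
                           v0: float | None = None) -> np.ndarray:
    """Integrate a single cell under an injected current waveform.

    Parameters
    ----------
    i_pa : array of injected current in pA, one value per time step.
    dt : step in ms.
    v0 : initial voltage (gating initialized at steady state); defaults
        to the resting potential.

    Returns
    -------
    Voltage trace, same length as ``i_pa`` (voltage *before* each step's
    update, so ``trace[0] == v0``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v = params.resting_potential if v0 is None else v0
    st = steady_state(params, v)
    h, n = float(st.gating[0]), float(st.gating[1])
    i_dens = np.asarray(i_pa, dtype=float) * 1e-6 / params.area_cm2
    out = np.empty(len(i_dens))
    for k in range(len(i_dens)):
        out[k] = v
        v, h, n = _step(v, h, n, params, i_dens[k], dt)
        if not math.isfinite(v):
            raise FloatingPointError(f"voltage diverged at t={k * dt:.3f} ms")
    return out


def ramp_threshold(params: CellParams, ramp_rate: float = 1.0,
                   dt: float = 0.01, t_max: float = 200.0) -> float:
    """Spike-initiation voltage under a linearly increasing current.

    The cell starts at rest and receives I(t) = ramp_rate * t (pA).  The
    reported threshold is the voltage at the last sample before dV/dt
    first exceeds ``SPIKE_INITIATION_SLOPE_MULTIPLE`` times the passive
    quasi-static slope ramp_rate / g_input.

    Raises
    ------
    NoThresholdError
        if no spike initiates within ``t_max`` ms.
    """
    if ramp_rate <= 0:
        raise ValueError("ramp_rate must be positive")
    t = np.arange(0.0, t_max, dt)
    trace = simulate_current_clamp(params, ramp_rate * t, dt)
    dvdt = np.diff(trace) / dt
    g_input_ns = params.leak_conductance * params.area_cm2 * 1e6
    passive_slope = ramp_rate / g_input_ns  # mV/ms
    idx = np.nonzero(dvdt > SPIKE_INITIATION_SLOPE_MULTIPLE * passive_slope)[0]
    if idx.size == 0:
        raise NoThresholdError(
            f"no action potential within {t_max} ms at {ramp_rate} pA/ms")
    return float(trace[idx[0]])


def spike_times_from_trace(trace: np.ndarray, dt: float,
                           v_cross: float = 0.0,
                           refractory: float = 2.0) -> np.ndarray:
    """Spike times (ms) as upward crossings of ``v_cross`` with a
    refractory lockout.  Matches the network simulator's detector."""
    up = np.nonzero((trace[:-1] < v_cross) & (trace[1:] >= v_cross))[0] + 1
    times = up * dt
    if times.size == 0:
        return times
    kept = [times[0]]
    for tt in times[1:]:
        if tt - kept[-1] > refractory:
            kept.append(tt)
    return np.asarray(kept)


def f_i_curve(params: CellParams, currents_pa: np.ndarray, dt: float = 0.01,
              t_stop: float = 500.0, t_discard: float = 100.0) -> np.ndarray:
    """Firing rate (Hz) for each constant injected current (pA)."""
    rates = []
    n_steps = int(round(t_stop / dt))
    for i0 in np.asarray(currents_pa, dtype=float):
        trace = simulate_current_clamp(params, np.full(n_steps, i0), dt)
        st = spike_times_from_trace(trace, dt)
        st = st[st >= t_discard]
        rates.append(1000.0 * len(st) / (t_stop - t_discard))
    return np.asarray(rates)
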
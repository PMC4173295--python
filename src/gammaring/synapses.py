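"""Dual-exponential conductance synapses.

Both the GABAergic connections between basket cells and the glutamatergic
drive events use the same functional form: a difference of exponentials

    g(t) = Gm * N * (exp(-t/tau_decay) - exp(-t/tau_rise)),   t >= 0

with N chosen so the peak equals the configured maximal conductance Gm
(the ``Exp2Syn`` convention of compartmental simulators).  Because the
form is linear in events, all inputs to a cell that share kinetics can be
lumped into one pair of exponential state variables; events increment both
components and each component decays with its own time constant, which is
exact (no integration error in the synaptic states themselves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SynapseParams", "SynapseState", "waveform", "on_event",
           "decay", "conductance", "current",
           "GABA_DEFAULT", "EPSC_DEFAULT"]


@dataclass(frozen=True)
class SynapseParams:
    """Kinetics and strength of one synapse class."""

    tau_rise: float        # ms
    tau_decay: float       # ms
    peak_conductance: float  # nS per event
    reversal: float        # mV

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_rise < self.tau_decay):
            raise ValueError(
                "need 0 < tau_rise < tau_decay (equal time constants would "
                "be the degenerate alpha-function case, not supported)")
        if self.peak_conductance < 0:
            raise ValueError("peak_conductance must be >= 0")

    @property
    def t_peak(self) -> float:
        """Time to peak: (t1*t2/(t2-t1)) * ln(t2/t1)."""
        t1, t2 = self.tau_rise, self.tau_decay
        return t1 * t2 / (t2 - t1) * math.log(t2 / t1)

    @property
    def norm(self) -> float:
        """Factor N with N*(exp(-tp/t2) - exp(-tp/t1)) = 1."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_decay)
                      - math.exp(-tp / self.tau_rise))


# Default parameters of the two synapse classes.  GABA reverses at the
# resting potential (shunting inhibition).  The kinetics are fixed by
# the model family; the peak conductances (2 nS each) are calibration
# outputs frozen so the baseline network oscillates at 18 Hz under
# 300 Hz drive (see experiments.calibrate and docs/methods.md).
GABA_DEFAULT = SynapseParams(tau_rise=2.5, tau_decay=10.0,
                             peak_conductance=2.0, reversal=-65.0)
EPSC_DEFAULT = SynapseParams(tau_rise=0.5, tau_decay=5.0,
                             peak_conductance=2.0, reversal=0.0)


@dataclass
class SynapseState:
    """Lumped exponential components of one synapse class on one cell.

    ``rise`` and ``fall`` decay with tau_rise and tau_decay respectively;
    the instantaneous conductance is fall - rise (both already carry the
    peak normalization), which is >= 0 for any event history.
    """

    rise: float = 0.0  # nS
    fall: float = 0.0  # nS


def waveform(params: SynapseParams, t_since_event: float | np.ndarray) -> np.ndarray | float:
    """Conductance (nS) at time t after a single event."""
    t = np.asarray(t_since_event, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_event must be >= 0")
    g = params.peak_conductance * params.norm * (
        np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise))
    return float(g) if np.isscalar(t_since_event) else g


def on_event(state: SynapseState, params: SynapseParams,
             weight: float | None = None) -> SynapseState:
    """Register one presynaptic event; superposition-exact increment."""
    w = params.peak_conductance if weight is None else weight
    if w < 0:
        raise ValueError("weight must be >= 0")
    inc = w * params.norm
    return SynapseState(rise=state.rise + inc, fall=state.fall + inc)


def decay(state: SynapseState, params: SynapseParams, h: float) -> SynapseState:
    """Propagate the state over a step of length h ms (analytically exact)."""
    if h < 0:
        raise ValueError("h must be >= 0")
    return SynapseState(rise=state.rise * math.exp(-h / params.tau_rise),
                        fall=state.fall * math.exp(-h / params.tau_decay))


def conductance(state: SynapseState) -> float:
    """Instantaneous conductance in nS."""
    return state.fall - state.rise


def current(state: SynapseState, v: float, reversal: float,
            area_cm2: float) -> float:
    """Synaptic current density in uA/cm^2, inward-positive.

    Positive return values depolarize, so an excitatory synapse
    (reversal 0 mV) on a cell below 0 mV yields a positive current.
    """
    g_ns = conductance(state)
    return -g_ns * 1e-6 * (v - reversal) / area_cm2
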
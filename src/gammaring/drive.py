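"""Stochastic excitatory drive: the stand-in for the pyramidal-cell subnetwork.

Each basket cell normally hosts about 2000 excitatory synapses from
pyramidal neurons firing at 1-2 Hz with release probability 0.2-0.3,
which budgets to an EPSC barrage of several hundred Hz per cell.  The
model reduces that subnetwork to one independent Poisson event stream
per basket cell with a controllable, piecewise-constant rate (baseline
f0 = 300 Hz), feeding dual-exponential EPSC conductances
(tau_rise 0.5 ms, tau_decay 5 ms, reversal 0 mV).

This module is the synthetic-data generator of the package: rate
schedules define the study conditions and `generate_events` realizes
them as seeded inhomogeneous Poisson streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synapses import SynapseParams, EPSC_DEFAULT

__all__ = ["DriveConfig", "PyramidalBudget", "RateSchedule",
           "expected_rate", "generate_events"]


@dataclass(frozen=True)
class DriveConfig:
    base_frequency: float = 300.0       # Hz per cell (f0)
    epsc_params: SynapseParams = EPSC_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_frequency < 0:
            raise ValueError("base_frequency must be >= 0")


@dataclass(frozen=True)
class PyramidalBudget:
    """Bookkeeping for the EPSC rate implied by the pyramidal subnetwork."""

    n_synapses: int = 2000
    pyramidal_rate: float = 1.5         # Hz, plausible range 1-2
    release_probability: float = 0.25   # plausible range 0.2-0.3 (0-0.45 explored)

    def __post_init__(self) -> None:
        if self.n_synapses < 0:
            raise ValueError("n_synapses must be >= 0")
        if self.pyramidal_rate < 0:
            raise ValueError("pyramidal_rate must be >= 0")
        if not (0.0 <= self.release_probability <= 1.0):
            raise ValueError("release_probability must be in [0, 1]")


def expected_rate(budget: PyramidalBudget) -> float:
    """Expected EPSC barrage frequency (Hz) assuming all connections active."""
    return budget.n_synapses * budget.pyramidal_rate * budget.release_probability


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant per-cell rate functions over [0, run_length].

    ``segments[i]`` is a list of (t_start, t_end, rate_hz) covering the
    run without gaps or overlap for cell i.
    """

    n_cells: int
    run_length: float  # ms
    segments: tuple[tuple[tuple[float, float, float], ...], ...]

    def __post_init__(self) -> None:
        if len(self.segments) != self.n_cells:
            raise ValueError("one segment list per cell required")
        for i, segs in enumerate(self.segments):
            t = 0.0
            for (t0, t1, r) in segs:
                if abs(t0 - t) > 1e-9 or t1 <= t0:
                    raise ValueError(f"cell {i}: segments must tile the run")
                if r < 0:
                    raise ValueError("rates must be >= 0")
                t = t1
            if abs(t - self.run_length) > 1e-9:
                raise ValueError(f"cell {i}: segments must cover the run")

    @classmethod
    def constant(cls, n_cells: int, run_length: float, rate: float) -> "RateSchedule":
        seg = ((0.0, run_length, rate),)
        return cls(n_cells=n_cells, run_length=run_length,
                   segments=tuple(seg for _ in range(n_cells)))

    def rate_at(self, cell: int, t: float) -> float:
        for (t0, t1, r) in self.segments[cell]:
            if t0 <= t < t1:
                return r
        raise ValueError(f"t={t} outside run")

    def expected_count(self, cell: int) -> float:
        """Expected number of events for one cell over the whole run."""
        return sum(r * (t1 - t0) / 1000.0 for (t0, t1, r) in self.segments[cell])


def generate_events(schedule: RateSchedule, seed: int) -> list[np.ndarray]:
    """Per-cell sorted event times (ms) from independent Poisson streams.

    Each cell uses its own child of the seed sequence, so one cell's
    stream does not depend on another cell's schedule.  Within a cell
    the inhomogeneous stream is built by coupling to the cell's
    reference rate (its first segment): a homogeneous stream at the
    reference rate is drawn for the whole run, events are thinned with
    probability rate/reference inside reduced-rate segments, and an
    independent extra stream at (rate - reference) is superposed inside
    elevated segments.  This is an exact construction of the
    piecewise-homogeneous Poisson process, and it makes a rate step
    *pathwise* confined to its window: outside the stepped segments the
    realized events are identical to the unperturbed stream under the
    same seed — the property that lets paired conditions share their
    drive.
    """
    children = np.random.SeedSequence(seed).spawn(schedule.n_cells)
    out: list[np.ndarray] = []
    for i in range(schedule.n_cells):
        rng = np.random.default_rng(children[i])
        segs = schedule.segments[i]
        ref = segs[0][2]
        T = schedule.run_length
        base = np.empty(0)
        if ref > 0:
            n = rng.poisson(ref * T / 1000.0)
            base = T * np.sort(rng.random(n))
        pieces = []
        for (t0, t1, r) in segs:
            in_seg = base[(base >= t0) & (base < t1)]
            if r < ref:
                keep = rng.random(in_seg.size) < (r / ref if ref > 0 else 0.0)
                pieces.append(in_seg[keep])
            else:
                pieces.append(in_seg)
                if r > ref:
                    n_extra = rng.poisson((r - ref) * (t1 - t0) / 1000.0)
                    pieces.append(t0 + (t1 - t0) * np.sort(rng.random(n_extra)))
        out.append(np.sort(np.concatenate(pieces)) if pieces else np.empty(0))
    return out
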
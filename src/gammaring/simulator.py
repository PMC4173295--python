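"""Full network simulation: HH cells + delayed GABA ring + Poisson drive.

`run` assembles the pieces declared in a `RunConfig`, integrates with a
fixed step (default 0.01 ms), and returns per-cell spike trains.  The
master seed deterministically spawns independent sub-seeds for topology,
drive, and perturbation-target selection, so paired comparisons (e.g.
clustered vs random selection on the same network and drive) only need
to share the master seed.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _kernel
from .cell import CellParams, steady_state
from .drive import DriveConfig, RateSchedule, generate_events
from .network import TopologyConfig, NetworkTopology, build
from .perturbation import Protocol, AffectedSet, select, apply
from .synapses import SynapseParams, GABA_DEFAULT, EPSC_DEFAULT

__all__ = ["RunConfig", "SpikeData", "RunResult", "run", "derive_subseeds",
           "save_spikes", "load_spikes", "save_voltage", "SimulationError"]


class SimulationError(RuntimeError):
    """Numerical blow-up or resource overflow during integration."""


def derive_subseeds(master_seed: int) -> dict[str, int]:
    """Independent sub-seeds (< 2**31) for the three random components."""
    state = np.random.SeedSequence(master_seed).generate_state(3)
    names = ("topology", "drive", "protocol")
    return {k: int(s & 0x7FFFFFFF) for k, s in zip(names, state)}


@dataclass(frozen=True)
class RunConfig:
    dt: float = 0.01                 # ms
    run_length: float = 3500.0       # ms
    warmup: float = 500.0            # ms excluded from analysis
    record_voltage: bool = False
    voltage_stride: float = 1.0      # ms between recorded snapshots
    master_seed: int = 0
    cell: CellParams = field(default_factory=CellParams)
    gaba: SynapseParams = GABA_DEFAULT
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    drive: DriveConfig = field(default_factory=DriveConfig)
    protocol: Protocol | None = None
    refractory: float = 2.0          # ms spike-detector lockout
    max_rate_cap: float = 600.0      # Hz per cell, spike-buffer sizing

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (0 <= self.warmup < self.run_length):
            raise ValueError("need 0 <= warmup < run_length")

    def config_hash(self) -> str:
        def enc(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        blob = json.dumps(asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class SpikeData:
    """Per-cell strictly increasing spike times (ms) plus run metadata."""

    n_cells: int
    run_length: float
    trains: tuple[np.ndarray, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trains) != self.n_cells:
            raise ValueError("one train per cell required")
        for tr in self.trains:
            if tr.size and (np.any(np.diff(tr) <= 0) or tr[0] < 0
                            or tr[-1] > self.run_length):
                raise ValueError("trains must be strictly increasing within the run")

    @property
    def n_spikes(self) -> int:
        return int(sum(tr.size for tr in self.trains))

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(cell_index, time_ms) arrays sorted by time."""
        cells = np.concatenate([np.full(tr.size, i, dtype=np.int64)
                                for i, tr in enumerate(self.trains)]) \
            if self.n_spikes else np.empty(0, dtype=np.int64)
        times = np.concatenate([tr for tr in self.trains]) \
            if self.n_spikes else np.empty(0)
        order = np.argsort(times, kind="stable")
        return cells[order], times[order]


@dataclass(frozen=True)
class RunResult:
    spikes: SpikeData
    topology: NetworkTopology
    affected: AffectedSet | None
    schedule: RateSchedule
    voltage_times: np.ndarray | None = None   # ms
    voltage: np.ndarray | None = None         # (n_snapshots, n_cells)

    def population_voltage_snapshot(self, t: float) -> np.ndarray:
        """Per-cell voltages at the recorded snapshot nearest to t."""
        if self.voltage is None:
            raise ValueError("run was executed without voltage recording")
        if not (self.voltage_times[0] <= t <= self.voltage_times[-1]):
            raise ValueError(f"t={t} outside recorded range")
        k = int(np.argmin(np.abs(self.voltage_times - t)))
        return self.voltage[k].copy()


def _csr_topology(topo: NetworkTopology, dt: float):
    order = np.argsort(topo.pre, kind="stable")
    pre = topo.pre[order]
    post = topo.post[order].astype(np.int64)
    delay_steps = np.maximum(1, np.rint(topo.delay_ms[order] / dt)).astype(np.int64)
    ptr = np.zeros(topo.n_cells + 1, dtype=np.int64)
    np.add.at(ptr, pre + 1, 1)
    ptr = np.cumsum(ptr)
    return ptr, post, delay_steps


def run(config: RunConfig) -> RunResult:
    """Simulate one run; bit-reproducible for identical config."""
    seeds = derive_subseeds(config.master_seed)
    dt = config.dt
    n_steps = int(round(config.run_length / dt))
    n_cells = config.topology.n_cells

    topo_cfg = TopologyConfig(**{**asdict(config.topology),
                                 "seed": seeds["topology"]})
    topo = build(topo_cfg)

    if config.protocol is not None and config.protocol.n_affected > 0:
        prot = config.protocol
        affected = select(prot.mode, prot.n_affected, n_cells,
                          prot.n_clusters, seed=seeds["protocol"])
        schedule = apply(prot, affected, config.drive,
                         config.run_length, n_cells)
    else:
        affected = None
        schedule = RateSchedule.constant(n_cells, config.run_length,
                                         config.drive.base_frequency)
    events = generate_events(schedule, seeds["drive"])

    # drive events grouped by integration step
    ev_step = np.concatenate(
        [np.minimum((tr / dt).astype(np.int64), n_steps - 1) for tr in events]
    ) if any(tr.size for tr in events) else np.empty(0, dtype=np.int64)
    ev_cell = np.concatenate(
        [np.full(tr.size, i, dtype=np.int64) for i, tr in enumerate(events)]
    ) if ev_step.size else np.empty(0, dtype=np.int64)
    order = np.argsort(ev_step, kind="stable")
    ev_step, ev_cell = ev_step[order], ev_cell[order]
    step_start = np.searchsorted(ev_step, np.arange(n_steps + 1)).astype(np.int64)

    p = config.cell
    epsc = config.drive.epsc_params
    gaba = config.gaba
    tabs = _kernel.build_gating_tables(dt, p.gating_rate_scale)

    st0 = steady_state(p, p.resting_potential)
    v = np.full(n_cells, p.resting_potential)
    h = np.full(n_cells, float(st0.gating[0]))
    n_gate = np.full(n_cells, float(st0.gating[1]))
    exc_rise = np.zeros(n_cells)
    exc_fall = np.zeros(n_cells)
    inh_rise = np.zeros(n_cells)
    inh_fall = np.zeros(n_cells)

    out_ptr, out_post, out_delay = _csr_topology(topo, dt)
    L = int(out_delay.max()) + 1 if out_delay.size else 1
    inh_buf = np.zeros((L, n_cells))

    max_spikes = int(config.max_rate_cap * n_cells
                     * config.run_length / 1000.0) + 1000
    spike_cell = np.empty(max_spikes, dtype=np.int64)
    spike_step = np.empty(max_spikes, dtype=np.int64)
    last_spike = np.full(n_cells, -(10 ** 9), dtype=np.int64)

    if config.record_voltage:
        stride = max(1, int(round(config.voltage_stride / dt)))
        n_rec = (n_steps - 1) // stride + 1
        v_record = np.empty((n_rec, n_cells))
    else:
        stride = 0
        v_record = np.empty((1, n_cells))

    n_spk, status = _kernel.integrate(
        n_steps, dt, v, h, n_gate,
        *tabs,
        p.specific_capacitance, p.na_conductance, p.na_reversal,
        p.k_conductance, p.k_reversal, p.leak_conductance, p.leak_reversal,
        exc_rise, exc_fall, epsc.reversal,
        inh_rise, inh_fall, gaba.reversal,
        math.exp(-dt / epsc.tau_rise), math.exp(-dt / epsc.tau_decay),
        math.exp(-dt / gaba.tau_rise), math.exp(-dt / gaba.tau_decay),
        1e-6 / p.area_cm2,
        ev_cell, step_start, epsc.peak_conductance * epsc.norm,
        out_ptr, out_post, out_delay, gaba.peak_conductance * gaba.norm,
        inh_buf, int(round(config.refractory / dt)),
        spike_cell, spike_step, last_spike,
        v_record, stride)

    if status == _kernel.STATUS_BLOWUP:
        raise SimulationError(
            "non-finite or out-of-range voltage: numerical blow-up "
            f"(config hash {config.config_hash()})")
    if status == _kernel.STATUS_SPIKE_OVERFLOW:
        raise SimulationError("spike buffer overflow: network firing "
                              f"exceeds {config.max_rate_cap} Hz/cell cap")

    sc, ss = spike_cell[:n_spk], spike_step[:n_spk]
    trains = tuple(np.sort(ss[sc == i]) * dt for i in range(n_cells))
    meta = {"config_hash": config.config_hash(),
            "master_seed": config.master_seed, **{f"seed_{k}": v_
                                                  for k, v_ in seeds.items()}}
    spikes = SpikeData(n_cells=n_cells, run_length=config.run_length,
                       trains=trains, meta=meta)
    vt = np.arange(v_record.shape[0]) * stride * dt if stride else None
    return RunResult(spikes=spikes, topology=topo, affected=affected,
                     schedule=schedule,
                     voltage_times=vt,
                     voltage=v_record if stride else None)


def save_spikes(spikes: SpikeData, path: str | Path,
                sidecar: dict | None = None) -> None:
    """Two-column TSV (cell_index, spike_time_ms) plus a JSON sidecar."""
    path = Path(path)
    cells, times = spikes.as_arrays()
    with open(path, "w") as fh:
        fh.write("cell_index\tspike_time_ms\n")
        for c, t in zip(cells, times):
            fh.write(f"{c}\t{t:.6f}\n")
    side = {"n_cells": spikes.n_cells, "run_length": spikes.run_length,
            **spikes.meta, **(sidecar or {})}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(side, indent=2, default=str))


def save_voltage(result: RunResult, path: str | Path) -> None:
    """Optional voltage-trace export: a text matrix, one row per
    recorded snapshot (first column time in ms, then one column per
    cell, mV)."""
    if result.voltage is None:
        raise ValueError("run was executed without voltage recording")
    mat = np.column_stack([result.voltage_times, result.voltage])
    header = "time_ms\t" + "\t".join(
        f"cell_{i}" for i in range(result.voltage.shape[1]))
    np.savetxt(path, mat, fmt="%.4f", delimiter="\t", header=header,
               comments="")


def load_spikes(path: str | Path) -> SpikeData:
    path = Path(path)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n_cells = int(side["n_cells"])
    run_length = float(side["run_length"])
    cells, times = [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            c, t = line.split("\t")
            cells.append(int(c))
            times.append(float(t))
    cells = np.asarray(cells, dtype=np.int64)
    times = np.asarray(times)
    trains = tuple(np.sort(times[cells == i]) for i in range(n_cells))
    return SpikeData(n_cells=n_cells, run_length=run_length, trains=trains,
                     meta={k: v for k, v in side.items()
                           if k not in ("n_cells", "run_length")})
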
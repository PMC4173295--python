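"""Ring topology with neighbourhood-limited random inhibitory connectivity.

The 200 basket cells sit on a virtual ring with 50 um spacing between
neighbours; the ring encodes neighbourhood relations of the connection
matrix, not physical geometry.  Each ordered pair of cells within the
100-nearest-neighbour window (50 on each side) is connected by a directed
inhibitory synapse independently with probability 0.57.  Conduction
delays grow linearly with ring distance: delay = distance * spacing /
velocity.

The default conduction velocity (80 um/ms, i.e. 0.625 ms per ring step,
31 ms across the half-ring) is a calibration output, frozen together
with the two synaptic peak conductances so that the baseline network
oscillates at 18 Hz under 300 Hz drive; see experiments.calibrate and
docs/methods.md.  Delays of this order are consistent with the ~2 mm
effective propagation extent of the network being comparable to its
spike-release latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TopologyConfig", "NetworkTopology", "ring_distance", "build",
           "total_extent", "save_topology", "load_topology"]


@dataclass(frozen=True)
class TopologyConfig:
    n_cells: int = 200
    neighbourhood: int = 100          # eligible nearest neighbours (both sides)
    connection_probability: float = 0.57
    spacing: float = 50.0             # um between ring neighbours
    conduction_velocity: float = 80.0  # um/ms, calibrated (see module docstring)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neighbourhood % 2 != 0 or not (0 < self.neighbourhood < self.n_cells):
            raise ValueError("neighbourhood must be even and < n_cells")
        if not (0.0 <= self.connection_probability <= 1.0):
            raise ValueError("connection_probability must be in [0, 1]")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.conduction_velocity <= 0:
            raise ValueError("conduction_velocity must be > 0")


@dataclass(frozen=True)
class NetworkTopology:
    """Directed, delayed inhibitory edge list."""

    n_cells: int
    pre: np.ndarray      # int, shape (n_edges,)
    post: np.ndarray     # int, shape (n_edges,)
    delay_ms: np.ndarray  # float, shape (n_edges,)

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    def out_degrees(self) -> np.ndarray:
        return np.bincount(self.pre, minlength=self.n_cells)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.post, minlength=self.n_cells)


def ring_distance(i: int | np.ndarray, j: int | np.ndarray, n: int):
    """Shortest distance between ring positions i and j (in cell steps)."""
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i < 0) or np.any(i >= n) or np.any(j < 0) or np.any(j >= n):
        raise ValueError(f"cell indices must lie in [0, {n})")
    d = np.abs(i - j)
    out = np.minimum(d, n - d)
    return int(out) if out.ndim == 0 else out


def build(config: TopologyConfig) -> NetworkTopology:
    """Sample the directed edge set; reproducible under config.seed.

    Every ordered pair (i, j) with 1 <= ring_distance(i, j) <=
    neighbourhood/2 is included independently with the configured
    probability.  No self-edges, no multi-edges.
    """
    n = config.n_cells
    half = config.neighbourhood // 2
    rng = np.random.default_rng(config.seed)
    # candidate offsets -half..-1, 1..half for every source cell
    offsets = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    pre = np.repeat(np.arange(n), offsets.size)
    post = (pre + np.tile(offsets, n)) % n
    keep = rng.random(pre.size) < config.connection_probability
    pre, post = pre[keep], post[keep]
    dist = ring_distance(pre, post, n)
    delay = dist * config.spacing / config.conduction_velocity
    return NetworkTopology(n_cells=n, pre=pre, post=post, delay_ms=delay)


def total_extent(config: TopologyConfig) -> dict[str, float]:
    """Ring circumference and equivalent radius in mm (documentation aid)."""
    circumference_um = config.n_cells * config.spacing
    return {"circumference_mm": circumference_um / 1000.0,
            "radius_mm": circumference_um / (2.0 * np.pi) / 1000.0}


def save_topology(topo: NetworkTopology, path: str | Path) -> None:
    """Write the edge list as a three-column TSV (pre, post, delay_ms)."""
    df = pd.DataFrame({"pre_index": topo.pre, "post_index": topo.post,
                       "delay_ms": topo.delay_ms})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_topology(path: str | Path, n_cells: int | None = None) -> NetworkTopology:
    df = pd.read_csv(path, sep="\t")
    n = n_cells if n_cells is not None else int(max(df.pre_index.max(),
                                                    df.post_index.max())) + 1
    return NetworkTopology(n_cells=n,
                           pre=df.pre_index.to_numpy(dtype=np.int64),
                           post=df.post_index.to_numpy(dtype=np.int64),
                           delay_ms=df.delay_ms.to_numpy(dtype=float))
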
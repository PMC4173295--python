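#!/usr/bin/env python
"""Facilitation of excitatory drive in a subset of cells.

Runs the facilitation grid — drive raised to 1.5x, 2x and 3x of the
300 Hz baseline over a 1000 ms window, in 10/25/50/100 of the 200
cells, random or clustered — and aggregates the statistics.  Expected
outcome: mean firing rises clearly with the facilitated fraction; the
network frequency stays within about 1 Hz of control (the
delay-dominated rhythm is stiff against drive — see docs/methods.md).
"""

from pathlib import Path

from gammaring.experiments import (GridSpec, aggregate,
                                   facilitation_conditions, run_grid)
from gammaring.simulator import RunConfig

OUT = Path(__file__).resolve().parents[1] / "results" / "facilitation"
SEED0 = 100
N_REPEATS = 2  # desk scale


def main() -> None:
    spec = GridSpec(conditions=tuple(facilitation_conditions()),
                    n_repeats=N_REPEATS, base_config=RunConfig(), seed0=SEED0)
    df = run_grid(spec, out_dir=OUT)
    agg = aggregate(df)
    agg.to_csv(OUT / "grid_aggregate.csv", index=False)
    pert = df[df["mode"] != "control"]
    ctrl = df[df["mode"] == "control"]
    print(agg.to_string(index=False))
    print(f"\ncontrol Omega: {ctrl.omega_hz.mean():.2f} "
          f"+- {ctrl.omega_hz.std():.2f} Hz")
    print(f"pooled grid Omega: {pert.omega_hz.mean():.2f} "
          f"+- {pert.omega_hz.std():.2f} Hz")
    print(f"pooled grid phi:   {pert.phi_hz.mean():.2f} Hz "
          f"(control {ctrl.phi_hz.mean():.2f} Hz)")


if __name__ == "__main__":
    main()
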
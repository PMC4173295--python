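# Methods

## The model

`gammaring` simulates a ring network of 200 fast-spiking basket-cell
interneurons coupled by delayed GABAergic synapses and driven by
stochastic excitatory input, and asks how the network rhythm responds
when the excitatory drive to a subset of cells is scaled up or down —
with the subset either scattered at random or confined to contiguous
clusters, the latter mimicking the volume-limited territory of an
astrocyte.

### Single cell

Each interneuron is a single cylindrical compartment (length = diameter
= 62 um; membrane area pi·d·L ≈ 1.21e-4 cm²; Cm = 1 uF/cm²; the axial
resistance of 100 ohm·cm is carried in the parameter block for fidelity
but cannot affect a single compartment). Active properties follow the
classic fast-spiking interneuron Hodgkin–Huxley formulation of the
Wang–Buzsáki lineage: instantaneous sodium activation m = m∞(V),
inactivation h, delayed-rectifier activation n, with a gating rate
scale φ = 5; g_Na = 35, g_K = 9, g_L = 0.1 mS/cm²; E_Na = +55,
E_K = −90 mV. The leak reversal is calibrated (−65.71 mV) so that the
resting potential is exactly −65 mV — with the nominal −65 mV leak
reversal the Na/K window currents would shift rest upward.

The neuron is type I: firing emerges through a saddle-node bifurcation
(quasi-static saddle node at −60.0 mV, rheobase ≈ 28 pA). The
spike-initiation voltage under a slow current ramp (1 pA/ms) is read
out where dV/dt first exceeds 4× the passive quasi-static ramp slope
(ramp rate / input conductance), i.e. where the active inward current
contributes three times the passive displacement. This criterion
reports −58.1 mV at 1 pA/ms and moves by only ~1.3 mV when the ramp
rate doubles. A fixed large dV/dt criterion (e.g. 20 mV/ms) is *not*
suitable here: for a type-I neuron on a slow ramp it fires mid-upstroke
(−44 mV), far above initiation.

### Synapses

Both synapse classes are dual-exponential conductances normalized so
the peak equals the configured maximal conductance:

    g(t) = Gm · N · (exp(−t/τ_decay) − exp(−t/τ_rise))

* GABA (between basket cells): τ_rise 2.5 ms, τ_decay 10 ms, reversal
  −65 mV — shunting inhibition: at rest it passes no current and acts
  purely by raising the membrane conductance.
* Drive EPSC: τ_rise 0.5 ms, τ_decay 5 ms, reversal 0 mV.

Linearity lets all inputs of a class onto a cell share one pair of
exponential state variables; events increment both components
(weight × N) and each decays analytically — the synaptic states carry
no integration error. Conduction delays are applied in the event
queue, not in the synapse state.

### Network

Cells sit on a virtual ring (the ring encodes neighbourhood relations
of the connection matrix, not geometry) with 50 um spacing; each
ordered pair within the 100-nearest-neighbour window (50 per side) is
connected by a directed inhibitory edge independently with probability
0.57. Expected in/out degree 57 (Binomial(100, 0.57)). Delays grow
linearly with ring distance: delay = distance × spacing / velocity.
No self-edges or multi-edges; edges are sampled independently per
ordered pair (the least-structured choice consistent with a pairwise
connection probability).

### Drive (the synthetic-data generator)

The ~2000 pyramidal-cell inputs per basket cell (cells firing at
1–2 Hz, release probability 0.2–0.3, budgeting to an EPSC barrage of
400–1000 Hz if all connections are active) are reduced to one
independent Poisson EPSC stream per basket cell at a controllable rate,
f0 = 300 Hz at baseline. Streams are independent across cells (no
pyramidal–pyramidal correlation structure is modelled) and are seeded
per cell, so a condition that perturbs some cells leaves the
realization on every other cell unchanged.

Rate schedules are piecewise constant. A schedule is realized by
coupling: a homogeneous stream at the cell's reference rate is drawn
for the whole run, thinned with probability rate/reference inside
reduced-rate segments, and superposed with an independent extra stream
inside elevated segments. This is an exact construction of the
piecewise-homogeneous Poisson process, and it confines a rate step
*pathwise* to its window — outside the window the realized events are
identical to the unperturbed stream, which is what makes the paired
clustered-vs-random comparisons sharp.

What the generator does not emulate: slow rate fluctuations, burst
structure, pairwise correlations from shared presynaptic pools, or
synaptic depression/facilitation. Passing tests therefore demonstrate
the network's behaviour under idealized independent stochastic drive,
not under realistic pyramidal-population statistics.

### Perturbation protocols

A protocol scales the drive rate of `n_affected` cells (grid: 10, 25,
50, 100 of 200, i.e. 5–50%) by a factor (0, 0.25, 0.5 — depression;
1.5, 2, 3 — facilitation) over a 1000 ms window with instantaneous
onset/offset. Selection is uniform without replacement (random mode)
or as `n_clusters` contiguous, non-overlapping ring segments of
near-equal size at seeded random positions (clustered mode). The
cluster count defaults to ceil(n_affected/25) — one 25-cell-scale
domain per 25 affected cells — and is configurable. Both modes with
equal n and scale exert identical total expected drive change:
n_affected × |scale − 1| × f0 × window.

The run timeline is 3500 ms: 500 ms warm-up (discarded), baseline
analysis window 500–1500 ms, action window 1500–2500 ms (which is also
the perturbation analysis window), 1000 ms post-window.

## Monitoring statistics

Computed over a 1000 ms window:

* **Ω** — the frequency of the largest non-DC component of the
  periodogram of the 1 ms-binned, mean-subtracted population spike
  histogram. Spectral resolution is 1 Hz. The search is restricted to
  2–100 Hz by default because in near-tonic regimes the otherwise flat
  spectrum can place the raw argmax on an arbitrary noise line; the
  peak-to-mean power ratio is reported as a confidence flag, and
  `omega_band=None` restores the literal greatest-harmonic rule. Exact
  ties (a strictly periodic pulse train carries equal power in all its
  harmonics) break toward the fundamental.
* **φ** — total spike count / (n_cells × window), with per-cell rates
  and the silent-cell count reported alongside.
* **k(τ)** — the window is divided into bins of τ = 0.1/Ω; each cell's
  spiking is binarized per bin (1 = at least one spike — at τ of a
  tenth of the population period, multi-spike bins are negligible);
  for each pair k_ij = Σ_m X(m)Y(m) / sqrt(Σ X · Σ Y), and k(τ) is the
  mean over pairs in which both cells spiked (pairs with a silent
  member are 0/0 and excluded; their number is reported). Ω is
  estimated first, then τ, then k — no re-estimation loop.

## Calibration

Three parameters of the operating point are not fixed by the model
family: the two synaptic peak conductances and the conduction-delay
scale. `experiments.calibrate` grid-searches them against the baseline
behaviour (mean Ω over seeds inside 18–22 Hz, synchrony above a floor
of 0.10), preferring the candidate closest to the 18.0 Hz reference,
ties toward higher synchrony. At the 1 Hz spectral resolution several
candidates tie on Ω, so the driver (`analysis/01_calibrate.py`)
confirms the finalists with full-length five-seed runs and resolves
the remaining tie by preferring mean firing closest to Ω — the regime
in which each interneuron fires about once per population cycle, as
expected for basket cells sustaining the rhythm (the alternative
accepted points are cycle-skipping, φ ≈ 11 Hz at Ω ≈ 18 Hz). The
frozen result, used as the package default everywhere:

| parameter | value |
|---|---|
| EPSC peak conductance g_exc | 2.0 nS |
| GABA peak conductance g_inh | 2.0 nS |
| conduction velocity | 80 um/ms (0.625 ms per ring step) |

At this point the baseline network oscillates at 18–19 Hz (five seeds:
19, 18, 18, 18, 18 Hz; mean 18.2 ± 0.4), each cell fires ≈ 18 Hz
(about once per cycle), no cell is silent, and k(τ) ≈ 0.16, about
1.7× the independent-Poisson floor for the same rates.

The delay scale matters: at fast conduction (nearest-neighbour delay
0.1 ms) no conductance pair produces a coherent 18–22 Hz state — the
network either oscillates asynchronously at 27–55 Hz or collapses into
slow irregular bursting under very strong shunting. The 18–22 Hz
rhythm this family reaches is delay-dominated: the period is set
largely by the inhibition-propagation loop around the ring, consistent
with the network's ~2 mm extent being comparable to its spike-release
latencies. A consequence (see Limitations) is that Ω is stiff against
drive changes.

## Numerical choices

* Fixed step dt = 0.01 ms. Integration uses Strang splitting:
  exponential gating update over half a step (rates frozen at the
  current voltage), a two-stage explicit Heun update of the voltage
  with midpoint gating, then another half-step gating update. The
  scheme is second-order: halving dt moves single-cell spike times in
  a 1 s run by ≲ 0.2 ms (first-order staggered updating gives 12–17 ms)
  and changes network Ω by < 0.5 Hz and k(τ) by < 0.02.
* Voltage-dependent gating quantities come from dense lookup tables
  (0.01 mV grid, linear interpolation, −120…+80 mV) built per run;
  the interpolation error is far below the integration error.
* Delays are rounded to the step grid (≤ 5 us error, far below all
  synaptic time constants) and served through a ring-buffer event
  queue.
* Spike detection: upward crossing of 0 mV with a 2 ms lockout.
* Warm-up of 500 ms precedes any analysis window.
* Runs abort with a diagnostic on non-finite or out-of-range (|V| >
  200 mV) voltages, and on spike counts exceeding a configurable
  600 Hz/cell buffer cap.
* Seeding: one master seed spawns independent sub-seeds for topology,
  drive, and selection (NumPy `SeedSequence`); identical configs are
  bit-reproducible, and paired conditions share everything but the
  affected set.

## Problem sizes

Grids run all 24 conditions per direction (2 modes × 4 affected counts
× 3 scales) plus control at 2 repeats each — the package's desk-scale
default, with `n_repeats` configurable; baseline characterization uses
5 seeds. A full 3.5 s run of the 200-cell network takes a few seconds
on one core.

## Design choices where the design was open

* "100 nearest neighbours" is read symmetrically, 50 per side.
* Cluster count per condition is the ceil(n/25) rule above, not a
  fixed number; the placement is seeded-random with non-overlap
  enforced by rejection sampling.
* Drive streams may be shared across conditions (same master seed) or
  fresh per run; grids share per repeat to give a paired design.
* φ is reported as the average over *all* cells, with the silent-cell
  count reported separately rather than folded into the average.
* The synchrony coefficient's binarization maps "spiked" to 1; pairs
  with a silent member are excluded from the mean rather than assigned
  an arbitrary value.

## Limitations

* The facilitation-induced frequency shift is small here: the pooled
  facilitation-grid mean lies within about 1 Hz of control and varies
  by a similar amount between seed chains (e.g. 18.1 vs 19.0 Hz for
  two chains at 2 repeats), rather than showing a clear multi-Hz
  upward shift. The 18–22 Hz rhythm is delay-dominated and therefore
  stiff against drive; regimes in which recovery from inhibition sets
  the period would respond more strongly but do not reach a coherent
  18–22 Hz state in this network family.
* The difference between clustered and random action on pairwise
  synchrony at 50% affected cells is below sampling noise at this
  operating point (paired comparisons, 6 seeds × 3 scales); the
  segmentation effect — the clustered action broadening the per-cell
  firing-rate distribution and silencing more cells — is robust.
* Single-compartment cells, no channel noise, no short-term
  plasticity, no ambient-GABA tonic conductance, no feedback from
  interneuron firing onto the modulating (astroglia-like) signal, and
  no local-field-potential model.
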
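"""Network monitoring statistics.

Three quantities summarize a run over an analysis window (1000 ms by
default):

* Omega — network oscillation frequency: the largest non-DC harmonic of
  the power spectrum of the population spike histogram (all cells'
  spikes binned at 1 ms, mean subtracted).
* phi — mean cell firing rate: total spike count / (n_cells * window).
* k(tau) — mean pairwise synchronization: the window is divided into
  bins of width tau = 0.1/Omega; each cell's spiking per bin is
  binarized (1 = at least one spike) and for every pair

      k_ij = sum_m X(m) Y(m) / sqrt(sum_m X(m) * sum_m Y(m)),

  a normalized coincidence count in [0, 1].  k(tau) is the average of
  k_ij over all pairs where both cells spiked at least once in the
  window (pairs with a silent member are 0/0 and are excluded; their
  count is reported).

Omega is estimated first, then tau = 0.1/Omega, then k — no
re-estimation loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import periodogram

from .simulator import SpikeData

__all__ = ["MetricsConfig", "MetricsResult", "population_histogram",
           "oscillation_frequency", "mean_firing_rate", "sync_coefficient",
           "compute_metrics"]


@dataclass(frozen=True)
class MetricsConfig:
    analysis_window: tuple[float, float] = (1500.0, 2500.0)  # ms
    histogram_bin: float = 1.0       # ms
    tau_fraction: float = 0.1        # tau = tau_fraction / Omega
    omega_band: tuple[float, float] | None = (2.0, 100.0)  # Hz search band

    def __post_init__(self) -> None:
        if self.analysis_window[1] <= self.analysis_window[0]:
            raise ValueError("analysis window must have positive length")
        if not (0.0 < self.tau_fraction < 1.0):
            raise ValueError("tau_fraction must be in (0, 1)")
        if self.histogram_bin <= 0:
            raise ValueError("histogram_bin must be > 0")


@dataclass(frozen=True)
class MetricsResult:
    omega: float                 # Hz
    phi: float                   # Hz per cell
    k_tau: float                 # in [0, 1]; nan if undefined
    per_cell_rates: np.ndarray   # Hz
    n_silent: int
    spectral_contrast: float     # peak power / mean non-DC power
    n_pairs_excluded: int

    def flat(self) -> dict[str, float]:
        return {"omega_hz": self.omega, "phi_hz": self.phi,
                "k_tau": self.k_tau, "n_silent": self.n_silent,
                "spectral_contrast": self.spectral_contrast,
                "n_pairs_excluded": self.n_pairs_excluded}


def population_histogram(spikes: SpikeData, window: tuple[float, float],
                         bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Counts of all cells' spikes per bin; returns (counts, edges)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    n_bins = int(np.ceil((t1 - t0) / bin_ms))
    edges = t0 + bin_ms * np.arange(n_bins + 1)
    _, times = spikes.as_arrays()
    sel = times[(times >= t0) & (times < t0 + n_bins * bin_ms)]
    counts, _ = np.histogram(sel, bins=edges)
    return counts.astype(float), edges


def oscillation_frequency(series: np.ndarray, bin_ms: float = 1.0,
                          return_contrast: bool = False,
                          band: tuple[float, float] | None = None):
    """Frequency (Hz) of the largest non-DC spectral component.

    ``band`` optionally restricts the search to a frequency range; in
    near-tonic regimes the otherwise flat spectrum can put the raw
    argmax on an arbitrary noise line.  The contrast (peak power over
    mean non-DC power, computed over the full spectrum) flags such
    low-confidence estimates.

    Raises ValueError on an all-zero (or constant) series, where the
    oscillation frequency is undefined.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least two bins")
    x = series - series.mean()
    if not np.any(x):
        raise ValueError("flat population histogram: Omega undefined")
    fs = 1000.0 / bin_ms
    freqs, power = periodogram(x, fs=fs, detrend=False)
    power = power[1:]                      # drop DC
    freqs = freqs[1:]
    if band is not None:
        sel = (freqs >= band[0]) & (freqs <= band[1])
        if not np.any(sel):
            raise ValueError("no spectral bins inside the search band")
        p_sel = power[sel]
        idx_sel = np.nonzero(sel)[0]
    else:
        p_sel = power
        idx_sel = np.arange(len(power))
    # a strictly periodic pulse train carries equal power in all of its
    # harmonics; break exact (to rounding) ties toward the fundamental
    near_max = np.nonzero(p_sel >= p_sel.max() * (1.0 - 1e-9))[0]
    k = int(idx_sel[near_max[0]])
    contrast = float(power[k] / power.mean()) if power.mean() > 0 else np.inf
    if return_contrast:
        return float(freqs[k]), contrast
    return float(freqs[k])


def mean_firing_rate(spikes: SpikeData, window: tuple[float, float]
                     ) -> tuple[float, np.ndarray, int]:
    """(phi in Hz, per-cell rates in Hz, silent-cell count)."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty analysis window")
    dur_s = (t1 - t0) / 1000.0
    counts = np.array([np.count_nonzero((tr >= t0) & (tr < t1))
                       for tr in spikes.trains])
    rates = counts / dur_s
    return float(rates.mean()), rates, int(np.count_nonzero(counts == 0))


def _binary_matrix(spikes: SpikeData, window: tuple[float, float],
                   tau_ms: float) -> np.ndarray:
    t0, t1 = window
    n_bins = int((t1 - t0) / tau_ms)
    if n_bins < 1:
        raise ValueError("analysis window shorter than one bin")
    edges = t0 + tau_ms * np.arange(n_bins + 1)
    rows = [np.histogram(tr[(tr >= t0) & (tr < edges[-1])], bins=edges)[0] > 0
            for tr in spikes.trains]
    return np.asarray(rows, dtype=float)


def sync_coefficient(spikes: SpikeData, omega: float,
                     window: tuple[float, float], tau_fraction: float = 0.1
                     ) -> tuple[float, np.ndarray, int]:
    """Mean pairwise synchronization coefficient k(tau), tau = 0.1/Omega.

    Returns (k_tau, pairwise matrix with nan for excluded pairs,
    number of excluded pairs).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    tau_ms = 1000.0 * tau_fraction / omega
    B = _binary_matrix(spikes, window, tau_ms)
    s = B.sum(axis=1)
    num = B @ B.T
    denom = np.sqrt(np.outer(s, s))
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(K, np.nan)
    iu = np.triu_indices(len(s), k=1)
    vals = K[iu]
    n_excluded = int(np.count_nonzero(np.isnan(vals)))
    k_mean = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else float("nan")
    return k_mean, K, n_excluded


def compute_metrics(spikes: SpikeData, config: MetricsConfig = MetricsConfig()
                    ) -> MetricsResult:
    """Omega, phi and k(tau) over one analysis window."""
    window = config.analysis_window
    phi, rates, n_silent = mean_firing_rate(spikes, window)
    counts, _ = population_histogram(spikes, window, config.histogram_bin)
    try:
        omega, contrast = oscillation_frequency(counts, config.histogram_bin,
                                                return_contrast=True,
                                                band=config.omega_band)
    except ValueError:
        return MetricsResult(omega=float("nan"), phi=phi, k_tau=float("nan"),
                             per_cell_rates=rates, n_silent=n_silent,
                             spectral_contrast=float("nan"),
                             n_pairs_excluded=-1)
    k_tau, _, n_excl = sync_coefficient(spikes, omega, window,
                                        config.tau_fraction)
    return MetricsResult(omega=omega, phi=phi, k_tau=k_tau,
                         per_cell_rates=rates, n_silent=n_silent,
                         spectral_contrast=contrast, n_pairs_excluded=n_excl)
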
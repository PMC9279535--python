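"""Evaluation indices: population rate, smoothing, PSD and ITPC.

The population spiking rate is

    r_X(t) = 1000 * S_X(t) / (dt * N_X),   X = E, I,

with S_X the per-bin spike count (dt = 0.1 ms bins).  Rates are smoothed
with a Gaussian window (sigma = 10 ms), restricted to the analysis window
and z-scored; the power spectrum is the single-segment periodogram of the
z-scored series (4 s window -> 0.25 Hz resolution), normalized so that the
one-sided power sums to the window variance.  Inter-trial phase coherence
at frequency f across T trials is

    ITPC(T, f) = | (1/T) sum_m F_m(f) / |F_m(f)| |,

the modulus of the mean unit-normalized Fourier coefficient — identically
the mean resultant length of the per-trial phases.  Band means are
arithmetic means over the grid frequencies inside [f_s - df, f_s + df].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import DegenerateInputError, ParameterError
from .sim_engine import SpikeRecord

__all__ = [
    "RateSeries",
    "SpectralSummary",
    "population_rate",
    "gaussian_smooth",
    "zscore_window",
    "power_spectrum",
    "itpc",
    "band_mean",
    "summarize_trials",
]


@dataclass
class RateSeries:
    """A binned population-rate time series (Hz per bin)."""

    values: np.ndarray
    dt_ms: float
    t0_ms: float = 0.0
    population: str = "E"
    smoothing_sigma_ms: float | None = None
    zscored: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("rate series must be one-dimensional")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_ms(self) -> float:
        return len(self.values) * self.dt_ms

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + self.dt_ms * np.arange(len(self.values))


def population_rate(
    spikes: SpikeRecord, population: str = "E", dt_ms: float | None = None
) -> RateSeries:
    """Bin spikes of one population into a rate series (Eq. above)."""
    if dt_ms is None:
        dt_ms = spikes.dt_ms
    n_pop = spikes.n_e if population == "E" else spikes.n_i
    if population not in ("E", "I"):
        raise ParameterError("population must be 'E' or 'I'")
    if n_pop == 0:
        raise ParameterError(f"population {population!r} is empty")
    if population == "E":
        sel = spikes.neuron_ids < spikes.n_e
    else:
        sel = spikes.neuron_ids >= spikes.n_e
    n_bins = int(round(spikes.duration_ms / dt_ms))
    bins = np.floor(spikes.times_ms[sel] / dt_ms).astype(np.int64)
    bins = bins[bins < n_bins]
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    values = 1000.0 * counts / (dt_ms * n_pop)
    return RateSeries(values=values, dt_ms=dt_ms, t0_ms=0.0, population=population)


def gaussian_smooth(series: RateSeries, sigma_ms: float = 10.0) -> RateSeries:
    """Convolve with a unit-mass Gaussian kernel truncated at +/- 4 sigma.

    Edges are renormalized by the local kernel mass so a constant series is
    preserved exactly everywhere, including the boundaries.
    """
    if sigma_ms <= 0:
        raise ParameterError("sigma_ms must be positive")
    half = int(np.ceil(4.0 * sigma_ms / series.dt_ms))
    x = np.arange(-half, half + 1) * series.dt_ms
    kernel = np.exp(-0.5 * (x / sigma_ms) ** 2)
    kernel /= kernel.sum()
    smoothed = signal.fftconvolve(series.values, kernel, mode="same")
    coverage = signal.fftconvolve(np.ones_like(series.values), kernel, mode="same")
    smoothed /= coverage
    return replace(series, values=smoothed, smoothing_sigma_ms=sigma_ms)


def zscore_window(series: RateSeries, window_ms: tuple[float, float]) -> RateSeries:
    """Restrict to [t_a, t_b) and standardize to zero mean, unit SD."""
    t_a, t_b = window_ms
    if t_a < series.t0_ms - 1e-9 or t_b > series.t0_ms + series.duration_ms + 1e-9:
        raise ParameterError("window must lie inside the series")
    i0 = int(round((t_a - series.t0_ms) / series.dt_ms))
    i1 = int(round((t_b - series.t0_ms) / series.dt_ms))
    seg = series.values[i0:i1]
    if len(seg) == 0:
        raise ParameterError("empty analysis window")
    sd = seg.std()
    if sd == 0:
        raise DegenerateInputError("zero variance in the analysis window")
    return replace(
        series, values=(seg - seg.mean()) / sd, t0_ms=t_a, zscored=True
    )


def power_spectrum(series: RateSeries) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of the full (z-scored) window.

    Returns (frequencies in Hz, power).  Normalization: the sum of the
    one-sided power equals the mean square of the input, so for a z-scored
    window the total power is 1 (Parseval).  A 4 s window at 0.1 ms bins
    gives a 0.25 Hz frequency grid.
    """
    x = series.values
    if not np.all(np.isfinite(x)):
        raise ParameterError("series contains non-finite values")
    n = len(x)
    coef = np.fft.rfft(x)
    power = np.abs(coef) ** 2 / n**2
    # one-sided doubling for interior frequencies
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=series.dt_ms / 1000.0)
    return freqs, power


def itpc(trials: list[RateSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Inter-trial phase coherence across trials on a common grid.

    For each grid frequency, the modulus of the mean unit-normalized
    Fourier coefficient over trials.  Trials whose coefficient vanishes at
    a frequency carry no phase there and are excluded at that frequency
    (with a warning); a frequency with no retained trial is NaN.
    """
    if len(trials) < 1:
        raise ParameterError("need at least one trial")
    n = len(trials[0])
    dt = trials[0].dt_ms
    for tr in trials[1:]:
        if len(tr) != n or tr.dt_ms != dt:
            raise ParameterError("all trials must share the same time grid")
    coefs = np.stack([np.fft.rfft(tr.values) for tr in trials])
    mags = np.abs(coefs)
    zero = mags == 0
    if zero.any():
        warnings.warn(
            "trial(s) with zero Fourier coefficient excluded at some frequencies",
            stacklevel=2,
        )
    unit = np.where(zero, 0.0, coefs / np.where(zero, 1.0, mags))
    retained = (~zero).sum(axis=0)
    with np.errstate(invalid="ignore"):
        value = np.abs(unit.sum(axis=0)) / retained
    value = np.where(retained == 0, np.nan, np.minimum(value, 1.0))
    freqs = np.fft.rfftfreq(n, d=dt / 1000.0)
    return freqs, value


def band_mean(
    freqs: np.ndarray, values: np.ndarray, f_s: float, delta_f: float
) -> float:
    """Arithmetic mean of ``values`` over grid frequencies in [f_s-df, f_s+df]."""
    mask = (freqs >= f_s - delta_f - 1e-12) & (freqs <= f_s + delta_f + 1e-12)
    if not mask.any():
        raise ParameterError("band contains no grid frequency")
    return float(np.mean(values[mask]))


@dataclass
class SpectralSummary:
    """Cross-trial spectral indices for one condition."""

    freqs: np.ndarray
    psd_trials: np.ndarray        # (n_trials, n_freqs)
    psd_mean: np.ndarray
    psd_sd: np.ndarray            # sample SD (n-1) across trials
    itpc: np.ndarray
    itpc_jackknife_se: np.ndarray
    band_means: pd.DataFrame      # columns: f_s, delta_f, metric, mean, sd, n_trials
    n_trials: int

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "psd_mean": self.psd_mean,
                "psd_sd": self.psd_sd,
                "itpc": self.itpc,
            }
        )


def _jackknife_se(coefs_unit: np.ndarray) -> np.ndarray:
    """Leave-one-out jackknife standard error of the ITPC across trials."""
    t = coefs_unit.shape[0]
    if t < 2:
        return np.zeros(coefs_unit.shape[1])
    total = coefs_unit.sum(axis=0)
    loo = np.abs(total[None, :] - coefs_unit) / (t - 1)
    return np.sqrt((t - 1) / t * ((loo - loo.mean(axis=0)) ** 2).sum(axis=0))


def summarize_trials(
    trials: list[RateSeries],
    f_s: float,
    delta_fs: tuple[float, ...] = (1.0, 2.0, 3.0),
) -> SpectralSummary:
    """PSD, ITPC and band means around ``f_s`` for a set of analysis-ready trials.

    Trials must already be smoothed, windowed and z-scored.  The PSD
    spread is the sample SD across trials; the ITPC has no per-trial
    value, so its spread is a leave-one-out jackknife standard error.
    """
    spectra = [power_spectrum(tr) for tr in trials]
    freqs = spectra[0][0]
    psd_trials = np.stack([p for _, p in spectra])
    freqs_i, itpc_vals = itpc(trials)
    coefs = np.stack([np.fft.rfft(tr.values) for tr in trials])
    mags = np.abs(coefs)
    unit = np.where(mags == 0, 0.0, coefs / np.where(mags == 0, 1.0, mags))
    rows = []
    for df_hz in delta_fs:
        per_trial_power = [band_mean(freqs, p, f_s, df_hz) for p in psd_trials]
        rows.append(
            {
                "f_s": f_s,
                "delta_f": df_hz,
                "metric": "power",
                "mean": float(np.mean(per_trial_power)),
                "sd": float(np.std(per_trial_power, ddof=1)) if len(trials) > 1 else 0.0,
                "n_trials": len(trials),
            }
        )
        rows.append(
            {
                "f_s": f_s,
                "delta_f": df_hz,
                "metric": "itpc",
                "mean": band_mean(freqs_i, itpc_vals, f_s, df_hz),
                "sd": band_mean(freqs_i, _jackknife_se(unit), f_s, df_hz),
                "n_trials": len(trials),
            }
        )
    return SpectralSummary(
        freqs=freqs,
        psd_trials=psd_trials,
        psd_mean=psd_trials.mean(axis=0),
        psd_sd=psd_trials.std(axis=0, ddof=1) if len(trials) > 1 else np.zeros_like(freqs),
        itpc=itpc_vals,
        itpc_jackknife_se=_jackknife_se(unit),
        band_means=pd.DataFrame(rows),
        n_trials=len(trials),
    )
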
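"""Periodic windowed-Poisson stimulus generation.

The external drive is a periodic train of brief opportunities to spike:
during the first ``window_ms`` (1 ms) of every stimulus period ``1/F_s``,
each neuron independently receives Poisson events at rate ``lambda_hz``
(1 Hz); outside the window the rate is zero.  Every event adds
``amplitude_mv`` (21 mV) to the membrane potential instantaneously, which
exceeds the 20 mV threshold-to-rest distance, so a single event evokes a
spike in a resting neuron.  The directly evoked per-neuron firing rate is
therefore approximately ``F_s * lambda_hz / 1000`` Hz.

Stimulus frequencies are realized as integer-millisecond periods (40 Hz ->
25 ms, 83.3 Hz -> 12 ms, 90.9 Hz -> 11 ms, 142.8 Hz -> 7 ms); all analyses
use the exact frequency 1000/period.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["StimulusSpec", "StimulusTrain", "generate_stimulus"]


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of the periodic windowed-Poisson input.

    ``period_ms`` is the integer stimulus period; the nominal frequency is
    ``1000 / period_ms`` Hz.  ``lambda_hz`` is the in-window Poisson rate,
    ``window_ms`` the window length and ``amplitude_mv`` the instantaneous
    membrane jump per event.
    """

    period_ms: int = 25
    lambda_hz: float = 1.0
    window_ms: float = 1.0
    amplitude_mv: float = 21.0
    duration_ms: float = 7000.0

    def __post_init__(self) -> None:
        if self.period_ms < 1:
            raise ParameterError("period_ms must be a positive integer")
        if self.window_ms <= 0 or self.window_ms > self.period_ms:
            raise ParameterError("window must be positive and no longer than the period")
        if self.lambda_hz < 0:
            raise ParameterError("lambda_hz must be non-negative")
        if self.duration_ms <= 0:
            raise ParameterError("duration_ms must be positive")

    @property
    def f_s(self) -> float:
        """Exact stimulus frequency in Hz."""
        return 1000.0 / self.period_ms

    @classmethod
    def from_frequency(cls, f_hz: float, **kwargs) -> "StimulusSpec":
        """Spec whose integer period best matches the nominal frequency."""
        return cls(period_ms=int(round(1000.0 / f_hz)), **kwargs)


@dataclass
class StimulusTrain:
    """External event times for every neuron, time-sorted.

    ``times_ms`` and ``neuron_ids`` are parallel arrays; each event lies
    inside some window [k*period, k*period + window).
    """

    times_ms: np.ndarray
    neuron_ids: np.ndarray
    n_neurons: int
    spec: StimulusSpec

    def __len__(self) -> int:
        return len(self.times_ms)

    def events_for(self, neuron: int) -> np.ndarray:
        return self.times_ms[self.neuron_ids == neuron]

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.times_ms).tobytes())
        h.update(np.ascontiguousarray(self.neuron_ids).tobytes())
        return h.hexdigest()

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_neurons={self.n_neurons}\tperiod_ms={self.spec.period_ms}\n")
            fh.write("time_ms\tneuron_id\n")
            for t, i in zip(self.times_ms, self.neuron_ids):
                fh.write(f"{t:.6f}\t{int(i)}\n")


def generate_stimulus(
    spec: StimulusSpec, n_neurons: int, rng: np.random.Generator
) -> StimulusTrain:
    """Draw one stimulus realization for ``n_neurons`` neurons.

    Uses the superposition property of the Poisson process: the total
    number of events per neuron over all windows is Poisson with mean
    ``n_windows * lambda_hz * window_ms / 1000``; each event is then placed
    in a uniformly chosen window at a uniform offset.  This is distribution-
    identical to drawing each window's count independently, and keeps the
    realization compact at publication scale.
    """
    if n_neurons < 0:
        raise ParameterError("n_neurons must be non-negative")
    n_windows = int(np.ceil(spec.duration_ms / spec.period_ms))
    lam_per_window = spec.lambda_hz * spec.window_ms / 1000.0
    counts = rng.poisson(lam_per_window * n_windows, size=n_neurons)
    total = int(counts.sum())
    neuron_ids = np.repeat(np.arange(n_neurons, dtype=np.int32), counts)
    windows = rng.integers(0, n_windows, size=total)
    offsets = rng.uniform(0.0, spec.window_ms, size=total)
    times = windows * float(spec.period_ms) + offsets
    keep = times < spec.duration_ms
    times, neuron_ids = times[keep], neuron_ids[keep]
    order = np.argsort(times, kind="stable")
    return StimulusTrain(
        times_ms=times[order],
        neuron_ids=neuron_ids[order],
        n_neurons=n_neurons,
        spec=spec,
    )
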
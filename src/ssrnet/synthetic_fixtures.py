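"""Synthetic inputs with known statistical structure.

These generators let every analysis stage be exercised and validated
without running the network simulator: multi-trial sinusoidal rate series
with von Mises phase jitter (whose expected inter-trial phase coherence at
the carrier frequency is the Bessel ratio I1(kappa)/I0(kappa)),
inhomogeneous-Poisson population spike trains with a prescribed rate
profile, and scaled-down presets of the publication configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .net_builder import LogNormalEpspSpec, NetworkSpec
from .response_analysis import RateSeries
from .sim_engine import SimConfig, SpikeRecord
from .stimulus_gen import StimulusSpec

__all__ = [
    "SurrogateSpec",
    "make_phase_jittered_trials",
    "make_inhomogeneous_poisson_spikes",
    "scaled_preset",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Phase-jittered sinusoidal trial ensemble.

    ``kappa`` is the von Mises concentration of the per-trial phase
    (``inf`` = perfect locking, 0 = uniform phase); ``noise_sd`` adds white
    broadband noise on top of the unit-amplitude carrier.
    """

    f_hz: float = 40.0
    kappa: float = np.inf
    n_trials: int = 10
    window_s: float = 4.0
    dt_ms: float = 0.1
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ParameterError("kappa must be non-negative")
        if self.window_s * self.f_hz < 10:
            raise ParameterError("window must cover many carrier cycles")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be at least 1")


def make_phase_jittered_trials(spec: SurrogateSpec) -> list[RateSeries]:
    """Trials ``sin(2 pi f t + phi_m) + noise`` with ``phi_m ~ vonMises(0, kappa)``."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.window_s * 1000.0 / spec.dt_ms))
    t = np.arange(n) * spec.dt_ms / 1000.0
    trials = []
    for _ in range(spec.n_trials):
        phase = 0.0 if np.isinf(spec.kappa) else rng.vonmises(0.0, spec.kappa)
        x = np.sin(2.0 * np.pi * spec.f_hz * t + phase)
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(n)
        trials.append(RateSeries(values=x, dt_ms=spec.dt_ms, zscored=True))
    return trials


def make_inhomogeneous_poisson_spikes(
    rate_profile: RateSeries, n_neurons: int, seed: int = 0
) -> SpikeRecord:
    """Population spike train whose binned rate converges to the profile.

    ``rate_profile`` gives the per-neuron rate (Hz) per bin; the population
    count per bin is Poisson with mean ``n_neurons * rate * dt / 1000``
    (superposition of independent neurons), and events are attributed to
    uniformly chosen neurons at uniform offsets within the bin.
    """
    if n_neurons < 1:
        raise ParameterError("n_neurons must be positive")
    rates = rate_profile.values
    if np.any(rates < 0):
        raise ParameterError("rate profile must be non-negative")
    rng = np.random.default_rng(seed)
    dt = rate_profile.dt_ms
    lam = n_neurons * rates * dt / 1000.0
    counts = rng.poisson(lam)
    total = int(counts.sum())
    bin_idx = np.repeat(np.arange(len(rates)), counts)
    times = rate_profile.t0_ms + (bin_idx + rng.uniform(0.0, 1.0, total)) * dt
    ids = rng.integers(0, n_neurons, size=total).astype(np.int32)
    order = np.argsort(times, kind="stable")
    return SpikeRecord(
        times_ms=times[order],
        neuron_ids=ids[order],
        n_e=n_neurons,
        n_i=0,
        duration_ms=rate_profile.duration_ms,
        dt_ms=dt,
    )


def scaled_preset(scale: float, *, period_ms: int = 25, ei_ratio: tuple[int, int] = (4, 1),
                  remove_strong: bool = False, base_seed: int = 0):
    """A :class:`~ssrnet.experiment_pipeline.ConditionSpec` at a fraction of full size.

    ``scale`` = 1 is the publication configuration (12000 neurons, 0.1 ms
    step, 7 s trials with a [3, 7] s analysis window, 10 trials); smaller
    scales shrink the neuron count while preserving all probabilities and
    weights.  ``ei_ratio`` is given as the (E, I) ratio pair, e.g. (4, 1).
    """
    from .experiment_pipeline import ConditionSpec, partition_ei

    if not 0.0 < scale <= 1.0:
        raise ParameterError("scale must lie in (0, 1]")
    n_total = int(round(12000 * scale))
    n_e, n_i = partition_ei(n_total, ei_ratio)
    if n_i < 10:
        raise ParameterError("scale too small: fewer than 10 inhibitory neurons")
    return ConditionSpec(
        network=NetworkSpec(n_total=n_total, ei_ratio=(n_e, n_i), remove_strong=remove_strong),
        epsp=LogNormalEpspSpec(),
        stimulus=StimulusSpec(period_ms=period_ms, duration_ms=7000.0),
        sim=SimConfig(dt_ms=0.1, duration_ms=7000.0, record_from_ms=3000.0),
        n_trials=10,
        base_seed=base_seed,
    )
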
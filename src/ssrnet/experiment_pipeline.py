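"""Orchestration of the stimulation experiment grid.

A *condition* is one (E/I ratio, stimulus frequency, strong-synapse
setting) cell: the same stimulus realization drives ``n_trials``
independently rebuilt networks (fresh topology, amplitudes, delays,
initial state and failure draws per trial), and the excitatory population
rate of each trial is smoothed, windowed, z-scored and Fourier-analyzed.
The sweep walks the Cartesian product of ratios x frequencies x
strong-synapse flags and collects band means of PSD and inter-trial phase
coherence around each stimulus frequency for half-widths of 1, 2 and 3 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import streams
from .errors import DegenerateInputError, IntegrationError, ParameterError
from .net_builder import LogNormalEpspSpec, NetworkSpec, build_network
from .response_analysis import (
    RateSeries,
    SpectralSummary,
    gaussian_smooth,
    population_rate,
    summarize_trials,
    zscore_window,
)
from .sim_engine import SimConfig, SpikeRecord, simulate_trial
from .stimulus_gen import StimulusSpec, StimulusTrain, generate_stimulus

__all__ = [
    "ConditionSpec",
    "ConditionResult",
    "partition_ei",
    "run_condition",
    "run_ei_sweep",
]

SMOOTHING_SIGMA_MS = 10.0
DELTA_FS_HZ = (1.0, 2.0, 3.0)


def partition_ei(n_total: int, ratio: tuple[float, float]) -> tuple[int, int]:
    """Split ``n_total`` into (N_E, N_I) closest to the requested ratio."""
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ParameterError("ratio terms must be positive")
    n_i = int(round(n_total * b / (a + b)))
    n_e = n_total - n_i
    if n_e < 1 or n_i < 1:
        raise ParameterError("ratio leaves an empty population")
    return n_e, n_i


@dataclass(frozen=True)
class ConditionSpec:
    """Everything needed to run one condition of the experiment grid."""

    network: NetworkSpec
    epsp: LogNormalEpspSpec = field(default_factory=LogNormalEpspSpec)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    n_trials: int = 10
    base_seed: int = 0
    stimulate_inhibitory: bool = True

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ParameterError("n_trials must be at least 1")
        if self.stimulus.duration_ms < self.sim.duration_ms:
            raise ParameterError("stimulus must cover the simulated duration")

    @property
    def analysis_window_ms(self) -> tuple[float, float]:
        return (self.sim.record_from_ms, self.sim.duration_ms)


@dataclass
class ConditionResult:
    """Artifacts of one executed condition."""

    condition: ConditionSpec
    summary: SpectralSummary | None
    trial_series: list[RateSeries]         # analysis-ready z-scored r_E per retained trial
    trial_status: list[str]                # "ok" / "degenerate" per trial
    stimulus_hash: str
    spike_records: list[SpikeRecord] | None = None

    @property
    def n_retained(self) -> int:
        return sum(s == "ok" for s in self.trial_status)


def _trial_seed(base_seed: int, trial: int) -> int:
    return int(
        np.random.SeedSequence([int(base_seed), 1000, int(trial)]).generate_state(1)[0]
        % (2**31)
    )


def analyze_record(
    record: SpikeRecord,
    window_ms: tuple[float, float],
    sigma_ms: float = SMOOTHING_SIGMA_MS,
) -> RateSeries:
    """Excitatory rate -> Gaussian smoothing -> windowed z-score."""
    r_e = population_rate(record, "E")
    return zscore_window(gaussian_smooth(r_e, sigma_ms), window_ms)


def run_condition(
    cond: ConditionSpec,
    *,
    keep_spikes: bool = False,
    outdir: str | Path | None = None,
) -> ConditionResult:
    """Execute one condition: shared stimulus, ``n_trials`` reseeded networks.

    The stimulus realization is drawn once from the condition's stimulus
    stream and reused for every trial (the phase-coherence protocol);
    topology, synaptic amplitudes, delays, initial membrane potentials and
    transmission failures are reseeded per trial.  Trials whose analysis
    window is silent (zero variance) are recorded as degenerate and
    excluded from the spectral summary.
    """
    n = cond.network.n_total
    stim_rng = streams.stream_rng(cond.base_seed, streams.STIMULUS)
    n_stim = cond.network.n_e if not cond.stimulate_inhibitory else n
    stim = generate_stimulus(cond.stimulus, n_stim, stim_rng)

    series: list[RateSeries] = []
    status: list[str] = []
    records: list[SpikeRecord] = []
    for trial in range(cond.n_trials):
        table = build_network(cond.network, cond.epsp, seed=cond.base_seed, trial=trial)
        cfg = replace(cond.sim, trial_seed=_trial_seed(cond.base_seed, trial))
        try:
            record = simulate_trial(table, stim, cfg=cfg)
        except IntegrationError as err:
            raise IntegrationError(
                f"trial {trial} failed at t={err.time_ms} ms: {err}", err.time_ms
            ) from err
        if keep_spikes:
            records.append(record)
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            record.write_tsv(outdir / f"spikes_trial{trial:02d}.tsv")
        try:
            series.append(analyze_record(record, cond.analysis_window_ms))
            status.append("ok")
        except DegenerateInputError:
            status.append("degenerate")

    summary = (
        summarize_trials(series, cond.stimulus.f_s, DELTA_FS_HZ) if series else None
    )
    result = ConditionResult(
        condition=cond,
        summary=summary,
        trial_series=series,
        trial_status=status,
        stimulus_hash=stim.content_hash(),
        spike_records=records if keep_spikes else None,
    )
    if outdir is not None and summary is not None:
        summary.to_table().to_csv(Path(outdir) / "spectrum.tsv", sep="\t", index=False)
        summary.band_means.to_csv(Path(outdir) / "band_means.tsv", sep="\t", index=False)
    return result


def run_ei_sweep(
    ratios: list[tuple[float, float]],
    period_ms_list: list[int],
    strong_flags: list[bool],
    template: ConditionSpec,
) -> pd.DataFrame:
    """Run the Cartesian product of conditions and tabulate band means.

    Returns one row per (condition, delta_f) with columns ei_ratio, f_s,
    strong_synapses, delta_f, mean/sd of band ITPC and band power, and the
    trial count.  ``strong_flags`` uses True for the intact log-normal tail
    and False for the ablated (no EPSP > 9 mV) control.
    """
    rows = []
    for ratio in ratios:
        n_e, n_i = partition_ei(template.network.n_total, ratio)
        for period_ms in period_ms_list:
            for strong in strong_flags:
                network = replace(
                    template.network, ei_ratio=(n_e, n_i), remove_strong=not strong
                )
                stimulus = replace(template.stimulus, period_ms=period_ms)
                cond = replace(template, network=network, stimulus=stimulus)
                result = run_condition(cond)
                if result.summary is None:
                    raise DegenerateInputError(
                        f"all trials degenerate for ratio {ratio}, period {period_ms}"
                    )
                bm = result.summary.band_means
                for df_hz in DELTA_FS_HZ:
                    itpc_row = bm[(bm.delta_f == df_hz) & (bm.metric == "itpc")].iloc[0]
                    pow_row = bm[(bm.delta_f == df_hz) & (bm.metric == "power")].iloc[0]
                    rows.append(
                        {
                            "ei_ratio": f"{ratio[0]:g}:{ratio[1]:g}",
                            "n_e": n_e,
                            "n_i": n_i,
                            "f_s": cond.stimulus.f_s,
                            "strong_synapses": strong,
                            "delta_f": df_hz,
                            "mean_itpc": itpc_row["mean"],
                            "sd_itpc": itpc_row["sd"],
                            "mean_band_power": pow_row["mean"],
                            "sd_band_power": pow_row["sd"],
                            "n_trials": result.n_retained,
                        }
                    )
    return pd.DataFrame(rows)
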
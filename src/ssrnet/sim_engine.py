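"""Forward-Euler integration of the conductance-based LIF network.

Membrane dynamics per neuron:

    dv/dt = -(v - V_L)/tau_m - g_E (v - V_E) - g_I (v - V_I) + I_ex
    dg_X/dt = -g_X/tau_s + sum_j G_{X,j} sum_s delta(t - s_j - d_j)

with threshold/reset (v >= V_thr -> v -> V_r), a 1 ms absolute refractory
period, per-synapse conduction delays and, on EE synapses only, independent
Bernoulli transmission failure per delivery.  External stimulus events are
delta inputs realized as instantaneous jumps of the membrane potential.

Update order within a step: (1) conductance decay, (2) arrival of delayed
synaptic increments, (3) stimulus jumps, (4) Euler voltage update,
(5) threshold/reset.  During refractoriness the voltage is clamped at the
reset value and stimulus jumps are lost, while conductances keep evolving
and accumulating input.  Delays are rounded to the integration grid at
scheduling time, with a one-step floor so a delivery never lands in the
step that produced it.

The hot loop is compiled with numba; per-trial stochasticity (initial
membrane potentials, transmission failures) comes from named streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np

from . import streams
from .errors import IntegrationError, ParameterError
from .net_builder import EXCITATORY, INHIBITORY, NeuronClassParams, SynapseTable
from .stimulus_gen import StimulusTrain

__all__ = ["SimConfig", "SpikeRecord", "simulate_trial"]

_STATUS_OK = 0
_STATUS_OVERFLOW = 1
_STATUS_NONFINITE = 2


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for one trial.

    ``record_from_ms`` marks the start of the analysis window (the initial
    transient is simulated but excluded from spectral analysis downstream).
    ``trial_seed`` controls the trial-specific streams: initial membrane
    potentials and EE transmission failures.  ``max_spike_rate_hz`` bounds
    the preallocated spike buffer (mean population rate headroom).
    """

    dt_ms: float = 0.1
    duration_ms: float = 7000.0
    record_from_ms: float = 3000.0
    trial_seed: int = 0
    max_spike_rate_hz: float = 200.0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ParameterError("dt_ms must be positive")
        if not (0 <= self.record_from_ms < self.duration_ms):
            raise ParameterError("require 0 <= record_from_ms < duration_ms")


@dataclass
class SpikeRecord:
    """Spike events (time-sorted) from one simulated trial."""

    times_ms: np.ndarray
    neuron_ids: np.ndarray
    n_e: int
    n_i: int
    duration_ms: float
    dt_ms: float
    # EE delivery bookkeeping (attempted vs delivered after stochastic failure)
    ee_attempts: int = 0
    ee_delivered: int = 0

    def __len__(self) -> int:
        return len(self.times_ms)

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    def population_ids(self, population: str) -> np.ndarray:
        if population == "E":
            return self.neuron_ids[self.neuron_ids < self.n_e]
        if population == "I":
            return self.neuron_ids[self.neuron_ids >= self.n_e]
        raise ParameterError("population must be 'E' or 'I'")

    def mean_rate_hz(self, population: str = "E", from_ms: float = 0.0) -> float:
        n_pop = self.n_e if population == "E" else self.n_i
        sel = self.times_ms >= from_ms
        ids = self.neuron_ids[sel]
        count = int((ids < self.n_e).sum() if population == "E" else (ids >= self.n_e).sum())
        return 1000.0 * count / (n_pop * (self.duration_ms - from_ms))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# n_e={self.n_e}\tn_i={self.n_i}\tduration_ms={self.duration_ms}"
                f"\tdt_ms={self.dt_ms}\n"
            )
            fh.write("time_ms\tneuron_id\n")
            for t, i in zip(self.times_ms, self.neuron_ids):
                fh.write(f"{t:.4f}\t{int(i)}\n")


@nb.njit(cache=True)
def _euler_loop(
    dt,
    n_steps,
    v,
    g_e,
    g_i,
    tau_m,
    tau_s,
    v_leak,
    v_exc,
    v_inh,
    v_reset,
    v_thr,
    refractory,
    indptr,
    syn_post,
    syn_w,
    syn_delay_steps,
    syn_p_fail,
    syn_exc,
    buf_e,
    buf_i,
    stim_step,
    stim_neuron,
    stim_amp,
    fail_seed,
    spike_t,
    spike_id,
    rec_ids,
    v_trace,
):
    np.random.seed(fail_seed)
    n = v.shape[0]
    d_slots = buf_e.shape[0]
    has_syn = syn_post.shape[0] > 0
    n_stim = stim_step.shape[0]
    max_spikes = spike_t.shape[0]
    refrac_until = np.full(n, -1.0)
    count = 0
    sp = 0
    attempts = 0
    delivered = 0
    for step in range(n_steps):
        t = step * dt
        slot = step % d_slots
        if has_syn:
            for i in range(n):
                g_e[i] += dt * (-g_e[i] / tau_s) + buf_e[slot, i]
                g_i[i] += dt * (-g_i[i] / tau_s) + buf_i[slot, i]
                buf_e[slot, i] = 0.0
                buf_i[slot, i] = 0.0
        while sp < n_stim and stim_step[sp] == step:
            i = stim_neuron[sp]
            if t >= refrac_until[i]:
                v[i] += stim_amp
            sp += 1
        for i in range(n):
            if t < refrac_until[i]:
                v[i] = v_reset
                continue
            dv = (
                -(v[i] - v_leak) / tau_m[i]
                - g_e[i] * (v[i] - v_exc)
                - g_i[i] * (v[i] - v_inh)
            )
            v[i] += dt * dv
            if v[i] >= v_thr:
                if count >= max_spikes:
                    return count, attempts, delivered, _STATUS_OVERFLOW, step
                spike_t[count] = t
                spike_id[count] = i
                count += 1
                v[i] = v_reset
                refrac_until[i] = t + refractory
                for k in range(indptr[i], indptr[i + 1]):
                    if syn_p_fail[k] > 0.0:
                        attempts += 1
                        if np.random.random() < syn_p_fail[k]:
                            continue
                        delivered += 1
                    dslot = (step + syn_delay_steps[k]) % d_slots
                    if syn_exc[k]:
                        buf_e[dslot, syn_post[k]] += syn_w[k]
                    else:
                        buf_i[dslot, syn_post[k]] += syn_w[k]
        for j in range(rec_ids.shape[0]):
            v_trace[step, j] = v[rec_ids[j]]
    for i in range(n):
        if not np.isfinite(v[i]):
            return count, attempts, delivered, _STATUS_NONFINITE, n_steps - 1
    return count, attempts, delivered, _STATUS_OK, n_steps - 1


def _csr_from_table(table: SynapseTable, dt_ms: float):
    """Sort synapses by presynaptic neuron into CSR arrays for the kernel."""
    n = table.n_total
    df = table.df
    pre = df["pre_id"].to_numpy(np.int64)
    order = np.argsort(pre, kind="stable")
    pre = pre[order]
    post = df["post_id"].to_numpy(np.int32)[order]
    w = df["weight"].to_numpy(float)[order]
    delay = df["delay_ms"].to_numpy(float)[order]
    p_fail = df["p_fail"].to_numpy(float)[order]
    # delivery scheduling: round to the grid, at least one step ahead
    delay_steps = np.maximum(np.rint(delay / dt_ms).astype(np.int64), 1)
    syn_exc = (pre < table.n_e).astype(np.bool_)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, pre + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, post, w, delay_steps, p_fail, syn_exc


def simulate_trial(
    table: SynapseTable,
    stim: StimulusTrain | None,
    params_e: NeuronClassParams = EXCITATORY,
    params_i: NeuronClassParams = INHIBITORY,
    cfg: SimConfig = SimConfig(),
    *,
    initial_v: np.ndarray | None = None,
    record_v_ids=None,
) -> SpikeRecord | tuple[SpikeRecord, np.ndarray]:
    """Simulate one trial and return its spike record.

    Initial membrane potentials are uniform on [V_L, V_thr) from the
    trial's initial-state stream unless ``initial_v`` overrides them;
    initial conductances are zero.  ``record_v_ids`` requests voltage
    traces for the listed neurons (returned as a second value, one column
    per neuron, one row per step).  The result is a deterministic function
    of (table, stim, params, cfg).
    """
    n = table.n_total
    if stim is not None and stim.n_neurons > n:
        raise ParameterError("stimulus addresses more neurons than the network has")
    if params_e.tau_s != params_i.tau_s:
        raise ParameterError("the engine assumes a common synaptic decay constant")
    dt = cfg.dt_ms
    n_steps = int(round(cfg.duration_ms / dt))

    indptr, post, w, delay_steps, p_fail, syn_exc = _csr_from_table(table, dt)
    d_slots = int(delay_steps.max()) + 1 if len(delay_steps) else 1
    buf_e = np.zeros((d_slots, n))
    buf_i = np.zeros((d_slots, n))

    if initial_v is None:
        rng = streams.stream_rng(cfg.trial_seed, streams.INITIAL_STATE)
        v = rng.uniform(params_e.v_leak, params_e.v_thr, size=n)
    else:
        v = np.array(initial_v, dtype=float)
        if v.shape != (n,):
            raise ParameterError("initial_v must have one entry per neuron")
    g_e = np.zeros(n)
    g_i = np.zeros(n)
    tau_m = np.where(np.arange(n) < table.n_e, params_e.tau_m, params_i.tau_m)

    if stim is not None and len(stim):
        stim_step = np.floor(stim.times_ms / dt).astype(np.int64)
        stim_neuron = stim.neuron_ids.astype(np.int64)
        keep = stim_step < n_steps
        stim_step, stim_neuron = stim_step[keep], stim_neuron[keep]
        amp = float(stim.spec.amplitude_mv)
    else:
        stim_step = np.empty(0, dtype=np.int64)
        stim_neuron = np.empty(0, dtype=np.int64)
        amp = 0.0

    max_spikes = max(1024, int(n * cfg.duration_ms / 1000.0 * cfg.max_spike_rate_hz))
    spike_t = np.empty(max_spikes)
    spike_id = np.empty(max_spikes, dtype=np.int32)

    rec_ids = (
        np.asarray(record_v_ids, dtype=np.int64)
        if record_v_ids is not None
        else np.empty(0, dtype=np.int64)
    )
    v_trace = np.empty((n_steps if len(rec_ids) else 0, len(rec_ids)))

    fail_seed = streams.stream_seed32(cfg.trial_seed, streams.TRANSMISSION_FAILURE)
    count, attempts, delivered, status, last_step = _euler_loop(
        dt, n_steps, v, g_e, g_i, tau_m,
        params_e.tau_s, params_e.v_leak, params_e.v_exc, params_e.v_inh,
        params_e.v_reset, params_e.v_thr, params_e.refractory,
        indptr, post, w, delay_steps, p_fail, syn_exc,
        buf_e, buf_i, stim_step, stim_neuron, amp, fail_seed,
        spike_t, spike_id, rec_ids, v_trace,
    )
    if status == _STATUS_OVERFLOW:
        raise IntegrationError(
            "spike buffer overflow (raise SimConfig.max_spike_rate_hz)",
            time_ms=last_step * dt,
        )
    if status == _STATUS_NONFINITE:
        raise IntegrationError("non-finite membrane potential", time_ms=last_step * dt)

    record = SpikeRecord(
        times_ms=spike_t[:count].copy(),
        neuron_ids=spike_id[:count].copy(),
        n_e=table.n_e,
        n_i=table.n_i,
        duration_ms=cfg.duration_ms,
        dt_ms=dt,
        ee_attempts=int(attempts),
        ee_delivered=int(delivered),
    )
    if record_v_ids is not None:
        return record, v_trace
    return record
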
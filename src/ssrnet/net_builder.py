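"""Network construction for the log-normal-synapse spiking network.

The network is a directed Erdős–Rényi graph over ``n_total`` neurons
(excitatory ids first).  Excitatory-to-excitatory (EE) synapses carry EPSP
amplitudes drawn from a log-normal distribution truncated at 20 mV; the
amplitude ``V_EPSP`` (mV) maps to a conductance weight ``V_EPSP / 100``
(1/ms) and to a per-spike transmission-failure probability
``P = a / (a + V_EPSP)``, so weak synapses fail often and the rare strong
ones are reliable.  All other synapse classes (EI, IE, II) carry fixed
conductance weights.  Conduction delays are uniform per class: EE in
[1, 3] ms, everything else in [0, 2] ms.

"Strong" synapses are EE connections with amplitude above 9 mV — the heavy
tail of the log-normal.  ``remove_strong_synapses`` ablates them, which is
the control condition of the study this model supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from . import streams

__all__ = [
    "NeuronClassParams",
    "EXCITATORY",
    "INHIBITORY",
    "LogNormalEpspSpec",
    "NetworkSpec",
    "SynapseTable",
    "sample_epsp_amplitudes",
    "epsp_to_conductance",
    "calibrate_single_epsp",
    "build_network",
    "remove_strong_synapses",
]

_SYNAPSE_COLUMNS = ["pre_id", "post_id", "class_pair", "weight", "delay_ms", "epsp_mv", "p_fail"]


@dataclass(frozen=True)
class NeuronClassParams:
    """Single-compartment conductance-based LIF parameters for one neuron class.

    Units: time constants in ms, potentials in mV.
    """

    tau_m: float = 20.0       # membrane decay constant
    v_leak: float = -70.0     # leak reversal potential
    v_exc: float = 0.0        # excitatory (AMPA) reversal potential
    v_inh: float = -80.0      # inhibitory reversal potential
    v_reset: float = -60.0    # post-spike reset voltage
    v_thr: float = -50.0      # firing threshold
    tau_s: float = 2.0        # synaptic-conductance decay constant
    refractory: float = 1.0   # absolute refractory period

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.tau_s <= 0:
            raise ParameterError("tau_m and tau_s must be positive")
        if self.refractory < 0:
            raise ParameterError("refractory period must be non-negative")
        if not (self.v_reset < self.v_thr):
            raise ParameterError("require v_reset < v_thr")
        if not (self.v_inh <= self.v_leak < self.v_thr < self.v_exc):
            raise ParameterError("require v_inh <= v_leak < v_thr < v_exc")


EXCITATORY = NeuronClassParams(tau_m=20.0)
INHIBITORY = NeuronClassParams(tau_m=10.0)


@dataclass(frozen=True)
class LogNormalEpspSpec:
    """Truncated log-normal distribution of EE EPSP amplitudes (mV).

    The density is ``p(x) = exp(-(ln x - mu)^2 / 2 sigma^2) / (sqrt(2 pi)
    sigma x)`` with the location ``mu`` fixed by the requested mode:
    ``mode = exp(mu - sigma^2)``.  Samples above ``vmax_mv`` are rejected
    and redrawn.  Amplitudes above ``strong_threshold_mv`` define the
    "strong" synapses.
    """

    sigma: float = 1.0
    mode_mv: float = 0.2
    vmax_mv: float = 20.0
    strong_threshold_mv: float = 9.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.mode_mv <= 0:
            raise ParameterError("mode_mv must be positive")
        if self.vmax_mv <= self.mode_mv:
            raise ParameterError("vmax_mv must exceed the mode")

    @property
    def mu(self) -> float:
        """Location parameter: ln(mode) + sigma^2."""
        return math.log(self.mode_mv) + self.sigma**2

    def distribution(self):
        """The untruncated log-normal as a frozen scipy distribution."""
        return stats.lognorm(s=self.sigma, scale=math.exp(self.mu))

    def truncated_cdf(self, x) -> np.ndarray:
        """CDF of the distribution truncated to (0, vmax_mv]."""
        d = self.distribution()
        z = d.cdf(self.vmax_mv)
        return np.clip(d.cdf(x) / z, 0.0, 1.0)

    def tail_mass(self, lo_mv: float) -> float:
        """Probability mass of the truncated distribution above ``lo_mv``."""
        d = self.distribution()
        return float((d.cdf(self.vmax_mv) - d.cdf(lo_mv)) / d.cdf(self.vmax_mv))


@dataclass(frozen=True)
class NetworkSpec:
    """Population sizes, coupling probabilities and fixed synapse constants.

    ``ei_ratio`` is the pair (N_E, N_I); excitatory neurons occupy ids
    [0, N_E) and inhibitory ids [N_E, N_E + N_I).  Coupling probabilities
    are outgoing: each ordered (pre, post) pair is connected independently
    with the probability of the presynaptic class.  Weights are in
    conductance units (1/ms).
    """

    n_total: int = 12000
    ei_ratio: tuple[int, int] = (9600, 2400)
    p_conn_exc: float = 0.1
    p_conn_inh: float = 0.5
    g_ei: float = 0.018
    g_ie: float = 0.002
    g_ii: float = 0.0025
    delay_ee_ms: tuple[float, float] = (1.0, 3.0)
    delay_other_ms: tuple[float, float] = (0.0, 2.0)
    a_mv: float = 0.1         # failure constant in P = a / (a + V_EPSP)
    remove_strong: bool = False

    def __post_init__(self) -> None:
        n_e, n_i = self.ei_ratio
        if n_e < 1 or n_i < 1:
            raise ParameterError("need at least one neuron of each class")
        if n_e + n_i != self.n_total:
            raise ParameterError("ei_ratio must partition n_total")
        for p in (self.p_conn_exc, self.p_conn_inh):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("coupling probabilities must lie in [0, 1]")
        for lo, hi in (self.delay_ee_ms, self.delay_other_ms):
            if lo < 0 or hi < lo:
                raise ParameterError("delay ranges must satisfy 0 <= low <= high")
        if self.a_mv <= 0:
            raise ParameterError("failure constant a_mv must be positive")

    @property
    def n_e(self) -> int:
        return self.ei_ratio[0]

    @property
    def n_i(self) -> int:
        return self.ei_ratio[1]


@dataclass
class SynapseTable:
    """All synapses of one built network, one row per directed connection.

    Columns: pre_id, post_id, class_pair (EE/EI/IE/II), weight (1/ms),
    delay_ms, epsp_mv (EE only, NaN elsewhere), p_fail (0 for non-EE).
    """

    df: pd.DataFrame
    n_e: int
    n_i: int

    def __post_init__(self) -> None:
        missing = [c for c in _SYNAPSE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ParameterError(f"synapse table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_total(self) -> int:
        return self.n_e + self.n_i

    def rows(self, class_pair: str) -> pd.DataFrame:
        return self.df[self.df["class_pair"] == class_pair]

    def equals(self, other: "SynapseTable") -> bool:
        return (
            self.n_e == other.n_e
            and self.n_i == other.n_i
            and self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))
        )

    def write_tsv(self, path) -> None:
        header = f"# n_e={self.n_e}\tn_i={self.n_i}\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SynapseTable":
        with open(path) as fh:
            first = fh.readline()
            meta = dict(kv.split("=") for kv in first.lstrip("# ").split())
            df = pd.read_csv(fh, sep="\t")
        df["class_pair"] = df["class_pair"].astype("category")
        return cls(df=df, n_e=int(meta["n_e"]), n_i=int(meta["n_i"]))


def sample_epsp_amplitudes(
    n: int, spec: LogNormalEpspSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` EPSP amplitudes (mV) by rejection from the truncated log-normal.

    Values above ``spec.vmax_mv`` are redrawn, not clipped, so the returned
    sample follows the renormalized density on (0, vmax_mv].
    """
    if n < 0:
        raise ParameterError("n must be non-negative")
    out = rng.lognormal(mean=spec.mu, sigma=spec.sigma, size=n)
    bad = out > spec.vmax_mv
    while bad.any():
        out[bad] = rng.lognormal(mean=spec.mu, sigma=spec.sigma, size=int(bad.sum()))
        bad = out > spec.vmax_mv
    return out


def epsp_to_conductance(epsp_mv) -> np.ndarray | float:
    """Convert an EPSP amplitude (mV) to a synaptic weight (1/ms): V/100.

    The division by 100 is a calibration of the two-ODE single-synapse
    response (see :func:`calibrate_single_epsp`), accurate to ~15 % over the
    physiological amplitude range.
    """
    arr = np.asarray(epsp_mv, dtype=float)
    if np.any(arr <= 0):
        raise ParameterError("EPSP amplitude must be positive")
    out = arr / 100.0
    return float(out) if np.isscalar(epsp_mv) else out


def calibrate_single_epsp(
    weight: float,
    params: NeuronClassParams = EXCITATORY,
    dt: float = 0.01,
    t_max_ms: float = 100.0,
) -> float:
    """Peak depolarization (mV) evoked by one excitatory spike of the given weight.

    Integrates, with the forward Euler method, the two-variable system of a
    passive membrane receiving a single delta input on its excitatory
    conductance at t = 0:

        dv/dt = -(v - V_L)/tau_m - g(v - V_E),   dg/dt = -g/tau_s,

    from v(0) = V_L, g(0) = weight, and returns max_t v(t) - V_L.  This is
    the reference against which the V/100 conductance rule is calibrated.
    """
    if weight < 0:
        raise ParameterError("weight must be non-negative")
    if dt <= 0 or dt > 0.1:
        raise ParameterError("dt must be in (0, 0.1] ms")
    n = int(round(t_max_ms / dt))
    v = params.v_leak
    g = weight
    peak = 0.0
    for _ in range(n):
        dv = -(v - params.v_leak) / params.tau_m - g * (v - params.v_exc)
        v += dt * dv
        g += dt * (-g / params.tau_s)
        if v - params.v_leak > peak:
            peak = v - params.v_leak
    return peak


def _bernoulli_edges(
    n_sources: int,
    n_total: int,
    p: np.ndarray,
    rng: np.random.Generator,
    chunk: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Directed Erdős–Rényi edges, sources 0..n_sources-1, no autapses.

    ``p`` gives the per-source outgoing probability.  Draws are chunked over
    sources with a fixed chunk size so that the result is deterministic for
    a given generator state and bounded in memory at publication scale.
    """
    pres, posts = [], []
    for lo in range(0, n_sources, chunk):
        hi = min(lo + chunk, n_sources)
        u = rng.random((hi - lo, n_total))
        mask = u < p[lo:hi, None]
        rows = np.arange(lo, hi)
        mask[rows - lo, rows] = False  # no self-connections
        r, c = np.nonzero(mask)
        pres.append((r + lo).astype(np.int32))
        posts.append(c.astype(np.int32))
    if not pres:
        return np.empty(0, np.int32), np.empty(0, np.int32)
    return np.concatenate(pres), np.concatenate(posts)


def build_network(
    spec: NetworkSpec,
    epsp_spec: LogNormalEpspSpec | None = None,
    seed: int = 0,
    trial: int = 0,
) -> SynapseTable:
    """Build one random network realization.

    Each ordered (pre, post) pair, pre != post, is connected independently
    with the outgoing probability of the presynaptic class.  EE rows get a
    sampled EPSP amplitude, the V/100 weight and the failure probability
    a/(a + V); EI/IE/II rows get the fixed class constants.  Delays are
    uniform per class.  Topology, amplitudes and delays come from separate
    named streams derived from (seed, trial), so rebuilding with the same
    pair reproduces the network exactly.
    """
    if epsp_spec is None:
        epsp_spec = LogNormalEpspSpec()
    rng_topo = streams.stream_rng(seed, streams.TOPOLOGY, trial)
    rng_epsp = streams.stream_rng(seed, streams.EPSP_AMPLITUDES, trial)
    rng_delay = streams.stream_rng(seed, streams.DELAYS, trial)

    n_e, n_i, n = spec.n_e, spec.n_i, spec.n_total
    p = np.where(np.arange(n) < n_e, spec.p_conn_exc, spec.p_conn_inh)
    pre, post = _bernoulli_edges(n, n, p, rng_topo)

    pre_exc = pre < n_e
    post_exc = post < n_e
    class_pair = np.where(
        pre_exc,
        np.where(post_exc, "EE", "EI"),
        np.where(post_exc, "IE", "II"),
    )

    weight = np.empty(len(pre), dtype=float)
    epsp = np.full(len(pre), np.nan)
    p_fail = np.zeros(len(pre), dtype=float)
    delay = np.empty(len(pre), dtype=float)

    ee = pre_exc & post_exc
    n_ee = int(ee.sum())
    amps = sample_epsp_amplitudes(n_ee, epsp_spec, rng_epsp)
    epsp[ee] = amps
    weight[ee] = amps / 100.0
    p_fail[ee] = spec.a_mv / (spec.a_mv + amps)
    weight[pre_exc & ~post_exc] = spec.g_ei
    weight[~pre_exc & post_exc] = spec.g_ie
    weight[~pre_exc & ~post_exc] = spec.g_ii

    lo, hi = spec.delay_ee_ms
    delay[ee] = rng_delay.uniform(lo, hi, n_ee)
    lo, hi = spec.delay_other_ms
    delay[~ee] = rng_delay.uniform(lo, hi, int((~ee).sum()))

    df = pd.DataFrame(
        {
            "pre_id": pre,
            "post_id": post,
            "class_pair": pd.Categorical(class_pair, categories=["EE", "EI", "IE", "II"]),
            "weight": weight,
            "delay_ms": delay,
            "epsp_mv": epsp,
            "p_fail": p_fail,
        }
    )
    table = SynapseTable(df=df, n_e=n_e, n_i=n_i)
    if spec.remove_strong:
        table = remove_strong_synapses(table, epsp_spec.strong_threshold_mv)
    return table


def remove_strong_synapses(table: SynapseTable, threshold_mv: float = 9.0) -> SynapseTable:
    """Delete every EE synapse with EPSP amplitude above ``threshold_mv``.

    Non-EE rows are untouched; applying the operation twice is the same as
    applying it once.
    """
    df = table.df
    drop = (df["class_pair"] == "EE") & (df["epsp_mv"] > threshold_mv)
    return SynapseTable(df=df[~drop].reset_index(drop=True), n_e=table.n_e, n_i=table.n_i)
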
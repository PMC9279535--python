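# Methods

## Model

`ssrnet` simulates a recurrent network of `N = N_E + N_I` conductance-based
leaky-integrate-and-fire neurons (excitatory ids `[0, N_E)`, inhibitory
`[N_E, N)`):

    dv/dt   = -(v - V_L)/tau_m - g_E (v - V_E) - g_I (v - V_I) + I_ex
    dg_X/dt = -g_X/tau_s + sum_j G_{X,j} sum_s delta(t - s_j - d_j)

with threshold/reset (`v >= V_thr` → spike, `v → V_r`) and a 1 ms absolute
refractory period. Parameters (mV, ms): `V_L = -70`, `V_E = 0`, `V_I = -80`,
`V_r = -60`, `V_thr = -50`, `tau_m = 20` (E) / `10` (I), `tau_s = 2`.

Connectivity is directed Erdős–Rényi with outgoing probability 0.1 for
excitatory and 0.5 for inhibitory sources, no autapses, no multi-edges.
EE synapses carry EPSP amplitudes `V` from a log-normal density
`p(x) = exp(-(ln x - mu)^2 / 2 sigma^2) / (sqrt(2 pi) sigma x)` with
`sigma = 1`, mode `exp(mu - sigma^2) = 0.2` mV (natural logarithm
throughout, so both parameters live on one scale), rejection-resampled
above 20 mV. Amplitude maps to conductance weight as `G = V/100` (1/ms),
and each delivery independently fails with probability `P = a/(a + V)`,
`a = 0.1` mV — weak-dense, strong-sparse-reliable coupling. EI/IE/II
weights are fixed at 0.018 / 0.002 / 0.0025. Delays are uniform: EE in
[1, 3] ms, all other classes in [0, 2] ms. "Strong" synapses are EE rows
with `V > 9` mV; the ablated control deletes them (the distribution is not
resampled), which at full size removes a few rows per excitatory neuron
(the truncated tail mass above 9 mV is ≈ 2.5e-3, i.e. ≈ 2.4 expected
strong out-synapses per excitatory neuron at `N_E = 9600`, `p = 0.1`).

The `V/100` rule is a calibration of the two-ODE single-synapse response
(passive membrane + one conductance kick); `calibrate_single_epsp`
integrates that system and is kept as an independent oracle — the rule
reproduces the ODE peak within 15 % over `V` in [0.1, 10] mV.

## Stimulus

The external drive is periodic and windowed: during the first 1 ms of
every period `1/F_s`, each neuron receives Poisson events at `Lambda = 1`
Hz (zero outside the window); each event jumps the membrane by 21 mV,
which exceeds the 20 mV threshold-to-rest distance, so an event in a
non-refractory neuron evokes a spike. Directly evoked per-neuron rate:
`F_s * Lambda / 1000` Hz. Frequencies are realized as integer periods
(25, 12, 11, 7 ms); analyses use the exact values `1000/period`
(40, 83.33, 90.91, 142.86 Hz). One stimulus realization is shared by all
trials of a condition; everything else is reseeded per trial.

## Integration

Forward Euler, `dt = 0.1` ms, with per-step order: conductance decay →
arrival of delayed increments → stimulus jumps → voltage update →
threshold/reset. This order makes the single-event spike guarantee exact.
Choices for the cases the continuous equations leave open:

- During refractoriness `v` is clamped at `V_r` and not integrated;
  stimulus jumps landing there are lost; conductances keep evolving.
- Delta inputs are instantaneous increments (`g += G`, `v += 21`), the
  exact integral of the delta under Euler.
- Delays are drawn continuously at build time and rounded to the grid at
  scheduling, floored at one step so a delivery never lands in the step
  that produced it.
- Spike times are recorded at the start-of-step grid time of the crossing.
- Initial `v` uniform on `[V_L, V_thr)` per neuron; initial conductances 0.
- A non-finite state or spike-buffer overflow raises an integration error
  carrying the failure time.

Named, separate RNG streams (topology, amplitudes, delays, initial state,
transmission failure, stimulus) derive from `numpy.random.SeedSequence`
keyed by (base seed, stream id, trial), so the phase-coherence protocol
can pin the stimulus while reseeding the rest. The hot loop is
numba-compiled; transmission failures use a dedicated 31-bit seed.

## Evaluation indices

Population rate `r_X(t) = 1000 S_X(t) / (dt N_X)` Hz in 0.1 ms bins,
smoothed with a unit-mass Gaussian kernel (`sigma = 10` ms, truncated at
±4σ, edge-renormalized so constants are preserved). The excitatory series
is restricted to the [3, 7] s analysis window and z-scored (population
SD), then:

- **PSD**: single-segment rectangular-window periodogram of the 4 s
  window (0.25 Hz grid), one-sided, normalized so total power equals the
  window variance (= 1 after z-scoring). Per-trial periodograms are
  averaged; spread is the sample SD (n−1) across trials.
- **ITPC**: `|mean_m F_m(f)/|F_m(f)||` over trials on the same grid —
  identically the mean resultant length of per-trial phases, clipped at 1
  against rounding. Trials with an exactly zero coefficient at a frequency
  are excluded there (warned); the ITPC has no per-trial value, so its
  error bar is a leave-one-out jackknife SE.
- **Band means**: arithmetic means over grid frequencies in the closed
  interval `[F_s − Δf, F_s + Δf]`, `Δf ∈ {1, 2, 3}` Hz, for both indices.

Smoothing precedes z-scoring and both spectral indices; PSD and ITPC
share one frequency grid so band means are comparable. Both choices are
config-visible in `analyze_record`/`summarize_trials`.

## Experiment grid

A condition = (E/I ratio, stimulus period, strong-synapse flag); the sweep
covers ratios 3:1 … 9:1 (integer partitions of 12000, e.g. 6:1 →
10286/1714), the four periods, both flags, 10 trials each. Trial `m`
rebuilds the network (topology, amplitudes, delays), redraws initial
state and failure stream, reuses the condition's stimulus. Degenerate
trials (silent analysis window, zero variance) are flagged and excluded
from spectra rather than poisoning them.

## Synthetic fixtures

`make_phase_jittered_trials` produces sinusoidal trials with von Mises
phase jitter: expected ITPC at the carrier is the Bessel ratio
`I1(kappa)/I0(kappa)`, giving the analysis stack an analytically known
target. `make_inhomogeneous_poisson_spikes` generates population spike
trains with a prescribed rate profile via Poisson superposition (counts
per bin are population-Poisson, events attributed to uniform neurons) —
statistically identical to independent per-neuron thinning for every
population-level index computed here, though it does not enforce
per-neuron refractoriness. `scaled_preset(scale)` shrinks the 12000-neuron
configuration while preserving coupling probabilities and weights.

What the fixtures do *not* emulate: recurrent correlations, refractory
structure, or the stimulus-locked higher harmonics of the simulator —
passing fixture-based tests validates the analysis stages, not the
network dynamics.

## Regimes, problem sizes and known limitations

- **Scaling shrinks in-degree.** Preserving probabilities means a
  `scale`-fold network has `scale`-fold EE in-degree (~96 at 1200 vs ~960
  at 12000). Measured ignition of recurrent autonomous activity sits
  between scale 0.7 and 0.85 (~700–800 in-degree): below it the network is
  a pure relay — every spike is a direct stimulus response, trials of a
  condition are (near-)identical and ITPC ≈ 1 at every frequency. Scaled
  runs therefore exercise the pipeline, not the paper-scale dynamics;
  quantitative claims about E/I-ratio dependence are meaningful only at
  scale 1.
- **Ignition at full scale is stochastic.** At 12000 neurons, 4:1, with
  strong synapses, some realizations ignite self-sustained ~2 Hz activity
  within seconds while others remain in the ~0.04 Hz relay regime for the
  whole 7 s trial — the model family is bistable between quiescence and
  low-rate autonomous firing. Tests assert the broad non-runaway band
  (0.02–20 Hz) rather than a point rate.
- **Problem sizes used by the test suite and the acceptance script** (the
  package's own choices for desk-scale validation): distribution checks at
  1e5–1e6 samples; delivery/failure statistics at 1e4 events; stimulus-rate
  recovery at 10,000 uncoupled neurons × 100 s (acceptance) and 2,000 × 25 s
  (tests); the qualitative pipeline smoke at 1200 neurons × 10 trials; one
  full-scale 3 s regime check. The full published grid (~56 conditions ×
  10 trials at 12000 neurons × 7 s) runs in hours via
  `ssrnet sweep --scale 1` and is not part of the default suite.
- Tolerances: stochastic checks use 3 standard errors of the relevant
  counting statistic; oracle equivalences use machine-precision bounds
  (1e-12) where exact identity is the contract, and the stated 15 % for
  the `V/100` calibration rule.
- Not modeled (out of scope): inter-regional coupling, voltage-dependent
  (NMDA-like) currents, E/I manipulation via inhibitory conductance
  amplitude, plasticity, non-periodic naturalistic stimuli, clustered or
  distance-dependent topologies.
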
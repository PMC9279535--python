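"""Named, independent random-number streams.

Every stochastic ingredient of a simulated condition draws from its own
stream so that the inter-trial phase-coherence protocol can hold the
stimulus realization fixed across trials while the network topology,
synaptic amplitudes, delays, initial membrane potentials and transmission
failures are reseeded per trial.  Streams are derived from a single base
seed with :class:`numpy.random.SeedSequence`, keyed by (base seed, stream
id, trial index).
"""

from __future__ import annotations

import numpy as np

# stream identifiers
TOPOLOGY = 1
EPSP_AMPLITUDES = 2
DELAYS = 3
INITIAL_STATE = 4
TRANSMISSION_FAILURE = 5
STIMULUS = 6


def stream_rng(base_seed: int, stream: int, trial: int = 0) -> np.random.Generator:
    """A Generator for the given (base seed, stream, trial) triple."""
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), int(stream), int(trial)])
    )


def stream_seed32(base_seed: int, stream: int, trial: int = 0) -> int:
    """A 31-bit integer seed for the same triple (for legacy-style PRNGs)."""
    ss = np.random.SeedSequence([int(base_seed), int(stream), int(trial)])
    return int(ss.generate_state(1)[0] % (2**31))
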
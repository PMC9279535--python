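"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An input parameter violates its documented contract."""


class DegenerateInputError(ValueError):
    """A computation received input it cannot meaningfully process
    (e.g. z-scoring a window with zero variance)."""


class IntegrationError(RuntimeError):
    """Numerical integration failed (non-finite state or spike-buffer
    overflow); carries the simulation time at which it happened."""

    def __init__(self, message: str, time_ms: float | None = None):
        super().__init__(message)
        self.time_ms = time_ms
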
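"""Exception types shared by the simulators."""


class DivergenceError(RuntimeError):
    """A trajectory exceeded the divergence guard.

    Raised with enough context (step index, time, offending element) to
    identify where an unstable configuration blew up.  Unstable regimes are
    expected for some parameter ranges; they must fail loudly rather than
    overflow silently.
    """

    def __init__(self, message: str, step: int | None = None,
                 time: float | None = None, element: int | None = None):
        super().__init__(message)
        self.step = step
        self.time = time
        self.element = element


class SilentSignalError(ValueError):
    """An analysis was requested on a signal with no usable content."""
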
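"""Exception types shared across the package."""


class PolybridgeError(Exception):
    """Base class for package-specific errors."""


class StabilityError(PolybridgeError):
    """A Brownian-dynamics step moved a particle too far in one update.

    Carries the offending particle index and the step number at which the
    integrator detected the runaway displacement.
    """

    def __init__(self, message: str, particle: int | None = None, step: int | None = None):
        super().__init__(message)
        self.particle = particle
        self.step = step


class ParseError(PolybridgeError):
    """A text input (BED track, TSV table, config) failed validation.

    ``line`` is the 1-based line number of the offending record where known.
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class IntegrityError(PolybridgeError):
    """A file read back from disk violates a structural invariant."""
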
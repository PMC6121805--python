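"""Exception hierarchy for shoreclines."""


class ShoreclinesError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(ShoreclinesError):
    """Degenerate coordinate input (e.g. all points identical)."""


class MissingDataError(ShoreclinesError):
    """Required observations are absent (e.g. empty habitat survey)."""


class InvalidParameterError(ShoreclinesError, ValueError):
    """A model parameter violates its domain (e.g. non-positive cline width)."""


class UndefinedSlopeError(ShoreclinesError):
    """Slope requested for a model without a cline (the constant-frequency null)."""


class ZeroRangeError(ShoreclinesError):
    """A quantitative trait is constant and cannot be rescaled to [0, 1]."""


class DegenerateDataError(ShoreclinesError):
    """Data carry no contrast for the requested fit (e.g. single-class morph)."""


class SimulationFailureError(ShoreclinesError):
    """A deme went extinct during the forward simulation."""

    def __init__(self, generation: int, deme: int):
        self.generation = generation
        self.deme = deme
        super().__init__(
            f"all individuals lost from deme {deme} at generation {generation}"
        )


class InsufficientNullError(ShoreclinesError):
    """Too few simulated neutral loci to define a var.ex threshold."""


class ConfigurationError(ShoreclinesError):
    """Invalid or inconsistent run configuration."""
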
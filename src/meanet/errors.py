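"""Exception hierarchy shared across the package."""


class MeaError(Exception):
    """Base class for all meanet errors."""


class FormatError(MeaError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(MeaError):
    """Inputs that must agree (channel counts, layouts, grids) do not."""


class ValidationError(MeaError, ValueError):
    """A value violates a documented invariant."""


class InsufficientDataError(MeaError):
    """Not enough data to compute the requested quantity."""


class DegenerateInputError(MeaError):
    """Input is degenerate for this operation (zero variance, zero baseline...)."""
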
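"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2,
CapacityError / SamplingError -> 3.
"""


class EvographError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EvographError, ValueError):
    """Invalid parameters or malformed input data."""


class CapacityError(EvographError, RuntimeError):
    """Problem size exceeds what a solver or simulator supports."""


class SamplingError(EvographError, RuntimeError):
    """A rejection sampler exhausted its draw budget."""
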
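"""Exception hierarchy.

Everything raised on bad data or bad configuration derives from
:class:`MFEScreenError` so callers (and the CLI) can catch one type.
"""


class MFEScreenError(Exception):
    """Base class for all mfescreen errors."""


class InvalidRateError(MFEScreenError):
    """Target sampling rate violates the Nyquist requirement for the beta band."""


class TooShortError(MFEScreenError):
    """Recording too short for the requested number of epochs."""


class DegenerateChannelError(MFEScreenError):
    """A channel is flat (max equals min), normalization undefined."""


class ConfigError(MFEScreenError):
    """Invalid or inconsistent configuration."""


class MontageError(MFEScreenError):
    """Input channels do not cover the required 10-20 montage."""


class InsufficientCohortError(MFEScreenError):
    """Fewer than two subjects in a reference group."""


class IncompatibleConfigError(MFEScreenError):
    """Mixing artifacts produced under different configuration fingerprints."""


class SchemaError(MFEScreenError):
    """Malformed or version-mismatched serialized model/report."""
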
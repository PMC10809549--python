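"""Exception hierarchy shared across the package."""


class KaryoshuffleError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KaryoshuffleError):
    """A file does not conform to the expected dialect."""


class ValidationError(KaryoshuffleError):
    """Input data violates a documented invariant."""
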
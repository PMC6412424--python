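"""Exception hierarchy."""


class EcgParafitError(Exception):
    """Base class for package errors."""


class FormatError(EcgParafitError):
    """A file could not be parsed in the expected format."""


class ValidationError(EcgParafitError):
    """Input data violates a documented invariant."""
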
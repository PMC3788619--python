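"""Exception hierarchy for phosphorewire."""


class PhosphoRewireError(Exception):
    """Base class for all package errors."""


class FormatError(PhosphoRewireError):
    """A file or record violates the expected format or an invariant."""


class DegenerateModelError(PhosphoRewireError):
    """A PWM carries no information at any scored column (Max == Min)."""
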
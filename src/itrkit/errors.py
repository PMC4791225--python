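"""Exception hierarchy shared across itrkit modules."""


class ItrkitError(Exception):
    """Base class for all itrkit errors."""


class FormatError(ItrkitError):
    """A file does not conform to its declared format (missing columns,
    malformed lines). Carries the offending path/line where known."""


class ValidationError(ItrkitError):
    """Content is well-formed but violates a domain invariant
    (non-positive weight, score outside [0,1], duplicate gene rows...)."""


class EmptySignatureError(ItrkitError):
    """A gene signature ended up empty; downstream scoring refuses it."""
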
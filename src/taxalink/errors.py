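"""Exception hierarchy shared across the package."""


class TaxalinkError(Exception):
    """Base class for all errors raised by taxalink."""


class FormatError(TaxalinkError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(TaxalinkError):
    """Parsed data violates a domain invariant (duplicates, negatives, ...)."""
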
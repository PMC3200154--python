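"""Exception hierarchy shared across enscon modules."""


class EnsconError(Exception):
    """Base class for all enscon errors."""


class StructureError(EnsconError):
    """A structural model file is missing, unreadable or unusable."""


class FormatError(EnsconError):
    """A text input (RR file, domain string, quality table) is malformed."""


class DataError(EnsconError):
    """Inputs are well-formed but inconsistent (e.g. missing quality scores)."""
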
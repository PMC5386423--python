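"""Exception hierarchy for the pipeline."""


class CnvModError(Exception):
    """Base class for all package errors."""


class FormatError(CnvModError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(CnvModError):
    """Parsed data violate a domain invariant."""


class InsufficientDataError(CnvModError):
    """Too few usable observations to compute a quantity."""


class AscertainmentError(CnvModError):
    """A sampling stratum could not be filled under the given parameters."""
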
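class VtquantError(Exception):
    """Base class for all package errors."""


class FormatError(VtquantError):
    """Malformed input file (bad columns, unparsable field, duplicate id...)."""


class DataError(VtquantError):
    """Structurally valid input that violates a method precondition."""
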
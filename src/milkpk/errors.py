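"""Exception hierarchy."""


class MilkPKError(Exception):
    """Base class for all package errors."""


class ValidationError(MilkPKError):
    """Invalid input data (bad record fields, malformed tables)."""


class DomainError(MilkPKError):
    """A quantity left its mathematical domain (e.g. non-positive S/W denominator)."""


class UnsupportedDrugClassError(MilkPKError):
    """The requested model has no formula for this charge class."""


class UnknownModelError(MilkPKError):
    """Model name not found in the registry."""
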
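"""Exception hierarchy for the converter.

All fatal conditions raise a subclass of :class:`ConversionError`, so the
command-line front end can distinguish expected failures (bad input, format
limits) from programming errors.
"""


class ConversionError(Exception):
    """Base class for every error the converter raises on purpose."""


class InputError(ConversionError):
    """The input file cannot be opened or read."""


class CifParseError(ConversionError):
    """The input is not syntactically valid mmCIF."""


class StructureError(ConversionError):
    """The parsed tables do not describe a usable structure."""


class FieldOverflowError(ConversionError):
    """A value cannot be represented within a fixed-width PDB field."""


class ContractError(ConversionError):
    """An internal precondition was violated by the caller."""
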
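"""Faithful mmCIF to legacy PDB conversion with Best Effort/Minimal bundles.

Public surface::

    from cif2pdb import convert_file            # one-call conversion
    from cif2pdb.reader import open_input, tokenize, parse_categories
    from cif2pdb.model import build_document
    from cif2pdb.bundle import plan_bundle, render_file
    from cif2pdb.fixtures import FixtureSpec, generate_cif
"""

from .cli import ConvertOptions, run_convert
from .errors import (
    CifParseError,
    ContractError,
    ConversionError,
    FieldOverflowError,
    InputError,
    StructureError,
)
from .model import StructureDoc, build_document
from .reader import open_input, parse_categories, tokenize

__version__ = "1.0.0"


def convert_file(input_path, **kwargs) -> int:
    """Convert ``input_path`` with :class:`ConvertOptions` keyword overrides."""
    return run_convert(input_path, ConvertOptions(**kwargs))


__all__ = [
    "CifParseError",
    "ContractError",
    "ConversionError",
    "ConvertOptions",
    "FieldOverflowError",
    "InputError",
    "StructureDoc",
    "StructureError",
    "build_document",
    "convert_file",
    "open_input",
    "parse_categories",
    "run_convert",
    "tokenize",
    "__version__",
]
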
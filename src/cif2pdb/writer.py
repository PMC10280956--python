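"""Fixed-width PDB v3.3 record formatter.

The central design rule: values arriving from the mmCIF parser are strings
and stay strings.  A coordinate like ``"24.430"`` is padded into its
8-column field exactly as written; no float round-trip ever reformats it.
Only when a value is wider than its field does :func:`pad_field` fall back
to decimal rounding (round-half-even), and only ANISOU converts numbers on
purpose, because the PDB format stores anisotropic U values as integers
scaled by 10⁴ while mmCIF stores Å² decimals.

Two chain-ID styles are supported: the Best Effort/Minimal bundle style
(single-character chain ID in column 22) and the Phenix style, which packs
a two-character chain ID into columns 21–22, column 21 being unused by the
legacy format.

Overflow conventions for oversized identifiers:

* residue numbers of 5 digits spill their last digit into column 27, the
  insertion-code column (the insertion code is then dropped);
* residue names longer than 3 characters are remapped to the reserved
  chemical component IDs ``01``–``99``, ``DRG``, ``INH``, ``LIG``, which the
  PDB will never assign to a real component.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation, ROUND_HALF_EVEN

from .errors import ContractError, FieldOverflowError, StructureError
from .model import (
    AnisoRecord,
    AtomRecord,
    Citation,
    DbRef,
    HeaderMeta,
    PolymerSeq,
    UnitCell,
    blank,
)

logger = logging.getLogger(__name__)

#: a PDB record is a plain string of exactly 80 characters
PdbLine = str

LINE_WIDTH = 80


@dataclass(frozen=True)
class ChainStyle:
    """How chain IDs are written: column 22 only, or columns 21-22."""

    mode: str  # "bundle_single_char" | "phenix_two_char"

    @property
    def max_chain_chars(self) -> int:
        return 1 if self.mode == "bundle_single_char" else 2


STYLE_BUNDLE = ChainStyle("bundle_single_char")
STYLE_PHENIX = ChainStyle("phenix_two_char")


def _pad80(text: str) -> PdbLine:
    if len(text) > LINE_WIDTH:
        raise ContractError(f"record longer than 80 columns: {text!r}")
    return text.ljust(LINE_WIDTH)


def pad_field(
    value: str,
    width: int,
    justify: str = "right",
    *,
    record: str = "",
    columns: str = "",
) -> str:
    """Pad ``value`` into a fixed-width field without reformatting it.

    If the value is wider than the field and is numeric, decimal places are
    reduced (round-half-even) until it fits; a non-numeric over-width value
    raises :class:`FieldOverflowError` naming the record and column range.
    """
    if len(value) <= width:
        return value.rjust(width) if justify == "right" else value.ljust(width)
    where = f" in {record} columns {columns}" if record else ""
    try:
        d = Decimal(value)
    except InvalidOperation:
        raise FieldOverflowError(
            f"value {value!r} does not fit {width} columns{where}"
        ) from None
    int_len = len(f"{d.quantize(Decimal(1), rounding=ROUND_HALF_EVEN):f}")
    max_places = width - int_len - 1
    for places in range(max(max_places, 0), -1, -1):
        q = d.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_EVEN)
        s = f"{q:f}"
        if len(s) <= width:
            return s.rjust(width) if justify == "right" else s.ljust(width)
    raise FieldOverflowError(
        f"numeric value {value!r} does not fit {width} columns even with "
        f"no decimal places{where}"
    )


def _fixed(value: str, width: int, places: int) -> str:
    """Right-justify ``value`` reformatted to exactly ``places`` decimals.

    Used by CRYST1, whose fields conventionally carry a fixed number of
    decimals (``"90"`` becomes ``"90.00"``).  Falls back to
    :func:`pad_field` when the canonical form is too wide.
    """
    try:
        q = Decimal(value).quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_EVEN)
        s = f"{q:f}"
    except InvalidOperation:
        s = value
    if len(s) > width:
        return pad_field(value, width, record="CRYST1")
    return s.rjust(width)


def format_residue_number(res_seq: str, icode: str, *, context: str = "") -> str:
    """Render columns 23-27: residue number plus insertion code.

    Numbers of up to 4 characters are right-justified in columns 23-26 with
    the insertion code in column 27.  A 5-digit number fills all five
    columns; its insertion code is discarded with a warning.  Anything wider
    exceeds the capacity of the legacy format and is fatal.
    """
    icode = blank(icode)[:1]
    if len(res_seq) <= 4:
        return res_seq.rjust(4) + (icode or " ")
    if len(res_seq) == 5:
        if icode:
            logger.warning(
                "insertion code %r of residue %s%s discarded: column 27 holds "
                "the 5th digit", icode, res_seq, f" ({context})" if context else "",
            )
        return res_seq
    raise FieldOverflowError(
        f"residue number {res_seq} exceeds PDB capacity (max 99999)"
    )


class ResnameRegistry:
    """Stable mapping of over-long residue names to reserved component IDs.

    The pool ``01``-``99``, ``DRG``, ``INH``, ``LIG`` is consumed in that
    order; a repeated input name reuses its assignment.  Assignments are
    exposed via :attr:`assigned` for the conversion report.
    """

    POOL: tuple[str, ...] = tuple(f"{i:02d}" for i in range(1, 100)) + (
        "DRG",
        "INH",
        "LIG",
    )

    def __init__(self) -> None:
        self.assigned: dict[str, str] = {}

    def map(self, res_name: str) -> str:
        if len(res_name) <= 3:
            return res_name
        alias = self.assigned.get(res_name)
        if alias is not None:
            return alias
        if len(self.assigned) >= len(self.POOL):
            raise FieldOverflowError(
                "reserved chemical component ID pool exhausted: more than "
                f"{len(self.POOL)} distinct residue names longer than 3 characters"
            )
        alias = self.POOL[len(self.assigned)]
        self.assigned[res_name] = alias
        logger.info("long residue name %s written as reserved ID %s", res_name, alias)
        return alias


def map_long_resname(res_name: str, registry: ResnameRegistry) -> str:
    """Functional wrapper around :meth:`ResnameRegistry.map`."""
    return registry.map(res_name)


_CHARGE_SIGN_FIRST = re.compile(r"[+-]\d$")
_CHARGE_DIGIT_FIRST = re.compile(r"\d[+-]$")


def _format_charge(charge: str) -> str:
    """Columns 79-80; PDB wants digit-then-sign, e.g. ``2-``."""
    c = blank(charge)
    if not c or c == "0":
        return "  "
    if _CHARGE_SIGN_FIRST.match(c):
        return c[1] + c[0]
    if _CHARGE_DIGIT_FIRST.match(c):
        return c
    return c[:2].ljust(2)


def _format_atom_name(name: str, element: str) -> str:
    """Columns 13-16.  Names of single-letter elements start at column 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def _chain_field(out_chain: str, style: ChainStyle) -> str:
    """Columns 21-22."""
    if style.max_chain_chars == 1:
        if len(out_chain) != 1:
            raise ContractError(
                f"bundle-style output requires a single-character chain ID, "
                f"got {out_chain!r}; remap chains first"
            )
        return " " + out_chain
    if len(out_chain) > 2 or not out_chain:
        raise ContractError(
            f"phenix-style output supports at most two chain-ID characters, "
            f"got {out_chain!r}"
        )
    return out_chain.rjust(2)


def _atom_prefix(
    record: str,
    atom: AtomRecord,
    serial: str,
    out_chain: str,
    style: ChainStyle,
    res_name: str,
) -> str:
    """Columns 1-27, shared between ATOM/HETATM and ANISOU."""
    if len(serial) > 5:
        raise ContractError(f"atom serial {serial!r} does not fit 5 columns")
    element = blank(atom.element).strip()
    name_f = _format_atom_name(atom.atom_name, element)
    alt = blank(atom.alt_loc)[:1] or " "
    if len(res_name) > 3:
        raise ContractError(
            f"residue name {res_name!r} not remapped to 3 characters"
        )
    resnum = format_residue_number(
        atom.res_seq, atom.icode, context=f"chain {atom.chain_id}"
    )
    return (
        f"{record:<6}{serial:>5} {name_f}{alt}{res_name:>3}"
        f"{_chain_field(out_chain, style)}{resnum}"
    )


def format_atom(
    atom: AtomRecord,
    serial: str,
    out_chain: str,
    style: ChainStyle,
    res_name: str | None = None,
) -> PdbLine:
    """Emit one ATOM or HETATM record.

    ``res_name`` overrides the atom's residue name when the caller has
    remapped an over-long name; ``out_chain`` is the (possibly remapped)
    chain ID for this output file.
    """
    rn = atom.res_name if res_name is None else res_name
    prefix = _atom_prefix(atom.group, atom, serial, out_chain, style, rn)
    x = pad_field(atom.x, 8, record=atom.group, columns="31-38")
    y = pad_field(atom.y, 8, record=atom.group, columns="39-46")
    z = pad_field(atom.z, 8, record=atom.group, columns="47-54")
    occ = blank(atom.occupancy)
    occ_f = pad_field(occ, 6, record=atom.group, columns="55-60") if occ else "  1.00"
    b = blank(atom.b_factor)
    b_f = pad_field(b, 6, record=atom.group, columns="61-66") if b else "  0.00"
    element = blank(atom.element).strip()[:2].rjust(2)
    return _pad80(
        prefix + "   " + x + y + z + occ_f + b_f + " " * 10
        + element + _format_charge(atom.charge)
    )


def format_anisou(
    rec: AnisoRecord,
    atom: AtomRecord,
    serial: str,
    out_chain: str,
    style: ChainStyle,
    res_name: str | None = None,
) -> PdbLine | None:
    """Emit one ANISOU record, or ``None`` when a U value is unparseable.

    This is the single place where raw strings are converted to numbers:
    the PDB format stores U values as integers scaled by 10^4.
    """
    rn = atom.res_name if res_name is None else res_name
    prefix = _atom_prefix("ANISOU", atom, serial, out_chain, style, rn)
    fields = []
    for u in (rec.u11, rec.u22, rec.u33, rec.u12, rec.u13, rec.u23):
        try:
            q = (Decimal(u) * 10000).quantize(Decimal(1), rounding=ROUND_HALF_EVEN)
        except InvalidOperation:
            logger.warning("unparseable anisotropic U value %r; record skipped", u)
            return None
        fields.append(f"{int(q):>7}")
    element = blank(atom.element).strip()[:2].rjust(2)
    return _pad80(
        prefix + " " + "".join(fields) + " " * 6 + element + _format_charge(atom.charge)
    )


def format_ter(
    serial: str, res_name: str, out_chain: str, res_seq: str, icode: str,
    style: ChainStyle,
) -> PdbLine:
    """Chain-terminator record; consumes an atom serial number."""
    resnum = format_residue_number(res_seq, icode)
    return _pad80(
        f"{'TER':<6}{serial:>5}      {res_name:>3}"
        f"{_chain_field(out_chain, style)}{resnum}"
    )


_PLACEHOLDER_CELL = UnitCell(
    a="1.000", b="1.000", c="1.000",
    alpha="90.00", beta="90.00", gamma="90.00",
    space_group="P 1", z_value="1",
)


def format_cryst1(cell: UnitCell | None) -> PdbLine:
    """CRYST1 record; a missing cell yields the conventional placeholder
    (unit cell 1 1 1, 90 90 90, space group P 1, Z = 1)."""
    if cell is None:
        cell = _PLACEHOLDER_CELL
    a = _fixed(cell.a, 9, 3)
    b = _fixed(cell.b, 9, 3)
    c = _fixed(cell.c, 9, 3)
    alpha = _fixed(cell.alpha, 7, 2)
    beta = _fixed(cell.beta, 7, 2)
    gamma = _fixed(cell.gamma, 7, 2)
    sg = (cell.space_group or "P 1")[:11].ljust(11)
    z = (cell.z_value or "")[:4].rjust(4)
    return _pad80(f"CRYST1{a}{b}{c}{alpha}{beta}{gamma} {sg}{z}")


def compute_scale_matrix(cell: UnitCell) -> list[list[float]]:
    """Cartesian-to-fractional (fractionalization) matrix for SCALEn.

    With cosines ``ca, cb, cg`` and sines of the cell angles and
    ``v = sqrt(1 - ca^2 - cb^2 - cg^2 + 2 ca cb cg)`` (the unit-cell volume
    divided by ``abc``), the matrix is upper triangular::

        [ 1/a   -cg/(a sg)   (ca cg - cb)/(a v sg) ]
        [ 0      1/(b sg)    (cb cg - ca)/(b v sg) ]
        [ 0      0           sg/(c v)              ]
    """
    a, b, c = float(cell.a), float(cell.b), float(cell.c)
    if min(a, b, c) <= 0:
        raise StructureError("degenerate cell: non-positive edge length")
    alpha = math.radians(float(cell.alpha))
    beta = math.radians(float(cell.beta))
    gamma = math.radians(float(cell.gamma))
    ca, cb, cg = math.cos(alpha), math.cos(beta), math.cos(gamma)
    sg = math.sin(gamma)
    v_sq = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if v_sq <= 0 or sg == 0:
        raise StructureError("degenerate cell: angles give non-positive volume")
    v = math.sqrt(v_sq)
    return [
        [1.0 / a, -cg / (a * sg), (ca * cg - cb) / (a * v * sg)],
        [0.0, 1.0 / (b * sg), (cb * cg - ca) / (b * v * sg)],
        [0.0, 0.0, sg / (c * v)],
    ]


def format_scale(cell: UnitCell | None) -> list[PdbLine]:
    """SCALE1-3 records.  A missing cell yields the identity matrix."""
    matrix = compute_scale_matrix(cell if cell is not None else _PLACEHOLDER_CELL)
    lines = []
    for i, row in enumerate(matrix, start=1):
        body = "".join(f"{v:10.6f}" for v in row)
        lines.append(_pad80(f"SCALE{i}    {body}     {0:10.5f}"))
    return lines


def _wrap_tokens(tokens: list[str], width: int, sep: str) -> list[str]:
    """Greedy wrap that never splits a token; separators stay attached."""
    out: list[str] = []
    cur = ""
    for i, token in enumerate(tokens):
        piece = token + (sep if i < len(tokens) - 1 else "")
        if not cur:
            cur = piece
        elif len(cur) + len(piece) <= width:
            cur += piece
        else:
            out.append(cur)
            cur = piece
    if cur:
        out.append(cur)
    return out


def _continuation_lines(record: str, tokens: list[str], sep: str) -> list[PdbLine]:
    """Record with continuation numbers in columns 9-10, text from column 11."""
    lines = []
    for i, text in enumerate(_wrap_tokens(tokens, 68, sep)):
        cont = "  " if i == 0 else f"{i + 1:>2}"
        body = text if i == 0 else " " + text
        lines.append(_pad80(f"{record:<6}  {cont}{body}"))
    return lines


def _jrnl_lines(sub: str, tokens: list[str], sep: str) -> list[PdbLine]:
    """JRNL sub-record with continuation in columns 17-18, text from 20."""
    lines = []
    for i, text in enumerate(_wrap_tokens(tokens, 60, sep)):
        cont = "  " if i == 0 else f"{i + 1:>2}"
        lines.append(_pad80(f"JRNL        {sub:<4}{cont} {text}"))
    return lines


def _jrnl_ref(citation: Citation) -> PdbLine:
    journal = citation.journal.upper()[:28].ljust(28)
    vol = citation.volume[:4]
    v_marker = "V." if vol else "  "
    page = citation.page[:5]
    year = citation.year[:4]
    return _pad80(
        f"JRNL        REF    {journal} {v_marker} {vol:>4} {page:>5} {year:>4}"
    )


def format_title_section(header: HeaderMeta) -> list[PdbLine]:
    """HEADER, AUTHOR and JRNL records; empty metadata yields no lines."""
    lines: list[PdbLine] = []
    id_code = header.entry_id if len(header.entry_id) == 4 else ""
    if header.entry_id and not id_code:
        logger.info(
            "entry id %r is not 4 characters and cannot fit HEADER columns "
            "63-66; leaving idCode blank", header.entry_id,
        )
    if header.classification or header.dep_date or id_code:
        cls = header.classification.upper()[:40].ljust(40)
        lines.append(_pad80(f"HEADER    {cls}{header.dep_date:<9}   {id_code}"))
    if header.authors:
        lines.extend(_continuation_lines("AUTHOR", list(header.authors), ","))
    citation = header.citation
    if not citation.is_empty():
        if citation.authors:
            lines.extend(_jrnl_lines("AUTH", list(citation.authors), ","))
        if citation.title:
            lines.extend(_jrnl_lines("TITL", citation.title.split(), " "))
        if citation.journal or citation.volume or citation.page or citation.year:
            lines.append(_jrnl_ref(citation))
        lines.append(_pad80("JRNL        REFN"))
        if citation.pmid:
            lines.extend(_jrnl_lines("PMID", [citation.pmid], " "))
        if citation.doi:
            lines.extend(_jrnl_lines("DOI", [citation.doi], " "))
    return lines


def format_seqres(
    seqs: list[PolymerSeq],
    chain_map: dict[str, str],
    registry: ResnameRegistry | None = None,
) -> list[PdbLine]:
    """SEQRES records: 13 residues per line, serial restarting per chain.

    ``chain_map`` must cover every chain in ``seqs``; residue names longer
    than 3 characters go through the reserved-ID registry when given.
    """
    lines: list[PdbLine] = []
    for seq in seqs:
        out_chain = chain_map[seq.chain_id]
        if len(out_chain) > 2:
            raise ContractError(
                f"SEQRES chain ID {out_chain!r} exceeds two characters; "
                "remap chains first"
            )
        residues = [
            registry.map(r) if registry is not None else r for r in seq.residues
        ]
        num_res = len(residues)
        for ser, start in enumerate(range(0, num_res, 13), start=1):
            chunk = residues[start : start + 13]
            body = " ".join(f"{r:>3}" for r in chunk)
            lines.append(
                _pad80(f"SEQRES{ser:>4}{out_chain:>2}{num_res:>5}  {body}")
            )
    return lines


def format_dbref(ref: DbRef, out_chain: str, entry_id: str = "") -> PdbLine:
    """DBREF record (database cross-reference for one chain)."""
    if len(out_chain) > 2:
        raise ContractError(
            f"DBREF chain ID {out_chain!r} exceeds two characters"
        )
    id_code = entry_id[:4].ljust(4)
    return _pad80(
        f"DBREF  {id_code}{out_chain:>2} {ref.seq_begin:>4}{ref.icode_begin[:1] or ' '}"
        f" {ref.seq_end:>4}{ref.icode_end[:1] or ' '} {ref.db_name[:6]:<6} "
        f"{ref.db_accession[:8]:<8} {ref.db_id_code[:12]:<12} "
        f"{ref.db_seq_begin:>5}  {ref.db_seq_end:>5}"
    )


def format_model(model_num: str) -> PdbLine:
    return _pad80(f"MODEL {model_num:>8}")


def format_endmdl() -> PdbLine:
    return _pad80("ENDMDL")
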
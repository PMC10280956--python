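"""Typed structure document built from parsed mmCIF tables.

All numeric fields (coordinates, occupancies, B-factors, residue numbers,
cell constants) are stored as the exact strings found in the input.  They
are validated — a coordinate must parse as a decimal number — but never
converted for storage, so the writer can pad the original text into the
fixed-width PDB columns without any float round-trip.

Author-assigned identifiers (``auth_*``) are preferred over the
software-assigned ``label_*`` items, falling back to the latter when the
former are absent; legacy PDB files use author numbering.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .errors import StructureError
from .reader import CifTable

logger = logging.getLogger(__name__)

#: categories the converter reads from an mmCIF file
WANTED_CATEGORIES = frozenset(
    {
        "_atom_site",
        "_atom_site_anisotrop",
        "_struct_keywords",
        "_audit_author",
        "_citation",
        "_citation_author",
        "_cell",
        "_symmetry",
        "_entity_poly",
        "_entity_poly_seq",
        "_struct_ref",
        "_struct_ref_seq",
        "_pdbx_database_status",
        "_entry",
    }
)


def is_placeholder(value: str) -> bool:
    """True for the mmCIF null markers ``.`` and ``?`` (and empty strings)."""
    return value in ("", ".", "?")


def blank(value: str) -> str:
    """Normalize the mmCIF null markers to the empty string."""
    return "" if is_placeholder(value) else value


@dataclass(slots=True)
class AtomRecord:
    """One atom site; every field is the raw input string."""

    group: str  # "ATOM" or "HETATM"
    serial_src: str
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str  # author chain ID, unbounded length
    res_seq: str
    icode: str
    x: str
    y: str
    z: str
    occupancy: str
    b_factor: str
    element: str
    charge: str
    model_num: str


@dataclass(slots=True)
class AnisoRecord:
    """Anisotropic displacement parameters joined to one atom.

    ``key`` is the index of the companion :class:`AtomRecord` in
    ``StructureDoc.atoms``.  U values are Å² decimals kept verbatim.
    """

    key: int
    u11: str
    u22: str
    u33: str
    u12: str
    u13: str
    u23: str


@dataclass(slots=True)
class UnitCell:
    a: str
    b: str
    c: str
    alpha: str
    beta: str
    gamma: str
    space_group: str = ""
    z_value: str = ""


@dataclass(slots=True)
class Citation:
    authors: list[str] = field(default_factory=list)
    title: str = ""
    journal: str = ""
    volume: str = ""
    page: str = ""
    year: str = ""
    pmid: str = ""
    doi: str = ""

    def is_empty(self) -> bool:
        return not (
            self.authors
            or self.title
            or self.journal
            or self.volume
            or self.page
            or self.year
            or self.pmid
            or self.doi
        )


@dataclass(slots=True)
class HeaderMeta:
    classification: str = ""
    dep_date: str = ""  # DD-MMM-YY
    entry_id: str = ""
    authors: list[str] = field(default_factory=list)
    citation: Citation = field(default_factory=Citation)


@dataclass(slots=True)
class PolymerSeq:
    chain_id: str
    residues: list[str]


@dataclass(slots=True)
class DbRef:
    chain_id: str
    seq_begin: str = ""
    icode_begin: str = ""
    seq_end: str = ""
    icode_end: str = ""
    db_name: str = ""
    db_accession: str = ""
    db_id_code: str = ""
    db_seq_begin: str = ""
    db_seq_end: str = ""


@dataclass
class StructureDoc:
    """Everything the writer needs, in input order."""

    atoms: list[AtomRecord]
    anisou: list[AnisoRecord] = field(default_factory=list)
    cell: UnitCell | None = None
    header: HeaderMeta = field(default_factory=HeaderMeta)
    seqres: list[PolymerSeq] = field(default_factory=list)
    dbrefs: list[DbRef] = field(default_factory=list)


_MONTHS = {
    1: "JAN", 2: "FEB", 3: "MAR", 4: "APR", 5: "MAY", 6: "JUN",
    7: "JUL", 8: "AUG", 9: "SEP", 10: "OCT", 11: "NOV", 12: "DEC",
}

_ISO_DATE = re.compile(r"(\d{4})-(\d{1,2})-(\d{1,2})$")


def reformat_date(iso_date: str) -> str:
    """``YYYY-MM-DD`` -> ``DD-MMM-YY`` (PDB HEADER dialect); empty in, empty out.

    A malformed non-empty date yields an empty string with a warning; the
    HEADER date is cosmetic and must never abort a conversion.
    """
    if is_placeholder(iso_date):
        return ""
    m = _ISO_DATE.match(iso_date)
    if not m:
        logger.warning("unrecognized deposition date %r; leaving HEADER date blank", iso_date)
        return ""
    year, month, day = int(m.group(1)), int(m.group(2)), int(m.group(3))
    if not 1 <= month <= 12 or not 1 <= day <= 31:
        logger.warning("invalid deposition date %r; leaving HEADER date blank", iso_date)
        return ""
    return f"{day:02d}-{_MONTHS[month]}-{year % 100:02d}"


_NUM = re.compile(r"[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _is_number(value: str) -> bool:
    return bool(_NUM.match(value))


def _pick_col(table: CifTable, *names: str) -> int | None:
    """Index of the first present item among ``names`` (auth before label)."""
    for name in names:
        idx = table.col_index(name)
        if idx is not None:
            return idx
    return None


def _cell_from_tables(tables) -> UnitCell | None:
    cell_tbl = tables.get("_cell")
    if cell_tbl is None:
        return None
    a = blank(cell_tbl.first("length_a"))
    b = blank(cell_tbl.first("length_b"))
    c = blank(cell_tbl.first("length_c"))
    if not (a and b and c):
        return None
    alpha = blank(cell_tbl.first("angle_alpha")) or "90"
    beta = blank(cell_tbl.first("angle_beta")) or "90"
    gamma = blank(cell_tbl.first("angle_gamma")) or "90"
    for length in (a, b, c):
        if not _is_number(length) or float(length) <= 0:
            logger.warning("unusable cell length %r; omitting CRYST1 cell", length)
            return None
    for angle in (alpha, beta, gamma):
        if not _is_number(angle) or not 0 < float(angle) < 180:
            logger.warning("unusable cell angle %r; omitting CRYST1 cell", angle)
            return None
    sym_tbl = tables.get("_symmetry")
    space_group = ""
    if sym_tbl is not None:
        space_group = blank(sym_tbl.first("space_group_name_H-M"))
    return UnitCell(
        a=a, b=b, c=c, alpha=alpha, beta=beta, gamma=gamma,
        space_group=space_group, z_value=blank(cell_tbl.first("Z_PDB")),
    )


def _header_from_tables(tables) -> HeaderMeta:
    header = HeaderMeta()
    kw = tables.get("_struct_keywords")
    if kw is not None:
        header.classification = blank(kw.first("pdbx_keywords"))
    for cat, item in (
        ("_entry", "id"),
        ("_struct_keywords", "entry_id"),
        ("_cell", "entry_id"),
    ):
        tbl = tables.get(cat)
        if tbl is not None:
            entry_id = blank(tbl.first(item))
            if entry_id:
                header.entry_id = entry_id.upper()
                break
    status = tables.get("_pdbx_database_status")
    if status is not None:
        header.dep_date = reformat_date(
            blank(status.first("recvd_initial_deposition_date"))
        )
    authors = tables.get("_audit_author")
    if authors is not None:
        names = authors.column("name") or []
        header.authors = [blank(n) for n in names if blank(n)]
    header.citation = _citation_from_tables(tables)
    return header


def _citation_from_tables(tables) -> Citation:
    cit_tbl = tables.get("_citation")
    if cit_tbl is None or not cit_tbl.rows:
        return Citation()
    # only the primary citation becomes JRNL; fall back to the first row
    ids = cit_tbl.column("id") or [""] * len(cit_tbl.rows)
    row_idx = 0
    for i, cid in enumerate(ids):
        if cid.lower() == "primary":
            row_idx = i
            break
    chosen_id = ids[row_idx]

    def item(name: str) -> str:
        idx = cit_tbl.col_index(name)
        return blank(cit_tbl.rows[row_idx][idx]) if idx is not None else ""

    citation = Citation(
        title=item("title"),
        journal=item("journal_abbrev"),
        volume=item("journal_volume"),
        page=item("page_first"),
        year=item("year"),
        pmid=item("pdbx_database_id_PubMed"),
        doi=item("pdbx_database_id_DOI"),
    )
    auth_tbl = tables.get("_citation_author")
    if auth_tbl is not None:
        names = auth_tbl.column("name") or []
        cids = auth_tbl.column("citation_id")
        for i, name in enumerate(names):
            if cids is not None and chosen_id and cids[i] != chosen_id:
                continue
            if blank(name):
                citation.authors.append(blank(name))
    return citation


def _seqres_from_tables(tables) -> list[PolymerSeq]:
    poly = tables.get("_entity_poly")
    seq = tables.get("_entity_poly_seq")
    if poly is None or seq is None:
        return []
    entity_chains: dict[str, list[str]] = {}
    order: list[str] = []
    ent_col = poly.col_index("entity_id")
    strand_col = poly.col_index("pdbx_strand_id")
    if ent_col is None or strand_col is None:
        return []
    for row in poly.rows:
        ent = row[ent_col]
        strands = [s.strip() for s in blank(row[strand_col]).split(",") if s.strip()]
        entity_chains[ent] = strands
        order.append(ent)
    residues: dict[str, list[str]] = {}
    e_col = seq.col_index("entity_id")
    m_col = seq.col_index("mon_id")
    if e_col is None or m_col is None:
        return []
    for row in seq.rows:
        residues.setdefault(row[e_col], []).append(row[m_col])
    out: list[PolymerSeq] = []
    for ent in order:
        mons = residues.get(ent)
        if not mons:
            continue
        for chain in entity_chains.get(ent, []):
            out.append(PolymerSeq(chain_id=chain, residues=list(mons)))
    return out


def _dbrefs_from_tables(tables) -> list[DbRef]:
    refs = tables.get("_struct_ref")
    ref_seq = tables.get("_struct_ref_seq")
    if ref_seq is None:
        return []
    by_id: dict[str, dict[str, str]] = {}
    if refs is not None:
        id_col = refs.col_index("id")
        for row in refs.rows:
            rid = row[id_col] if id_col is not None else ""
            by_id[rid] = {
                item: blank(row[idx])
                for item, idx in (
                    ("db_name", refs.col_index("db_name")),
                    ("db_code", refs.col_index("db_code")),
                    ("accession", refs.col_index("pdbx_db_accession")),
                )
                if idx is not None
            }
    out: list[DbRef] = []
    for row in ref_seq.rows:
        def item(name: str, default: str = "") -> str:
            idx = ref_seq.col_index(name)
            return blank(row[idx]) if idx is not None else default

        parent = by_id.get(item("ref_id"), {})
        out.append(
            DbRef(
                chain_id=item("pdbx_strand_id"),
                seq_begin=item("pdbx_auth_seq_align_beg") or item("seq_align_beg"),
                icode_begin=item("pdbx_seq_align_beg_ins_code"),
                seq_end=item("pdbx_auth_seq_align_end") or item("seq_align_end"),
                icode_end=item("pdbx_seq_align_end_ins_code"),
                db_name=parent.get("db_name", ""),
                db_accession=parent.get("accession", "") or item("pdbx_db_accession"),
                db_id_code=parent.get("db_code", ""),
                db_seq_begin=item("db_align_beg"),
                db_seq_end=item("db_align_end"),
            )
        )
    return out


def build_document(tables: dict[str, CifTable]) -> StructureDoc:
    """Assemble a :class:`StructureDoc` from parsed category tables.

    Raises :class:`StructureError` when no coordinates are present or when an
    atom row lacks a parseable coordinate.
    """
    atom_tbl = tables.get("_atom_site")
    if atom_tbl is None or not atom_tbl.rows:
        raise StructureError("no coordinates: _atom_site category missing or empty")

    group_col = atom_tbl.col_index("group_PDB")
    id_col = atom_tbl.col_index("id")
    name_col = _pick_col(atom_tbl, "auth_atom_id", "label_atom_id")
    alt_col = atom_tbl.col_index("label_alt_id")
    res_col = _pick_col(atom_tbl, "auth_comp_id", "label_comp_id")
    chain_col = _pick_col(atom_tbl, "auth_asym_id", "label_asym_id")
    seq_col = _pick_col(atom_tbl, "auth_seq_id", "label_seq_id")
    icode_col = atom_tbl.col_index("pdbx_PDB_ins_code")
    x_col = atom_tbl.col_index("Cartn_x")
    y_col = atom_tbl.col_index("Cartn_y")
    z_col = atom_tbl.col_index("Cartn_z")
    occ_col = atom_tbl.col_index("occupancy")
    b_col = atom_tbl.col_index("B_iso_or_equiv")
    elem_col = atom_tbl.col_index("type_symbol")
    charge_col = atom_tbl.col_index("pdbx_formal_charge")
    model_col = atom_tbl.col_index("pdbx_PDB_model_num")

    if x_col is None or y_col is None or z_col is None:
        raise StructureError("_atom_site lacks Cartn_x/Cartn_y/Cartn_z coordinates")
    if chain_col is None:
        raise StructureError("_atom_site lacks auth_asym_id and label_asym_id")
    if res_col is None:
        raise StructureError("_atom_site lacks auth_comp_id and label_comp_id")
    if seq_col is None:
        raise StructureError("_atom_site lacks auth_seq_id and label_seq_id")

    atoms: list[AtomRecord] = []
    id_to_index: dict[str, int] = {}
    for rownum, row in enumerate(atom_tbl.rows, start=1):
        group = row[group_col] if group_col is not None else "ATOM"
        if group not in ("ATOM", "HETATM"):
            raise StructureError(
                f"_atom_site row {rownum}: group_PDB is {group!r}, "
                "expected ATOM or HETATM"
            )
        x, y, z = row[x_col], row[y_col], row[z_col]
        for axis, value in (("x", x), ("y", y), ("z", z)):
            if is_placeholder(value) or not _is_number(value):
                raise StructureError(
                    f"_atom_site row {rownum}: {axis} coordinate {value!r} "
                    "is not a number"
                )
        atoms.append(
            AtomRecord(
                group=group,
                serial_src=row[id_col] if id_col is not None else str(rownum),
                atom_name=row[name_col] if name_col is not None else "",
                alt_loc=row[alt_col] if alt_col is not None else "",
                res_name=row[res_col],
                chain_id=row[chain_col],
                res_seq=row[seq_col],
                icode=row[icode_col] if icode_col is not None else "",
                x=x, y=y, z=z,
                occupancy=row[occ_col] if occ_col is not None else "",
                b_factor=row[b_col] if b_col is not None else "",
                element=row[elem_col] if elem_col is not None else "",
                charge=row[charge_col] if charge_col is not None else "",
                model_num=(
                    blank(row[model_col]) or "1" if model_col is not None else "1"
                ),
            )
        )
        if id_col is not None:
            id_to_index[row[id_col]] = rownum - 1

    doc = StructureDoc(atoms=atoms)
    doc.anisou = _anisou_from_tables(tables, id_to_index)
    doc.cell = _cell_from_tables(tables)
    doc.header = _header_from_tables(tables)
    doc.seqres = _seqres_from_tables(tables)
    doc.dbrefs = _dbrefs_from_tables(tables)
    return doc


def _anisou_from_tables(tables, id_to_index: dict[str, int]) -> list[AnisoRecord]:
    aniso_tbl = tables.get("_atom_site_anisotrop")
    if aniso_tbl is None or not aniso_tbl.rows:
        return []
    if not id_to_index:
        logger.warning(
            "_atom_site_anisotrop present but _atom_site has no id column; "
            "dropping all ANISOU records"
        )
        return []
    id_col = aniso_tbl.col_index("id")
    u_cols = [
        aniso_tbl.col_index(item)
        for item in ("U[1][1]", "U[2][2]", "U[3][3]", "U[1][2]", "U[1][3]", "U[2][3]")
    ]
    if id_col is None or any(c is None for c in u_cols):
        logger.warning(
            "_atom_site_anisotrop lacks id or U[i][j] items; dropping ANISOU records"
        )
        return []
    out: list[AnisoRecord] = []
    for row in aniso_tbl.rows:
        atom_index = id_to_index.get(row[id_col])
        if atom_index is None:
            logger.warning(
                "anisotropic record id %s matches no atom; dropped", row[id_col]
            )
            continue
        us = [row[c] for c in u_cols]  # type: ignore[index]
        if any(is_placeholder(u) for u in us):
            logger.warning(
                "anisotropic record id %s has missing U values; dropped", row[id_col]
            )
            continue
        out.append(AnisoRecord(atom_index, *us))
    return out
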
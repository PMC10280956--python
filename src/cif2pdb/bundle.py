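"""Best Effort/Minimal bundle planning and output.

The legacy PDB format caps a file at 99,999 atom serial numbers and 62
distinct one-character chain IDs.  Structures beyond those limits are split
into several PDB files: chains are packed greedily in input order, each
file gets its own bijective mapping from original (possibly multi-
character) chain IDs onto the 62-symbol pool ``A``-``Z``, ``a``-``z``,
``0``-``9``, and a plain-text mapping file plus a POSIX ustar TAR archive
tie the bundle together.

TER records consume serial numbers in legacy PDB files, so each polymer
chain contributes its TER lines (one per model) to the 99,999-line budget.

A single chain that alone exceeds the budget is handled per the caller's
choice: split at residue boundaries across consecutive files, or written
into one file whose serial numbers wrap back to 1 after 99,999.
"""

from __future__ import annotations

import logging
import os
import string
from dataclasses import dataclass, field

from .errors import ContractError, StructureError
from .model import StructureDoc
from .writer import (
    ChainStyle,
    PdbLine,
    ResnameRegistry,
    STYLE_BUNDLE,
    _pad80,
    format_anisou,
    format_atom,
    format_cryst1,
    format_dbref,
    format_endmdl,
    format_model,
    format_scale,
    format_seqres,
    format_ter,
    format_title_section,
)

logger = logging.getLogger(__name__)

MAX_LINES = 99999  # atom + TER serials per file
MAX_CHAINS = 62

#: the 62 chain-ID symbols a legacy PDB file can express, in assignment order
CHAIN_ID_POOL: tuple[str, ...] = tuple(
    string.ascii_uppercase + string.ascii_lowercase + string.digits
)
_POOL_SET = frozenset(CHAIN_ID_POOL)


@dataclass
class ChainGroup:
    """One chain (or one piece of a split chain) destined for one file."""

    chain_id: str
    atom_indices: list[int]
    is_polymer: bool
    model_span: set[str] = field(default_factory=set)

    @property
    def n_ter(self) -> int:
        return len(self.model_span) if self.is_polymer else 0

    @property
    def atom_line_count(self) -> int:
        return len(self.atom_indices) + self.n_ter


@dataclass
class FilePlan:
    filename: str
    chains: list[ChainGroup]
    chain_map: dict[str, str]
    wrap_serials: bool = False


@dataclass
class BundlePlan:
    files: list[FilePlan]
    mapping_filename: str
    tar_filename: str


def collect_chains(doc: StructureDoc) -> list[ChainGroup]:
    """Group atoms by chain in order of first appearance (all models)."""
    groups: dict[str, ChainGroup] = {}
    order: list[ChainGroup] = []
    for i, atom in enumerate(doc.atoms):
        g = groups.get(atom.chain_id)
        if g is None:
            g = ChainGroup(atom.chain_id, [], False)
            groups[atom.chain_id] = g
            order.append(g)
        g.atom_indices.append(i)
        g.model_span.add(atom.model_num)
        if atom.group == "ATOM":
            g.is_polymer = True
    return order


def assign_chain_ids(chains: list[ChainGroup]) -> dict[str, str]:
    """Per-file bijection original chain ID -> single pool symbol.

    Processing chains in order: a chain keeps its own ID when it is exactly
    one character from the pool and still free; otherwise it takes the
    first unused pool symbol.
    """
    if len(chains) > MAX_CHAINS:
        raise ContractError(
            f"{len(chains)} chains in one file exceed the {MAX_CHAINS}-symbol "
            "pool; the planner must split first"
        )
    mapping: dict[str, str] = {}
    used: set[str] = set()
    for g in chains:
        cid = g.chain_id
        if len(cid) == 1 and cid in _POOL_SET and cid not in used:
            mapping[cid] = cid
            used.add(cid)
        else:
            symbol = next(s for s in CHAIN_ID_POOL if s not in used)
            mapping[cid] = symbol
            used.add(symbol)
    return mapping


def _split_chain(doc: StructureDoc, group: ChainGroup) -> list[ChainGroup]:
    """Split an oversized chain at residue boundaries into budget-sized pieces."""
    # consecutive atoms of one residue (within one model) form an unsplittable run
    runs: list[list[int]] = []
    prev_key: tuple[str, str, str] | None = None
    for i in group.atom_indices:
        atom = doc.atoms[i]
        key = (atom.model_num, atom.res_seq, atom.icode)
        if key != prev_key:
            runs.append([])
            prev_key = key
        runs[-1].append(i)

    pieces: list[ChainGroup] = []
    cur: list[int] = []
    cur_models: set[str] = set()
    for run in runs:
        run_models = cur_models | {doc.atoms[run[0]].model_num}
        ter = len(run_models) if group.is_polymer else 0
        if cur and len(cur) + len(run) + ter > MAX_LINES:
            pieces.append(
                ChainGroup(group.chain_id, cur, group.is_polymer, cur_models)
            )
            cur, cur_models = [], set()
        cur.extend(run)
        cur_models.add(doc.atoms[run[0]].model_num)
    if cur:
        pieces.append(ChainGroup(group.chain_id, cur, group.is_polymer, cur_models))
    logger.info(
        "chain %s split at residue boundaries into %d files",
        group.chain_id, len(pieces),
    )
    return pieces


def plan_bundle(
    doc: StructureDoc,
    overflow: str = "split_chain",
    stem: str | None = None,
) -> BundlePlan:
    """Partition a structure into Best Effort/Minimal output files.

    Chains are packed greedily in input order; a chain joins the current
    file unless that would exceed 62 chains or 99,999 atom+TER lines.  A
    chain that alone exceeds the budget is handled per ``overflow``:
    ``"split_chain"`` spreads it over consecutive files, splitting at
    residue boundaries; ``"duplicate_serials"`` keeps it in one file whose
    serials wrap back to 1 after 99,999.
    """
    if not doc.atoms:
        raise StructureError("no atoms: nothing to convert")
    if overflow not in ("split_chain", "duplicate_serials"):
        raise ContractError(f"unknown chain-overflow mode {overflow!r}")
    if stem is None:
        stem = doc.header.entry_id.lower() or "structure"

    file_groups: list[tuple[list[ChainGroup], bool]] = []  # (chains, wrap)
    cur: list[ChainGroup] = []
    cur_lines = 0

    def flush() -> None:
        nonlocal cur, cur_lines
        if cur:
            file_groups.append((cur, False))
            cur, cur_lines = [], 0

    for group in collect_chains(doc):
        if group.atom_line_count > MAX_LINES:
            flush()
            if overflow == "duplicate_serials":
                logger.warning(
                    "chain %s has %d lines; atom serials will wrap past 99999",
                    group.chain_id, group.atom_line_count,
                )
                file_groups.append(([group], True))
            else:
                for piece in _split_chain(doc, group):
                    file_groups.append(([piece], False))
            continue
        if cur and (
            len(cur) + 1 > MAX_CHAINS
            or cur_lines + group.atom_line_count > MAX_LINES
        ):
            flush()
        cur.append(group)
        cur_lines += group.atom_line_count
    flush()

    files = [
        FilePlan(
            filename=f"{stem}-pdb-bundle{n}.pdb",
            chains=chains,
            chain_map=assign_chain_ids(chains),
            wrap_serials=wrap,
        )
        for n, (chains, wrap) in enumerate(file_groups, start=1)
    ]
    return BundlePlan(
        files=files,
        mapping_filename=f"{stem}-chain-id-mapping.txt",
        tar_filename=f"{stem}-pdb-bundle.tar",
    )


def write_mapping_file(plan: BundlePlan) -> str:
    """Chain-ID mapping text: one section per bundle file, in file order."""
    lines: list[str] = []
    for fp in plan.files:
        # sections name the archive members, so a path prefix is stripped
        lines.append(f"{os.path.basename(fp.filename)}:")
        lines.append("    New chain ID    Original chain ID")
        for g in fp.chains:
            lines.append(f"    {fp.chain_map[g.chain_id]:<16}{g.chain_id}")
        lines.append("")
    return "\n".join(lines)


# --- POSIX ustar TAR writing -------------------------------------------------
#
# Written by hand rather than through the tarfile module so the archive is
# byte-minimal and byte-reproducible: fixed mtime 0, no record padding
# beyond the trailing two zero blocks (tarfile pads archives to 10 KiB
# records, which makes tiny bundles needlessly large).

_BLOCK = 512


def _ustar_header(name: str, size: int) -> bytes:
    encoded = name.encode("utf-8")
    if len(encoded) > 100:
        raise ContractError(f"tar member name exceeds 100 bytes: {name!r}")
    buf = bytearray(_BLOCK)
    buf[0 : len(encoded)] = encoded
    buf[100:108] = b"0000644\x00"  # mode
    buf[108:116] = b"0000000\x00"  # uid
    buf[116:124] = b"0000000\x00"  # gid
    buf[124:136] = f"{size:011o}".encode() + b"\x00"
    buf[136:148] = b"00000000000\x00"  # mtime 0 for reproducibility
    buf[148:156] = b" " * 8  # checksum field counts as spaces
    buf[156] = ord("0")  # regular file
    buf[257:263] = b"ustar\x00"
    buf[263:265] = b"00"
    buf[329:337] = b"0000000\x00"  # devmajor
    buf[337:345] = b"0000000\x00"  # devminor
    checksum = sum(buf)
    buf[148:156] = f"{checksum:06o}".encode() + b"\x00 "
    return bytes(buf)


def write_tar(members: list[tuple[str, bytes]]) -> bytes:
    """Serialize ``(name, content)`` members as a POSIX ustar archive."""
    parts: list[bytes] = []
    for name, content in members:
        parts.append(_ustar_header(name, len(content)))
        parts.append(content)
        if len(content) % _BLOCK:
            parts.append(b"\x00" * (_BLOCK - len(content) % _BLOCK))
    parts.append(b"\x00" * (2 * _BLOCK))
    return b"".join(parts)


# --- rendering one output file ----------------------------------------------


def render_file(
    doc: StructureDoc,
    groups: list[ChainGroup],
    chain_map: dict[str, str],
    style: ChainStyle = STYLE_BUNDLE,
    *,
    include_seqres: bool = False,
    include_dbref: bool = False,
    registry: ResnameRegistry | None = None,
    wrap_serials: bool = False,
) -> str:
    """Render one PDB file for the given chain groups.

    Atom serials restart at 1 and include TER records; when
    ``wrap_serials`` is set they wrap back to 1 after 99,999 instead of
    being a fatal overflow.
    """
    registry = registry if registry is not None else ResnameRegistry()
    aniso_by_atom = {rec.key: rec for rec in doc.anisou}
    selected = set(chain_map)

    lines: list[PdbLine] = []
    lines.extend(format_title_section(doc.header))
    if include_dbref:
        for ref in doc.dbrefs:
            if ref.chain_id in selected:
                lines.append(
                    format_dbref(ref, chain_map[ref.chain_id], doc.header.entry_id)
                )
    if include_seqres:
        seqs = [s for s in doc.seqres if s.chain_id in selected]
        lines.extend(format_seqres(seqs, chain_map, registry))
    lines.append(format_cryst1(doc.cell))
    lines.extend(format_scale(doc.cell))

    models: list[str] = []
    for g in groups:
        for i in g.atom_indices:
            m = doc.atoms[i].model_num
            if m not in models:
                models.append(m)
    multi_model = len(models) > 1

    serial = 0
    wrapped = False

    def next_serial() -> str:
        nonlocal serial, wrapped
        serial += 1
        if serial > MAX_LINES:
            if not wrap_serials:
                raise ContractError(
                    "atom serial exceeded 99999; the planner must split first"
                )
            serial = 1
            if not wrapped:
                logger.warning("atom serials wrapped back to 1 after 99999")
                wrapped = True
        return str(serial)

    for model in models:
        if multi_model:
            lines.append(format_model(model))
        for g in groups:
            out_chain = chain_map[g.chain_id]
            last = None
            for i in g.atom_indices:
                atom = doc.atoms[i]
                if atom.model_num != model:
                    continue
                res_name = registry.map(atom.res_name)
                s = next_serial()
                lines.append(format_atom(atom, s, out_chain, style, res_name))
                aniso = aniso_by_atom.get(i)
                if aniso is not None:
                    aniso_line = format_anisou(
                        aniso, atom, s, out_chain, style, res_name
                    )
                    if aniso_line is not None:
                        lines.append(aniso_line)
                last = (res_name, atom.res_seq, atom.icode)
            if last is not None and g.is_polymer:
                lines.append(
                    format_ter(next_serial(), last[0], out_chain, last[1], last[2], style)
                )
        if multi_model:
            lines.append(format_endmdl())
    lines.append(_pad80("END"))
    return "\n".join(lines) + "\n"
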
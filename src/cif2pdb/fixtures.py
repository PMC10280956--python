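"""Deterministic synthetic mmCIF generation for tests and demos.

Everything the converter must survive — multi-character chain IDs, files
beyond 99,999 atoms, residue names longer than 3 characters, 5-digit
residue numbers, anisotropic displacement records, multiple models — can
be produced here without downloading anything.  Coordinates and B-factors
are generated *as strings* with fixed decimal places, so end-to-end
fidelity tests can compare output columns to the source text exactly.

The geometry is not physical: atoms are scattered uniformly in a box.
"""

from __future__ import annotations

import gzip as _gzip
import itertools
import random
import string
from dataclasses import dataclass
from typing import Sequence

_ENTRY_ID = "9syn"
_ATOM_NAMES = ("N", "CA", "C", "O")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}
_AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic structure."""

    n_chains: int = 1
    atoms_per_chain: int | Sequence[int] = 4
    chain_id_len: int = 1
    resname_len: int = 3
    residues_per_chain: int = 1
    max_res_seq: int = 0  # 0: residue numbers start at 1
    with_anisou: bool = False
    n_models: int = 1
    with_cell: bool = False
    with_citation: bool = False
    with_seqres: bool = False
    with_dbref: bool = False
    seed: int = 0

    def chain_atom_counts(self) -> list[int]:
        if isinstance(self.atoms_per_chain, int):
            return [self.atoms_per_chain] * self.n_chains
        counts = list(self.atoms_per_chain)
        if len(counts) != self.n_chains:
            raise ValueError("atoms_per_chain list must have n_chains entries")
        return counts


def chain_ids(n: int, length: int) -> list[str]:
    """``n`` distinct deterministic chain IDs of the requested ``length``."""
    if length == 1:
        pool = string.ascii_uppercase + string.ascii_lowercase + string.digits
        if n > len(pool):
            raise ValueError(f"cannot make {n} distinct 1-character chain IDs")
        return list(pool[:n])
    out = []
    for combo in itertools.product(string.ascii_uppercase, repeat=length):
        out.append("".join(combo))
        if len(out) == n:
            return out
    raise ValueError(f"cannot make {n} chain IDs of length {length}")


def _residue_names(spec: FixtureSpec) -> list[str]:
    """One residue name per residue position; over-long names are distinct."""
    if spec.resname_len <= 3:
        return [
            _AMINO_ACIDS[i % len(_AMINO_ACIDS)]
            for i in range(spec.residues_per_chain)
        ]
    names = []
    for i in range(spec.residues_per_chain):
        suffix = f"{i % 1000:03d}"
        body = "X" * max(spec.resname_len - 3, 0)
        names.append((body + suffix)[-spec.resname_len :].rjust(spec.resname_len, "X"))
    return names


def generate_cif(spec: FixtureSpec) -> str:
    """Render the synthetic structure as mmCIF text (one data_ block)."""
    rng = random.Random(spec.seed)
    cids = chain_ids(spec.n_chains, spec.chain_id_len)
    counts = spec.chain_atom_counts()
    n_res = max(spec.residues_per_chain, 1)
    res_names = _residue_names(spec)
    start = spec.max_res_seq - n_res + 1 if spec.max_res_seq else 1

    out: list[str] = [f"data_{_ENTRY_ID}", "#"]
    out.append(f"_entry.id {_ENTRY_ID}")
    out.append("_struct_keywords.pdbx_keywords 'SYNTHETIC BENCHMARK'")
    out.append("_pdbx_database_status.recvd_initial_deposition_date 2023-06-20")
    out.append("#")
    out.append("loop_")
    out.append("_audit_author.name")
    out.append("_audit_author.pdbx_ordinal")
    out.append("'Doe, J.' 1")
    out.append("'Roe, Q.R.' 2")
    out.append("#")
    if spec.with_cell:
        a = f"{rng.uniform(20, 200):.3f}"
        b = f"{rng.uniform(20, 200):.3f}"
        c = f"{rng.uniform(20, 200):.3f}"
        alpha = f"{rng.uniform(75, 105):.2f}"
        beta = f"{rng.uniform(75, 105):.2f}"
        gamma = f"{rng.uniform(75, 105):.2f}"
        out += [
            f"_cell.entry_id {_ENTRY_ID}",
            f"_cell.length_a {a}",
            f"_cell.length_b {b}",
            f"_cell.length_c {c}",
            f"_cell.angle_alpha {alpha}",
            f"_cell.angle_beta {beta}",
            f"_cell.angle_gamma {gamma}",
            "_cell.Z_PDB 4",
            f"_symmetry.entry_id {_ENTRY_ID}",
            "_symmetry.space_group_name_H-M 'P 1'",
            "#",
        ]
    if spec.with_citation:
        out += [
            "_citation.id primary",
            "_citation.title",
            ";A synthetic structure generated for conversion testing,",
            "with a deliberately multi-line title",
            ";",
            "_citation.journal_abbrev 'J. Synth. Struct.'",
            "_citation.journal_volume 12",
            "_citation.page_first 345",
            "_citation.year 2023",
            "_citation.pdbx_database_id_PubMed 12345678",
            "_citation.pdbx_database_id_DOI 10.1000/synthetic.2023",
            "loop_",
            "_citation_author.citation_id",
            "_citation_author.name",
            "_citation_author.ordinal",
            "primary 'Doe, J.' 1",
            "primary 'Roe, Q.R.' 2",
            "#",
        ]
    if spec.with_seqres:
        out.append("loop_")
        out.append("_entity_poly.entity_id")
        out.append("_entity_poly.pdbx_strand_id")
        for k, cid in enumerate(cids, start=1):
            out.append(f"{k} {cid}")
        out.append("loop_")
        out.append("_entity_poly_seq.entity_id")
        out.append("_entity_poly_seq.num")
        out.append("_entity_poly_seq.mon_id")
        for k in range(1, spec.n_chains + 1):
            for i in range(n_res):
                out.append(f"{k} {i + 1} {res_names[i % len(res_names)]}")
        out.append("#")
    if spec.with_dbref:
        out += [
            "loop_",
            "_struct_ref.id",
            "_struct_ref.db_name",
            "_struct_ref.db_code",
            "_struct_ref.pdbx_db_accession",
            "1 UNP SYNT_TEST P99999",
            "loop_",
            "_struct_ref_seq.ref_id",
            "_struct_ref_seq.pdbx_strand_id",
            "_struct_ref_seq.pdbx_auth_seq_align_beg",
            "_struct_ref_seq.pdbx_auth_seq_align_end",
            "_struct_ref_seq.db_align_beg",
            "_struct_ref_seq.db_align_end",
        ]
        for cid in cids:
            out.append(f"1 {cid} {start} {start + n_res - 1} 1 {n_res}")
        out.append("#")

    out.append("loop_")
    for item in (
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "label_asym_id", "label_seq_id", "Cartn_x", "Cartn_y",
        "Cartn_z", "occupancy", "B_iso_or_equiv", "pdbx_formal_charge",
        "auth_seq_id", "auth_comp_id", "auth_asym_id", "pdbx_PDB_model_num",
    ):
        out.append(f"_atom_site.{item}")

    atom_id = 0
    atom_rows: list[str] = []
    aniso_rows: list[str] = []
    for model in range(1, spec.n_models + 1):
        for ci, cid in enumerate(cids):
            n_atoms = counts[ci]
            for j in range(n_atoms):
                atom_id += 1
                res_idx = j * n_res // max(n_atoms, 1)
                res_name = res_names[res_idx % len(res_names)]
                res_seq = start + res_idx
                name = _ATOM_NAMES[j % len(_ATOM_NAMES)]
                x = f"{rng.uniform(-99.999, 999.999):.3f}"
                y = f"{rng.uniform(-99.999, 999.999):.3f}"
                z = f"{rng.uniform(-99.999, 999.999):.3f}"
                b = f"{rng.uniform(0, 99.99):.2f}"
                atom_rows.append(
                    f"ATOM {atom_id} {_ELEMENTS[name]} {name} . {res_name} "
                    f"{cid} {res_idx + 1} {x} {y} {z} 1.00 {b} ? "
                    f"{res_seq} {res_name} {cid} {model}"
                )
                if spec.with_anisou:
                    us = " ".join(f"{rng.uniform(0.001, 0.9):.4f}" for _ in range(6))
                    aniso_rows.append(f"{atom_id} {us}")
    out.extend(atom_rows)
    out.append("#")
    if spec.with_anisou:
        out.append("loop_")
        for item in ("id", "U[1][1]", "U[2][2]", "U[3][3]", "U[1][2]",
                     "U[1][3]", "U[2][3]"):
            out.append(f"_atom_site_anisotrop.{item}")
        out.extend(aniso_rows)
        out.append("#")
    return "\n".join(out) + "\n"


def write_cif(path, spec: FixtureSpec, compress: bool = False) -> None:
    """Write the fixture to ``path``, optionally gzip-compressed.

    Compression uses ``mtime=0`` so repeated writes are byte-identical.
    """
    text = generate_cif(spec).encode("utf-8")
    if compress:
        with open(path, "wb") as fh:
            with _gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
                gz.write(text)
    else:
        with open(path, "wb") as fh:
            fh.write(text)
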
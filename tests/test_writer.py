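"""Fixed-width record layout, padding, and overflow conventions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cif2pdb.errors import ContractError, FieldOverflowError, StructureError
from cif2pdb.model import AnisoRecord, AtomRecord, Citation, HeaderMeta, PolymerSeq, UnitCell
from cif2pdb.writer import (
    ResnameRegistry,
    STYLE_BUNDLE,
    STYLE_PHENIX,
    compute_scale_matrix,
    format_anisou,
    format_atom,
    format_cryst1,
    format_residue_number,
    format_scale,
    format_seqres,
    format_title_section,
    map_long_resname,
    pad_field,
)


def atom(**kwargs) -> AtomRecord:
    base = dict(
        group="ATOM", serial_src="1", atom_name="N", alt_loc=".",
        res_name="MET", chain_id="A", res_seq="1", icode="?",
        x="0.000", y="0.000", z="0.000", occupancy="1.00", b_factor="10.00",
        element="N", charge="?", model_num="1",
    )
    base.update(kwargs)
    return AtomRecord(**base)


class TestPadField:
    @pytest.mark.parametrize(
        "value, width, justify, expected",
        [
            ("24.430", 8, "right", "  24.430"),
            ("1.00", 6, "right", "  1.00"),
            ("P 1", 11, "left", "P 1        "),
            # numeric fallback: round-half-even at the widest fitting precision
            ("12345.67891", 8, "right", "12345.68"),
            ("0.125", 4, "right", "0.12"),  # ties go to even
            ("0.135", 4, "right", "0.14"),
            ("-123.456789", 8, "right", "-123.457"),
        ],
    )
    def test_examples(self, value, width, justify, expected):
        assert pad_field(value, width, justify) == expected

    def test_non_numeric_overflow_names_the_field(self):
        with pytest.raises(FieldOverflowError, match="ATOM columns 13-16"):
            pad_field("TOOLONG", 4, record="ATOM", columns="13-16")

    def test_numeric_overflow_beyond_integer_digits(self):
        with pytest.raises(FieldOverflowError):
            pad_field("123456789.0", 6)

    @given(st.text(alphabet="0123456789.-", min_size=1, max_size=6))
    def test_fitting_values_are_never_altered(self, value):
        """Padding a value that already fits only adds spaces."""
        assert pad_field(value, 8).strip() == value.strip() or value.strip() == ""


class TestFormatAtom:
    def test_column_layout(self):
        line = format_atom(atom(), "1", "A", STYLE_BUNDLE)
        assert len(line) == 80
        assert line[0:6] == "ATOM  "
        assert line[6:11] == "    1"
        assert line[12:16] == " N  "
        assert line[17:20] == "MET"
        assert line[21] == "A" and line[20] == " "
        assert line[22:27] == "   1 "
        assert line[30:38] == "   0.000"
        assert line[54:60] == "  1.00"
        assert line[60:66] == " 10.00"
        assert line[76:78] == " N"

    def test_phenix_two_character_chain_uses_column_21(self):
        line = format_atom(atom(chain_id="XY"), "1", "XY", STYLE_PHENIX)
        assert line[20] == "X" and line[21] == "Y"

    def test_bundle_style_rejects_two_character_chain(self):
        with pytest.raises(ContractError):
            format_atom(atom(), "1", "XY", STYLE_BUNDLE)

    def test_atom_name_alignment_follows_element_width(self):
        # carbon CA (the alpha carbon) starts at column 14 ...
        ca = format_atom(atom(atom_name="CA", element="C"), "1", "A", STYLE_BUNDLE)
        assert ca[12:16] == " CA "
        # ... calcium CA (two-letter element) starts at column 13
        calcium = format_atom(
            atom(atom_name="CA", element="CA", group="HETATM"), "1", "A", STYLE_BUNDLE
        )
        assert calcium[12:16] == "CA  "
        assert calcium[0:6] == "HETATM"

    def test_four_character_name_fills_columns_13_to_16(self):
        line = format_atom(atom(atom_name="HG21", element="H"), "1", "A", STYLE_BUNDLE)
        assert line[12:16] == "HG21"

    def test_charge_is_digit_then_sign(self):
        line = format_atom(
            atom(charge="-1", element="O", group="HETATM"), "1", "A", STYLE_BUNDLE
        )
        assert line[78:80] == "1-"

    def test_string_fidelity_of_coordinates(self):
        a = atom(x="-99.123", y="8.400", z="123.456", occupancy="0.33", b_factor="5.70")
        line = format_atom(a, "42", "A", STYLE_BUNDLE)
        assert line[30:38].strip() == "-99.123"
        assert line[38:46].strip() == "8.400"
        assert line[46:54].strip() == "123.456"
        assert line[54:60].strip() == "0.33"
        assert line[60:66].strip() == "5.70"


class TestResidueNumber:
    @pytest.mark.parametrize(
        "res_seq, icode, expected",
        [
            ("1", "", "   1 "),
            ("42", "B", "  42B"),
            ("9999", "", "9999 "),
            ("12345", "", "12345"),  # 5th digit spills into column 27
            ("-1", "", "  -1 "),
            ("-999", "", "-999 "),
        ],
    )
    def test_examples(self, res_seq, icode, expected):
        assert format_residue_number(res_seq, icode) == expected

    def test_five_digits_discard_insertion_code_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert format_residue_number("12345", "A") == "12345"
        assert "discarded" in caplog.text

    def test_beyond_capacity_is_fatal(self):
        with pytest.raises(FieldOverflowError, match="exceeds PDB capacity"):
            format_residue_number("100000", "")

    @given(
        st.integers(min_value=1, max_value=9999),
        st.sampled_from([""] + [chr(c) for c in range(ord("A"), ord("Z") + 1)]),
    )
    def test_injective_below_five_digits(self, num, icode):
        """Distinct (number, icode) pairs give distinct column contents."""
        rendered = format_residue_number(str(num), icode)
        assert rendered[:4].strip() == str(num)
        assert rendered[4].strip() == icode

    @given(st.integers(min_value=10000, max_value=99999))
    def test_five_digit_numbers_recoverable(self, num):
        assert format_residue_number(str(num), "") == str(num)


class TestLongResnames:
    def test_short_names_unchanged(self):
        assert map_long_resname("MET", ResnameRegistry()) == "MET"

    def test_pool_order_and_stability(self):
        reg = ResnameRegistry()
        assert reg.map("A1B2C") == "01"
        assert reg.map("OTHER") == "02"
        assert reg.map("A1B2C") == "01"  # repeated name reuses its alias
        assert reg.assigned == {"A1B2C": "01", "OTHER": "02"}

    def test_hundredth_name_gets_drg(self):
        # oracle: enumerate the declared 102-element pool
        pool = [f"{i:02d}" for i in range(1, 100)] + ["DRG", "INH", "LIG"]
        reg = ResnameRegistry()
        aliases = [reg.map(f"LONG{i:03d}") for i in range(102)]
        assert aliases == pool
        assert aliases[99] == "DRG"

    def test_pool_exhaustion_is_fatal(self):
        reg = ResnameRegistry()
        for i in range(102):
            reg.map(f"LONG{i:03d}")
        with pytest.raises(FieldOverflowError, match="exhausted"):
            reg.map("ONEMORE")


class TestCryst1AndScale:
    def test_cryst1_layout(self):
        cell = UnitCell("10.000", "10.000", "10.000", "90.00", "90.00", "90.00",
                        "P 21 21 21", "4")
        line = format_cryst1(cell)
        assert line.rstrip() == (
            "CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 21 21 21    4"
        )

    def test_cryst1_placeholder_when_cell_absent(self):
        assert format_cryst1(None).rstrip() == (
            "CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1           1"
        )

    def test_cryst1_reformats_bare_angle(self):
        cell = UnitCell("10", "10", "10", "90", "90", "90")
        line = format_cryst1(cell)
        assert line[33:40] == "  90.00"

    def test_cubic_cell_scale_is_inverse_edge(self):
        m = compute_scale_matrix(UnitCell("10", "10", "10", "90", "90", "90"))
        assert np.allclose(m, np.diag([0.1, 0.1, 0.1]))

    def test_orthorhombic_diagonal(self):
        m = compute_scale_matrix(UnitCell("10", "20", "25", "90", "90", "90"))
        assert np.allclose(m, np.diag([0.1, 0.05, 0.04]))

    def test_triclinic_inverts_orthogonalization(self):
        cell = UnitCell("10", "12", "14", "80", "95", "100")
        m = np.array(compute_scale_matrix(cell))
        o = orthogonalization_matrix(10, 12, 14, 80, 95, 100)
        assert np.max(np.abs(m @ o - np.eye(3))) < 1e-9

    def test_degenerate_cell_is_fatal(self):
        with pytest.raises(StructureError, match="degenerate"):
            compute_scale_matrix(UnitCell("10", "10", "10", "1", "1", "179"))

    def test_scale_record_layout(self):
        lines = format_scale(UnitCell("10", "10", "10", "90", "90", "90"))
        assert [l[:6] for l in lines] == ["SCALE1", "SCALE2", "SCALE3"]
        assert lines[0][10:20] == "  0.100000"
        assert lines[0][45:55] == "   0.00000"
        assert all(len(l) == 80 for l in lines)


def orthogonalization_matrix(a, b, c, alpha, beta, gamma):
    """Independent fractional->Cartesian matrix (standard crystallographic form)."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    sg = math.sin(math.radians(gamma))
    v = math.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg)
    return np.array(
        [
            [a, b * cg, c * cb],
            [0, b * sg, c * (ca - cb * cg) / sg],
            [0, 0, c * v / sg],
        ]
    )


class TestTitleSection:
    def test_header_line(self):
        header = HeaderMeta(
            classification="Viral Protein", dep_date="15-MAR-21", entry_id="7ABC"
        )
        lines = format_title_section(header)
        assert lines[0].rstrip() == (
            "HEADER    VIRAL PROTEIN                           15-MAR-21   7ABC"
        )

    def test_author_wrapping_never_splits_a_name(self):
        names = [f"SURNAME{i:02d},A.B." for i in range(30)]
        lines = format_title_section(HeaderMeta(authors=names))
        assert lines[0].startswith("AUTHOR    SURNAME00")
        assert lines[1][8:10] == " 2"
        joined = "".join(l[10:].strip() for l in lines)
        for name in names:
            assert name in joined

    def test_no_citation_no_jrnl(self):
        lines = format_title_section(HeaderMeta(classification="X", entry_id="1ABC"))
        assert not any(l.startswith("JRNL") for l in lines)

    def test_empty_metadata_yields_no_lines(self):
        assert format_title_section(HeaderMeta()) == []

    def test_jrnl_subrecords_present(self):
        header = HeaderMeta(
            citation=Citation(
                authors=["DOE,J."], title="A TITLE", journal="J.TEST",
                volume="5", page="100", year="2020", pmid="123", doi="10.1/x",
            )
        )
        subs = [l[12:16].strip() for l in format_title_section(header)]
        for sub in ("AUTH", "TITL", "REF", "REFN", "PMID", "DOI"):
            assert sub in subs


class TestSeqres:
    def test_single_line(self):
        lines = format_seqres([PolymerSeq("A", ["MET", "ALA", "GLY"])], {"A": "A"})
        assert lines == ["SEQRES   1 A    3  MET ALA GLY".ljust(80)]

    def test_fourteen_residues_wrap_to_two_lines(self):
        lines = format_seqres([PolymerSeq("A", ["GLY"] * 14)], {"A": "A"})
        assert len(lines) == 2
        assert lines[0][6:10] == "   1" and lines[1][6:10] == "   2"
        assert lines[1][19:22] == "GLY"

    def test_remapped_chain_id_is_used(self):
        lines = format_seqres([PolymerSeq("AAA", ["MET"])], {"AAA": "B"})
        assert lines[0][11] == "B"


class TestAnisou:
    @pytest.mark.parametrize(
        "u, expected",
        [
            ("0.0500", "500"),
            ("0.12345", "1234"),  # 1234.5 rounds half-even to 1234
            ("0.12355", "1236"),
            ("0.0000", "0"),
        ],
    )
    def test_u_scaling(self, u, expected):
        rec = AnisoRecord(0, u, "0.0", "0.0", "0.0", "0.0", "0.0")
        line = format_anisou(rec, atom(), "1", "A", STYLE_BUNDLE)
        assert line[28:35].strip() == expected

    def test_prefix_mirrors_atom_line(self):
        a = atom(res_seq="42", icode="B")
        rec = AnisoRecord(0, "0.1", "0.1", "0.1", "0.0", "0.0", "0.0")
        atom_line = format_atom(a, "7", "A", STYLE_BUNDLE)
        aniso_line = format_anisou(rec, a, "7", "A", STYLE_BUNDLE)
        assert aniso_line[6:27] == atom_line[6:27]
        assert aniso_line[0:6] == "ANISOU"

    def test_unparseable_u_skips_record(self, caplog):
        rec = AnisoRecord(0, "abc", "0.1", "0.1", "0.0", "0.0", "0.0")
        with caplog.at_level("WARNING"):
            assert format_anisou(rec, atom(), "1", "A", STYLE_BUNDLE) is None
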
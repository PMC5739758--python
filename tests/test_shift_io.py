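"""I/O round trips, numbering, and parser validation rules."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csp_pocket import shift_io as sio
from csp_pocket.errors import IntegrityError, LookupError_, ParseError

from conftest import make_table


# ---------------------------------------------------------------------------
# shift tables
# ---------------------------------------------------------------------------

class TestReadShiftTable:
    def test_minimal_tsv(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("residue_number\tresidue_type\tatom_name\tshift_ppm\n"
                     "21\tG\tH\t8.45\n21\tG\tN\t109.2\n")
        table = sio.read_shift_table(p, "tsv")
        assert len(table) == 2
        assert table.get(21, "H").shift_ppm == 8.45
        assert table.get(21, "N").residue_type == "G"

    def test_glycine_cb_row_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.tsv"
        p.write_text("21\tG\tH\t8.45\n21\tG\tN\t109.2\n21\tG\tCB\t30.0\n")
        with caplog.at_level("WARNING"):
            table = sio.read_shift_table(p, "tsv")
        assert len(table) == 2
        assert "CB" in caplog.text

    def test_proline_amide_proton_dropped(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("5\tP\tH\t8.2\n5\tP\tN\t132.0\n")
        table = sio.read_shift_table(p, "tsv")
        assert table.get(5, "H") is None
        assert table.get(5, "N") is not None

    def test_duplicate_residue_atom_is_integrity_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("21\tG\tH\t8.45\n21\tG\tH\t8.46\n")
        with pytest.raises(IntegrityError, match="duplicate"):
            sio.read_shift_table(p, "tsv")

    def test_out_of_window_ppm_dropped_never_clamped(self, tmp_path, caplog):
        p = tmp_path / "s.tsv"
        p.write_text("21\tG\tH\t50.0\n21\tG\tN\t109.2\n")
        with caplog.at_level("WARNING"):
            table = sio.read_shift_table(p, "tsv")
        assert table.get(21, "H") is None  # rejected, not repaired

    def test_non_backbone_atoms_ignored(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("21\tK\tH\t8.1\n21\tK\tN\t121.0\n21\tK\tHB2\t1.8\n")
        table = sio.read_shift_table(p, "tsv")
        assert len(table) == 2

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("21\tG\tH\t8.45\nnot\ta\tnumber\there\n")
        with pytest.raises(ParseError, match="line 2"):
            sio.read_shift_table(p, "tsv")


class TestNmrStar:
    STAR = """\
data_example
save_assigned_chemical_shifts
loop_
    _Atom_chem_shift.ID
    _Atom_chem_shift.Comp_index_ID
    _Atom_chem_shift.Comp_ID
    _Atom_chem_shift.Atom_ID
    _Atom_chem_shift.Val
    1 21 GLY H 8.45
    2 21 GLY N 109.2
    3 22 LYS H 8.10
    4 22 LYS N 121.4
    5 22 LYS CA 56.3
stop_
save_
"""

    def test_atom_chem_shift_loop(self, tmp_path):
        p = tmp_path / "e.str"
        p.write_text(self.STAR)
        table = sio.read_shift_table(p, "nmrstar")
        assert len(table) == 5
        assert table.get(21, "H").residue_type == "G"
        assert table.get(22, "CA").shift_ppm == 56.3

    def test_missing_loop_is_parse_error(self, tmp_path):
        p = tmp_path / "e.str"
        p.write_text("data_empty\nsave_x\nsave_\n")
        with pytest.raises(ParseError, match="Atom_chem_shift"):
            sio.read_shift_table(p, "nmrstar")


# ---------------------------------------------------------------------------
# Sparky lists
# ---------------------------------------------------------------------------

class TestSparky:
    def test_assigned_row(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("      Assignment   w1   w2  Height\n"
                     "G21N-H 109.20 8.45 1.0e6\n")
        (peak,) = sio.read_sparky_list(p)
        assert peak.assignment == 21
        assert peak.n_ppm == 109.20 and peak.h_ppm == 8.45
        assert peak.intensity == 1.0e6

    def test_unassigned_and_default_intensity(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("Assignment w1 w2\n? 115.00 7.90\n")
        (peak,) = sio.read_sparky_list(p)
        assert peak.assignment is None
        assert peak.intensity == 1.0

    def test_empty_after_header(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("Assignment w1 w2 Height\n")
        assert sio.read_sparky_list(p) == []

    def test_axis_order_flag(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("Assignment w1 w2\nG21N-H 8.45 109.20\n")
        (peak,) = sio.read_sparky_list(p, axis_order="hn")
        assert peak.h_ppm == 8.45 and peak.n_ppm == 109.20

    def test_non_numeric_ppm_is_parse_error(self, tmp_path):
        p = tmp_path / "a.list"
        p.write_text("Assignment w1 w2\nG21N-H oops 8.45\n")
        with pytest.raises(ParseError, match="line 2"):
            sio.read_sparky_list(p)

    def test_writer_reader_round_trip(self, tmp_path):
        peaks = [sio.Peak2D(8.452, 109.234, 5.5e5, 21),
                 sio.Peak2D(7.901, 115.002, 1.0, None)]
        p = tmp_path / "rt.list"
        sio.write_sparky_list(peaks, p, residue_types={21: "G"})
        back = sio.read_sparky_list(p)
        assert [q.assignment for q in back] == [21, None]
        for orig, rt in zip(peaks, back):
            assert rt.h_ppm == pytest.approx(orig.h_ppm, abs=1e-4)
            assert rt.n_ppm == pytest.approx(orig.n_ppm, abs=1e-4)


# ---------------------------------------------------------------------------
# PDB Cα reader
# ---------------------------------------------------------------------------

def _pdb_line(serial, resnum, x, y, z, altloc=" ", occ=1.0, chain="A", name="CA"):
    return (f"ATOM  {serial:5d}  {name:<3s}{altloc}ALA {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           C")


class TestStructureCA:
    def test_three_residue_read(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text("\n".join([
            _pdb_line(1, 1, 1.0, 2.0, 3.0),
            _pdb_line(2, 2, 4.0, 5.0, 6.0),
            _pdb_line(3, 3, 7.0, 8.0, 9.0),
            "END",
        ]))
        s = sio.read_structure_ca(p, "A")
        assert s.residue_numbers == [1, 2, 3]
        assert s.coords([2]).tolist() == [[4.0, 5.0, 6.0]]

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text("\n".join([
            _pdb_line(1, 1, 1.0, 1.0, 1.0, altloc="A", occ=0.4),
            _pdb_line(2, 1, 2.0, 2.0, 2.0, altloc="B", occ=0.6),
            _pdb_line(3, 2, 0.0, 0.0, 0.0),
            "END",
        ]))
        s = sio.read_structure_ca(p, "A")
        assert s.coords([1]).tolist() == [[2.0, 2.0, 2.0]]

    def test_absent_chain_is_lookup_error(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(_pdb_line(1, 1, 0, 0, 0) + "\nEND\n")
        with pytest.raises(LookupError_, match="Z"):
            sio.read_structure_ca(p, "Z")

    def test_multi_model_uses_first(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text("\n".join([
            "MODEL        1",
            _pdb_line(1, 1, 1.0, 0.0, 0.0),
            _pdb_line(2, 2, 2.0, 0.0, 0.0),
            _pdb_line(3, 3, 3.0, 0.0, 1.0),
            "ENDMDL",
            "MODEL        2",
            _pdb_line(1, 1, 9.0, 9.0, 9.0),
            "ENDMDL",
            "END",
        ]))
        s = sio.read_structure_ca(p, "A")
        assert len(s) == 3
        assert s.coords([1]).tolist() == [[1.0, 0.0, 0.0]]


# ---------------------------------------------------------------------------
# numbering offsets
# ---------------------------------------------------------------------------

class TestNumbering:
    def test_construct_tag_offset(self):
        # a construct numbered from −3 lands on 21 after a +24 shift
        table = make_table([(-3, "M", "H", 8.2), (-3, "M", "N", 120.0)])
        shifted = sio.apply_numbering_offset(table, 24)
        assert shifted.residue_numbers == [21]

    def test_offset_zero_is_identity(self):
        table = make_table([(5, "A", "H", 8.0), (5, "A", "N", 118.0)])
        assert sio.apply_numbering_offset(table, 0) == table

    @given(a=st.integers(-50, 50), b=st.integers(-50, 50))
    @settings(max_examples=25, derandomize=True)
    def test_offsets_compose_as_group_action(self, a, b):
        table = make_table([(0, "G", "H", 8.0), (0, "G", "N", 110.0),
                            (7, "K", "H", 7.7), (7, "K", "N", 122.0)])
        via_two = sio.apply_numbering_offset(sio.apply_numbering_offset(table, a), b)
        direct = sio.apply_numbering_offset(table, a + b)
        assert via_two == direct

    def test_sequence_record_offset(self):
        rec = sio.SequenceRecord("x", "GKAM", first_residue_number=-3)
        assert sio.apply_numbering_offset(rec, 24).first_residue_number == 21


class TestAssignmentCompleteness:
    def test_both_range_conventions(self):
        # construct −3…10 with residues −3…4 and a proline unassigned
        entries = []
        for res in range(5, 11):
            entries.append((res, "A", "H", 8.0))
            entries.append((res, "A", "N", 118.0))
        table = make_table(entries)
        types = {r: "M" for r in range(-3, 5)}
        types[7] = "P"
        over_construct = sio.assignment_completeness(table, (-3, 10), types)
        over_core = sio.assignment_completeness(table, (5, 10), types)
        # proline 7 carries assigned atoms in the table, so it still counts
        assert over_core == pytest.approx(1.0)
        assert over_construct == pytest.approx(6 / 14)

    def test_external_proline_excluded_from_denominator(self):
        table = make_table([(1, "A", "H", 8.0), (1, "A", "N", 118.0)])
        frac = sio.assignment_completeness(table, (1, 3), {2: "P", 3: "G"})
        assert frac == pytest.approx(1 / 2)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

class TestReports:
    def test_profile_tsv_round_trip(self, tmp_path, free_bound_pair):
        from csp_pocket.csp_core import compute_csp

        profile = compute_csp(*free_bound_pair)
        p = tmp_path / "profile.tsv"
        sio.write_report(profile, p, "tsv")
        lines = p.read_text().splitlines()
        assert lines[0].split("\t")[:5] == [
            "residue", "delta_H", "delta_N", "delta_weighted", "status"]
        assert len(lines) == 3
        # re-read and compare at serialization precision
        row1 = dict(zip(lines[0].split("\t"), lines[1].split("\t")))
        assert float(row1["delta_weighted"]) == pytest.approx(0.1, abs=1e-6)

    def test_empty_profile_writes_header_only(self, tmp_path):
        from csp_pocket.csp_core import CSPProfile

        p = tmp_path / "empty.tsv"
        sio.write_report(CSPProfile([]), p, "tsv")
        assert p.read_text().splitlines() == [
            "residue\tdelta_H\tdelta_N\tdelta_weighted\tstatus\tsignificant"]

    def test_json_report_is_deterministic(self, tmp_path, free_bound_pair):
        from csp_pocket.csp_core import compute_csp

        profile = compute_csp(*free_bound_pair)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        sio.write_report(profile, p1, "json")
        sio.write_report(profile, p2, "json")
        assert p1.read_bytes() == p2.read_bytes()
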
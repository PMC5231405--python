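"""Structure model, PDB/mmCIF round trips, selection, symmetry, dihedrals."""

import math

import gemmi
import numpy as np
import pytest

from tcsgeom.structure import (Atom, ParseError, Selection, Structure,
                               StructureError, apply_symmetry_operator,
                               backbone_dihedral, dihedral_from_points,
                               read_structure, select, write_structure)
from tcsgeom.superpose import RigidTransform, apply_transform

from conftest import minimal_protein


def _residue_fixture() -> Structure:
    """Three residues over two chains plus a hetero Mg, with a unit cell."""
    rng = np.random.default_rng(7)
    atoms = []
    sn = 0
    for chain, rn, rname in [("A", 10, "HIS"), ("A", 11, "GLY"), ("B", 5, "ASP")]:
        for name in ["N", "CA", "C", "O"]:
            sn += 1
            atoms.append(Atom(sn, name, name[0], rname, chain, rn,
                              rng.normal(scale=6.0, size=3)))
    atoms.append(Atom(sn + 1, "MG", "MG", "MG", "B", 100, [1.0, 2.0, 3.0],
                      is_hetero=True))
    return Structure(atoms=atoms, cell=(20, 22, 24, 80, 95, 100),
                     space_group="P 1", source_id="fix3")


@pytest.mark.parametrize("fmt,ext", [("pdb", ".pdb"), ("mmcif", ".cif")])
def test_roundtrip_preserves_atoms_cell_and_order(tmp_path, fmt, ext):
    s = _residue_fixture()
    path = tmp_path / f"fix{ext}"
    write_structure(s, path, format=fmt)
    s2 = read_structure(path)
    assert s.allclose(s2)
    assert s2.cell == pytest.approx(s.cell)
    assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]
    assert [a.chain_id for a in s2.atoms] == [a.chain_id for a in s.atoms]
    # chain order preserved
    assert s2.chains() == ["A", "B"]


def test_pdb_and_mmcif_serializations_agree(tmp_path):
    s = _residue_fixture()
    write_structure(s, tmp_path / "a.pdb", format="pdb")
    write_structure(s, tmp_path / "a.cif", format="mmcif")
    sp = read_structure(tmp_path / "a.pdb")
    sc = read_structure(tmp_path / "a.cif")
    assert sp.allclose(sc)


def test_single_atom_record_fields_copied(tmp_path):
    path = tmp_path / "one.pdb"
    path.write_text(
        "ATOM      1  NE2 HIS A 188      11.104  22.000  -3.500  1.00 20.00"
        "           N\nEND\n")
    s = read_structure(path)
    assert len(s) == 1
    a = s.atoms[0]
    assert (a.name, a.res_name, a.chain_id, a.res_num) == ("NE2", "HIS", "A", 188)
    assert a.position == pytest.approx([11.104, 22.0, -3.5])
    assert a.element == "N" and not a.is_hetero


def test_unreadable_and_empty_files_raise(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("data_x\n_loop nonsense {{{{\n")
    with pytest.raises((ParseError, StructureError)):
        read_structure(bad, format="mmcif")
    empty = tmp_path / "empty.pdb"
    empty.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(StructureError):
        read_structure(empty)


def test_write_rejects_empty_and_long_atom_names(tmp_path):
    with pytest.raises(StructureError):
        write_structure(Structure(atoms=[]), tmp_path / "x.pdb")
    s = Structure(atoms=[Atom(1, "TOOLONG", "C", "LIG", "A", 1, [0, 0, 0])])
    with pytest.raises(StructureError):
        write_structure(s, tmp_path / "x.pdb", format="pdb")


def test_cryst1_written_when_cell_present(tmp_path):
    s = _residue_fixture()
    write_structure(s, tmp_path / "c.pdb", format="pdb")
    text = (tmp_path / "c.pdb").read_text()
    assert any(line.startswith("CRYST1") and "20.000" in line
               for line in text.splitlines())


def test_altloc_resolution_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00"
        "           C\n"
        "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60 10.00"
        "           C\n"
        "ATOM      3  CB AALA A   1       0.000   2.000   0.000  0.50 10.00"
        "           C\n"
        "ATOM      4  CB BALA A   1       0.000   3.000   0.000  0.50 10.00"
        "           C\nEND\n")
    s = read_structure(path)
    ca = s.find_atoms(name="CA")
    cb = s.find_atoms(name="CB")
    assert len(ca) == 1 and ca[0].position[0] == pytest.approx(1.0)  # occ 0.60
    assert len(cb) == 1 and cb[0].position[1] == pytest.approx(2.0)  # tie -> 'A'


class TestSelection:
    def test_range_selection_counts_inclusively(self):
        s = minimal_protein(n_res=61, start=180)  # residues 180..240
        sel = Selection.make(chains=["A"], res_ranges=[(190, 234)],
                             atom_names=["CA"])
        assert len(select(s, sel)) == 45

    def test_atom_name_selection(self, his_fixture):
        assert len(select(his_fixture, Selection.make(atom_names=["NE2"]))) == 1

    def test_hetero_excluded_unless_requested(self, his_fixture):
        default = select(his_fixture, Selection.make())
        assert all(not a.is_hetero for a in default.atoms)
        withhet = select(his_fixture, Selection.make(include_hetero=True))
        assert any(a.is_hetero for a in withhet.atoms)

    def test_composed_equals_intersection_of_single_predicates(self, his_fixture):
        s = his_fixture
        composed = select(s, Selection.make(chains=["B"], res_ranges=[(50, 60)],
                                            atom_names=["OD1", "OD2", "CA"]))
        by_chain = {id(a) for a in select(s, Selection.make(chains=["B"])).atoms}
        by_range = {id(a) for a in select(s, Selection.make(res_ranges=[(50, 60)])).atoms}
        by_name = {id(a) for a in
                   select(s, Selection.make(atom_names=["OD1", "OD2", "CA"])).atoms}
        assert {id(a) for a in composed.atoms} == by_chain & by_range & by_name

    def test_selection_is_idempotent(self, his_fixture):
        sel = Selection.make(chains=["A"], atom_names=["NE2", "CA"])
        once = select(his_fixture, sel)
        twice = select(once, sel)
        assert once.allclose(twice)


class TestSymmetry:
    def test_identity_operator_is_noop(self):
        s = _residue_fixture()
        assert np.allclose(apply_symmetry_operator(s, "x,y,z").coords,
                           s.coords, atol=1e-9)

    def test_orthogonal_cell_twofold(self):
        s = Structure(atoms=[Atom(1, "CA", "C", "GLY", "A", 1, [1.0, 2.0, 3.0])],
                      cell=(10, 10, 10, 90, 90, 90))
        out = apply_symmetry_operator(s, "-x,-y,z")
        assert out.atoms[0].position == pytest.approx([-1.0, -2.0, 3.0])

    @pytest.mark.parametrize("op", ["x,y,z", "-x,-y,-z", "x+1/2,y,z-1/3",
                                    "-x+1/2,-y,z", "1/4+x,y-1/2,z"])
    def test_triclinic_matches_matrix_oracle(self, op):
        """Independent oracle: build the 4x4 fractional-space matrix from the
        parsed operator and conjugate with the orthogonalization matrix."""
        s = _residue_fixture()
        cell = gemmi.UnitCell(*s.cell)
        gop = gemmi.Op(op)
        W = np.array(gop.rot, dtype=float) / gop.DEN
        w = np.array(gop.tran, dtype=float) / gop.DEN
        M = np.array(cell.orth.mat.tolist())       # frac -> orth
        Minv = np.linalg.inv(M)
        expect = (M @ (W @ (Minv @ s.coords.T) + w[:, None])).T
        out = apply_symmetry_operator(s, op)
        assert np.allclose(out.coords, expect, atol=1e-8)

    @pytest.mark.parametrize("op", ["-x,-y,-z", "x+1/2,y-1/3,z+3/4"])
    def test_lattice_compatible_ops_preserve_distances(self, op):
        # inversion and pure translations are isometries in any cell
        s = _residue_fixture()
        d0 = np.linalg.norm(s.coords[:, None] - s.coords[None], axis=-1)
        out = apply_symmetry_operator(s, op)
        d1 = np.linalg.norm(out.coords[:, None] - out.coords[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-6

    def test_missing_cell_and_bad_operator_raise(self):
        no_cell = Structure(atoms=[Atom(1, "CA", "C", "GLY", "A", 1, [0, 0, 0])])
        with pytest.raises(StructureError):
            apply_symmetry_operator(no_cell, "x,y,z")
        with pytest.raises(ValueError):
            apply_symmetry_operator(_residue_fixture(), "x,q,z")


class TestDihedral:
    def test_fully_extended_psi_is_180(self, extended_chain):
        psi = backbone_dihedral(extended_chain, "A", 2, "psi")
        assert abs(abs(psi) - 180.0) < 1e-6

    @pytest.mark.parametrize("theta", [-150.0, -60.0, 0.0, 60.0, 126.0, 179.0])
    def test_constructed_torsion_matches_gemmi_oracle(self, theta):
        rng = np.random.default_rng(int(abs(theta)) + 3)
        pts = rng.normal(scale=4.0, size=(4, 3))
        oracle = math.degrees(gemmi.calculate_dihedral(
            *[gemmi.Position(*p) for p in pts]))
        assert dihedral_from_points(*pts) == pytest.approx(oracle, abs=1e-9)

    def test_sixty_degree_torsion_by_construction(self):
        # cis reference (torsion 0) rotated by +60 deg about the central bond
        p0, p1, p2 = np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 0, 1.5])
        ref = np.array([1.0, 0, 0])
        theta = math.radians(60.0)
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1.0]])
        p3 = p2 + rot @ ref
        val = dihedral_from_points(p0, p1, p2, p3)
        assert abs(val) == pytest.approx(60.0, abs=1e-9)
        oracle = math.degrees(gemmi.calculate_dihedral(
            *[gemmi.Position(*p) for p in (p0, p1, p2, p3)]))
        assert val == pytest.approx(oracle, abs=1e-9)

    def test_invariant_under_rigid_transform(self, extended_chain):
        from scipy.spatial.transform import Rotation

        psi0 = backbone_dihedral(extended_chain, "A", 3, "psi")
        t = RigidTransform(Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix(),
                           np.array([5.0, -2.0, 7.0]))
        moved = apply_transform(extended_chain, t)
        assert backbone_dihedral(moved, "A", 3, "psi") == pytest.approx(psi0, abs=1e-8)

    def test_missing_atom_and_chain_break_raise(self, extended_chain):
        with pytest.raises(StructureError, match="absent"):
            backbone_dihedral(extended_chain, "A", 6, "psi")  # no residue 7
        s = minimal_protein(n_res=2)
        s.atoms = [a for a in s.atoms if not (a.res_num == 1 and a.name == "CA")]
        with pytest.raises(StructureError, match="CA"):
            backbone_dihedral(s, "A", 1, "psi")
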
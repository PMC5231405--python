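"""Coordinate data model, PDB/mmCIF I/O, atom selection and symmetry expansion.

The in-memory model is deliberately small: an ordered list of :class:`Atom`
records plus unit-cell / space-group metadata.  File parsing and writing and
the fractional-coordinate algebra of crystallographic symmetry operators are
delegated to :mod:`gemmi`; everything downstream (superposition, reaction
center geometry, surface metrics) works on this model only.

Residues are addressed by author numbering (with insertion codes) throughout,
because that is how reactive residues in TCS complexes are cited in the
literature (His188, Asp54, Pro85).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom", "Structure", "Selection", "StructureError", "ParseError",
    "read_structure", "write_structure", "select",
    "apply_symmetry_operator", "backbone_dihedral",
]


class StructureError(ValueError):
    """Invalid structure content or an unsatisfiable structural request."""


class ParseError(StructureError):
    """A coordinate file could not be parsed under the named standard."""


@dataclass
class Atom:
    """One atom record, PDB v3 naming conventions (NE2, OD1, MG, BE, PG...)."""

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_num: int
    position: np.ndarray
    icode: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def res_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_num, self.icode)

    def distance(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.position - other.position))

    def same_fields(self, other: "Atom", coord_tol: float = 1e-3) -> bool:
        """Field-wise equality with a coordinate tolerance (format precision)."""
        return (
            self.name == other.name
            and self.element == other.element
            and self.res_name == other.res_name
            and self.chain_id == other.chain_id
            and self.res_num == other.res_num
            and self.icode == other.icode
            and self.is_hetero == other.is_hetero
            and abs(self.occupancy - other.occupancy) <= 0.01
            and np.allclose(self.position, other.position, atol=coord_tol)
        )


@dataclass
class Structure:
    """An ordered atom collection with optional crystal metadata.

    ``cell`` is ``(a, b, c, alpha, beta, gamma)`` in Å / degrees, or ``None``;
    ``space_group`` is a Hermann–Mauguin label or ``None``.
    """

    atoms: list[Atom] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    model_index: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.cell is not None:
            a, b, c, al, be, ga = self.cell
            if min(a, b, c) <= 0 or not all(0.0 < x < 180.0 for x in (al, be, ga)):
                raise StructureError(f"invalid unit cell {self.cell}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in Å (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy of the structure with positions replaced row-by-row."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [replace(a, position=xyz[i].copy()) for i, a in enumerate(self.atoms)]
        return replace(self, atoms=atoms)

    def copy(self) -> "Structure":
        return replace(self, atoms=[replace(a, position=a.position.copy()) for a in self.atoms])

    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def find_atoms(self, chain_id: str | None = None, res_num: int | None = None,
                   name: str | None = None, res_name: str | None = None) -> list[Atom]:
        out = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if res_num is not None and a.res_num != res_num:
                continue
            if name is not None and a.name != name:
                continue
            if res_name is not None and a.res_name != res_name:
                continue
            out.append(a)
        return out

    def allclose(self, other: "Structure", coord_tol: float = 1e-3) -> bool:
        return len(self) == len(other) and all(
            a.same_fields(b, coord_tol) for a, b in zip(self.atoms, other.atoms)
        )


@dataclass
class Selection:
    """Predicate bundle for sub-structure extraction.

    All stated predicates must hold simultaneously.  Residue ranges use author
    numbering and are inclusive at both ends.  Hydrogens and hetero atoms are
    excluded unless explicitly requested, matching how the downstream geometry
    and surface calculations treat X-ray models.
    """

    chains: frozenset[str] | None = None
    res_ranges: tuple[tuple[int, int], ...] | None = None
    atom_names: frozenset[str] | None = None
    include_hetero: bool = False
    hetero_only: bool = False
    include_hydrogens: bool = False

    @classmethod
    def make(cls, chains=None, res_ranges=None, atom_names=None,
             include_hetero=False, hetero_only=False, include_hydrogens=False) -> "Selection":
        return cls(
            chains=frozenset(chains) if chains is not None else None,
            res_ranges=tuple(tuple(r) for r in res_ranges) if res_ranges is not None else None,
            atom_names=frozenset(atom_names) if atom_names is not None else None,
            include_hetero=include_hetero,
            hetero_only=hetero_only,
            include_hydrogens=include_hydrogens,
        )

    def matches(self, a: Atom) -> bool:
        if a.element == "H" and not self.include_hydrogens:
            return False
        if a.is_hetero and not (self.include_hetero or self.hetero_only):
            return False
        if self.hetero_only and not a.is_hetero:
            return False
        if self.chains is not None and a.chain_id not in self.chains:
            return False
        if self.res_ranges is not None and not any(
            lo <= a.res_num <= hi for lo, hi in self.res_ranges
        ):
            return False
        if self.atom_names is not None and a.name not in self.atom_names:
            return False
        return True


def select(s: Structure, sel: Selection) -> Structure:
    """Sub-structure of atoms satisfying every predicate of ``sel``.

    An empty result is valid.  Atom order is preserved.
    """
    return replace(s, atoms=[a for a in s.atoms if sel.matches(a)])


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)

_DEFAULT_CELL = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one altloc per (residue, atom name): highest occupancy, ties by
    lexicographically first altloc."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain_id, a.res_num, a.icode, a.res_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[key] = a
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # later in reverse-lexicographic order wins the max() above, i.e. 'A' beats 'B'
    return -ord(altloc) if altloc else 0.0


def _from_gemmi(st: gemmi.Structure, model_index: int, source_id: str) -> Structure:
    if len(st) == 0:
        raise StructureError(f"{source_id}: no models in file")
    try:
        model = st[model_index - 1]
    except IndexError:
        raise StructureError(f"{source_id}: model {model_index} not present") from None
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            for at in res:
                serial += 1
                atoms.append(Atom(
                    serial=at.serial if at.serial else serial,
                    name=at.name,
                    element=at.element.name.upper(),
                    res_name=res.name,
                    chain_id=chain.name,
                    res_num=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    altloc=at.altloc.strip() if at.altloc else "",
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    b_factor=at.b_iso,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    is_hetero=is_het,
                ))
    if not atoms:
        raise StructureError(f"{source_id}: structure contains zero atoms")
    atoms = _resolve_altlocs(atoms)
    cell = None
    if st.cell and st.cell.a > 0:
        c = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
        if tuple(round(x, 3) for x in c) != _DEFAULT_CELL:
            cell = c
    sg = st.spacegroup_hm if st.spacegroup_hm and st.spacegroup_hm != "P 1" else (
        st.spacegroup_hm if cell is not None else None)
    return Structure(atoms=atoms, cell=cell, space_group=sg or None,
                     model_index=model_index, source_id=source_id)


def read_structure(path: str | os.PathLike, format: str = "auto",
                   model_index: int = 1) -> Structure:
    """Read a PDB or mmCIF coordinate file.

    Returns model ``model_index`` (1-based; default the first model).
    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken alphabetically).  Unit cell and space group are captured
    from CRYST1 / the mmCIF cell and symmetry categories when present.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(path)
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
        elif fmt == "auto":
            st = gemmi.read_structure(path)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    source = os.path.splitext(os.path.basename(path))[0]
    return _from_gemmi(st, model_index, source)


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.source_id or "model"
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell)
    if s.space_group:
        st.spacegroup_hm = s.space_group
    model = gemmi.Model(1)
    chain_objs: dict[str, gemmi.Chain] = {}
    last_res_key: tuple | None = None
    res_obj: gemmi.Residue | None = None
    for a in s.atoms:
        if len(a.name) > 4:
            raise StructureError(f"atom name {a.name!r} exceeds the 4-character PDB field")
        if a.chain_id not in chain_objs:
            chain_objs[a.chain_id] = gemmi.Chain(a.chain_id)
            model.add_chain(chain_objs[a.chain_id])
            last_res_key = None
        res_key = (a.chain_id, a.res_num, a.icode, a.res_name)
        if res_key != last_res_key:
            res_obj = gemmi.Residue()
            res_obj.name = a.res_name
            res_obj.seqid = gemmi.SeqId(a.res_num, a.icode or " ")
            res_obj.het_flag = "H" if a.is_hetero else "A"
            # chain reference from model (add_chain copies)
            model[a.chain_id].add_residue(res_obj)
            last_res_key = res_key
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.position)
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        at.serial = a.serial
        if a.altloc:
            at.altloc = a.altloc
        model[a.chain_id][-1].add_atom(at)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | os.PathLike, format: str = "auto") -> None:
    """Write ``s`` as PDB or mmCIF; the emitted file re-reads to an equal
    structure within format precision (PDB coordinates carry 3 decimals)."""
    if len(s) == 0:
        raise StructureError("refusing to write an empty structure")
    path = os.fspath(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    st = _to_gemmi(s)
    if fmt == "pdb":
        st.write_pdb(path)
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Crystallographic symmetry

def apply_symmetry_operator(s: Structure, op: str) -> Structure:
    """Apply a symmetry operator given in fractional notation (e.g.
    ``-y,x-y,z+2/3``) to every atom.

    Positions are orthogonal→fractional converted using the structure's unit
    cell (standard PDB orthogonalization frame), transformed, and converted
    back.  Intra-molecular distances are preserved to numerical precision.
    """
    if s.cell is None:
        raise StructureError("symmetry expansion requires unit-cell parameters")
    try:
        gop = gemmi.Op(op)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse symmetry operator {op!r}: {exc}") from exc
    cell = gemmi.UnitCell(*s.cell)
    out = np.empty((len(s), 3))
    for i, a in enumerate(s.atoms):
        fr = cell.fractionalize(gemmi.Position(*a.position))
        fx, fy, fz = gop.apply_to_xyz([fr.x, fr.y, fr.z])
        pos = cell.orthogonalize(gemmi.Fractional(fx, fy, fz))
        out[i] = (pos.x, pos.y, pos.z)
    return s.with_coords(out)


# ---------------------------------------------------------------------------
# Backbone dihedrals

def dihedral_from_points(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                         p3: np.ndarray) -> float:
    """Signed torsion angle of four points, IUPAC convention, degrees in
    (−180, 180]."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def backbone_dihedral(s: Structure, chain: str, res_num: int, angle: str,
                      icode: str = "") -> float:
    """Backbone φ or ψ of residue ``res_num`` in ``chain``, degrees.

    ψ is defined by N(i), CA(i), C(i), N(i+1); φ by C(i−1), N(i), CA(i), C(i).
    The following residue is located by author numbering (next residue in
    chain order sharing the chain id), so a chain break raises.
    """
    angle = angle.lower()
    if angle not in ("phi", "psi"):
        raise ValueError("angle must be 'phi' or 'psi'")

    def get(rnum: int, name: str, what: str) -> np.ndarray:
        hits = [a for a in s.atoms
                if a.chain_id == chain and a.res_num == rnum and a.name == name]
        if not hits:
            raise StructureError(
                f"cannot compute {angle} of {chain}{res_num}: atom {name} of "
                f"residue {rnum} ({what}) is absent")
        return hits[0].position

    if angle == "psi":
        pts = [get(res_num, "N", "residue i"), get(res_num, "CA", "residue i"),
               get(res_num, "C", "residue i"), get(res_num + 1, "N", "residue i+1")]
    else:
        pts = [get(res_num - 1, "C", "residue i-1"), get(res_num, "N", "residue i"),
               get(res_num, "CA", "residue i"), get(res_num, "C", "residue i")]
    return dihedral_from_points(*pts)
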
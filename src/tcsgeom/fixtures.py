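"""Synthetic coordinate fixtures with analytic ground truth.

Every generator returns a legal :class:`~tcsgeom.structure.Structure` (written
through the normal PDB/mmCIF path when a file is requested, so parsing is
exercised rather than bypassed) together with a ground-truth record that the
corresponding analysis operation must recover: reaction-center distances and
ratios, rigid-motion parameters, slippage-matrix cells, closed-form sphere
SASA/BSA, and the flat-limit Sc of facing dot planes.

Geometry is minimal, not physical: residues carry just enough atoms for the
measurement paths (His with Nε2, Asp with Oδ1/Oδ2, backbone for dihedrals),
with deterministic placement from the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from tcsgeom.slippage import ComplexEntry
from tcsgeom.structure import Atom, Structure, write_structure
from tcsgeom.superpose import RigidTransform, apply_transform

__all__ = [
    "DEFAULT_SEED", "DotSurface", "make_reaction_center", "make_rigid_pair",
    "make_slippage_series", "make_sphere_system", "make_sc_surfaces",
    "sphere_sasa_isolated", "two_sphere_buried_area", "write_fixture",
]

#: default generator seed (documented, fixed)
DEFAULT_SEED = 20161212


def _atom(serial, name, element, res_name, chain, res_num, pos, het=False):
    return Atom(serial=serial, name=name, element=element, res_name=res_name,
                chain_id=chain, res_num=res_num, position=np.asarray(pos, float),
                is_hetero=het)


def _jittered_backbone(rng, origin, chain, res_num, res_name, serial0):
    """Backbone + CB scaffold near ``origin`` (plausible, not physical)."""
    base = np.asarray(origin, float)
    offs = {"N": [-1.2, 0.8, 0.3], "CA": [0, 0, 0], "C": [1.3, 0.6, -0.2],
            "O": [1.5, 1.8, -0.4], "CB": [-0.4, -1.3, 0.9]}
    atoms = []
    for k, (name, off) in enumerate(offs.items()):
        pos = base + np.asarray(off) + rng.normal(scale=0.02, size=3)
        el = name[0]
        atoms.append(_atom(serial0 + k, name, el, res_name, chain, res_num, pos))
    return atoms


def make_reaction_center(d_his_asp: float, d_mg_asp: float, d_mg_his: float,
                         with_surrogate: bool = False,
                         seed: int = DEFAULT_SEED) -> tuple[Structure, dict]:
    """Minimal His/Asp/Mg²⁺ reaction center at exactly the requested distances.

    His Nε2 sits at the origin, Asp Oδ1 at ``(d_his_asp, 0, 0)`` and the
    cation at the triangle point satisfying both Mg distances.  With
    ``with_surrogate`` a phospho-His phosphorus is placed on the Nε2→Oδ1 axis
    (1.9 Å from Nε2), giving an in-line ~180° donor–phosphorus–acceptor
    arrangement.  Distances violating the triangle inequality raise.
    """
    for nm, v in (("d_his_asp", d_his_asp), ("d_mg_asp", d_mg_asp),
                  ("d_mg_his", d_mg_his)):
        if v <= 0:
            raise ValueError(f"{nm} must be positive")
    x_mg = (d_his_asp ** 2 + d_mg_his ** 2 - d_mg_asp ** 2) / (2 * d_his_asp)
    y2 = d_mg_his ** 2 - x_mg ** 2
    if y2 < -1e-12:
        raise ValueError(
            f"infeasible geometry: no Mg position at {d_mg_asp} Å from Asp and "
            f"{d_mg_his} Å from His with d_his_asp={d_his_asp} Å "
            "(triangle inequality violated)")
    mg_pos = np.array([x_mg, np.sqrt(max(0.0, y2)), 0.0])

    rng = np.random.default_rng(seed)
    ne2 = np.zeros(3)
    od1 = np.array([d_his_asp, 0.0, 0.0])
    atoms: list[Atom] = []
    # His 188 on chain A: imidazole tip is NE2; ring + backbone filler
    atoms += _jittered_backbone(rng, ne2 + [-2.5, -2.5, 0.5], "A", 188, "HIS", 1)
    ring = {"CG": [-1.8, -1.2, 0.4], "ND1": [-1.9, 0.15, 0.3],
            "CD2": [-0.55, -1.55, 0.2], "CE1": [-0.75, 0.85, 0.1],
            "NE2": [0.0, 0.0, 0.0]}
    for k, (name, off) in enumerate(ring.items()):
        el = name[0]
        atoms.append(_atom(6 + k, name, el, "HIS", "A", 188, ne2 + np.asarray(off)))
    # Asp 54 on chain B
    atoms += _jittered_backbone(rng, od1 + [2.5, -2.0, -0.5], "B", 54, "ASP", 20)
    atoms.append(_atom(25, "CG", "C", "ASP", "B", 54, od1 + [1.05, -0.75, 0.1]))
    atoms.append(_atom(26, "OD1", "O", "ASP", "B", 54, od1))
    atoms.append(_atom(27, "OD2", "O", "ASP", "B", 54, od1 + [1.4, -1.9, 0.3]))
    atoms.append(_atom(30, "MG", "MG", "MG", "B", 201, mg_pos, het=True))
    truth = {"d_his_asp": d_his_asp, "d_mg_asp": d_mg_asp,
             "d_mg_his": d_mg_his, "r_mg": d_mg_asp / d_mg_his}
    if with_surrogate:
        p_pos = np.array([1.9, 0.0, 0.0])   # on the Nε2→Oδ1 axis
        atoms.append(_atom(31, "P", "P", "HIS", "A", 188, p_pos))
        truth["d_rxn"] = d_his_asp - 1.9
        truth["angle_n_p_o"] = 180.0
    s = Structure(atoms=atoms, source_id=f"synthetic-center-{seed}")
    return s, truth


def make_rigid_pair(n_atoms: int = 50, angle_deg: float = 90.0,
                    axis=(0.0, 0.0, 1.0), translation=(1.0, 2.0, 3.0),
                    noise_sd: float = 0.0,
                    seed: int = DEFAULT_SEED) -> tuple[Structure, Structure, RigidTransform]:
    """A random Cα cloud and its rigid-motion copy, with the true transform.

    The second structure is the first mapped by ``x -> R x + t`` (rotation
    ``angle_deg`` about ``axis``), optionally plus isotropic Gaussian noise.
    ``n_atoms >= 4`` guarantees a non-degenerate fit in practice (the cloud
    is full-rank with probability 1).
    """
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms")
    rng = np.random.default_rng(seed)
    xyz = rng.normal(scale=8.0, size=(n_atoms, 3))
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix()
    t = np.asarray(translation, float)
    true = RigidTransform(R, t)
    atoms_a = [_atom(i + 1, "CA", "C", "GLY", "A", i + 1, xyz[i])
               for i in range(n_atoms)]
    a = Structure(atoms=atoms_a, source_id="rigid-pair-a")
    b = apply_transform(a, true)
    if noise_sd > 0:
        b = b.with_coords(b.coords + rng.normal(scale=noise_sd, size=(n_atoms, 3)))
    b.source_id = "rigid-pair-b"
    return a, b, true


def make_slippage_series(displacements: list, seed: int = DEFAULT_SEED,
                         scramble: bool = True) -> tuple[list[ComplexEntry], dict]:
    """Complexes sharing a rigid DHp-like scaffold with the REC-like domain
    rigidly displaced per entry.

    Ground truth: DHp-regime cell (i,j) = |δ_i − δ_j| (the REC domains are
    internally identical, so the evaluation rmsd equals the relative
    displacement magnitude), REC-regime cells = 0.  With ``scramble`` each
    entry is additionally moved by a global rigid transform, which must not
    change any cell.
    """
    displacements = [np.asarray(d, float) for d in displacements]
    if len(displacements) < 2:
        raise ValueError("need at least two entries")
    rng = np.random.default_rng(seed)
    # DHp-like scaffold: helix-ish Cα trace, residues 190-234 on two chains
    n_dhp = 45
    tt = np.arange(n_dhp)
    helix = np.column_stack([2.3 * np.cos(tt * 1.75), 2.3 * np.sin(tt * 1.75),
                             1.5 * tt])
    dhp_a = helix
    dhp_b = helix + np.array([6.0, 0.0, 0.0])
    rec = rng.normal(scale=6.0, size=(129, 3)) + np.array([15.0, 0.0, 20.0])
    entries = []
    n = len(displacements)
    for idx, delta in enumerate(displacements):
        atoms = []
        sn = 0
        for k in range(n_dhp):
            sn += 1
            atoms.append(_atom(sn, "CA", "C", "ALA", "A", 190 + k, dhp_a[k]))
        for k in range(n_dhp):
            sn += 1
            atoms.append(_atom(sn, "CA", "C", "ALA", "B", 190 + k, dhp_b[k]))
        for k in range(129):
            sn += 1
            atoms.append(_atom(sn, "CA", "C", "ALA", "C", 1 + k, rec[k] + delta))
        s = Structure(atoms=atoms, source_id=f"slip-{idx}")
        if scramble:
            R = Rotation.random(random_state=np.random.RandomState(seed + idx)
                                ).as_matrix()
            tr = RigidTransform(R, rng.normal(scale=20.0, size=3))
            s = apply_transform(s, tr)
        entries.append(ComplexEntry(f"synthetic-{idx}", s, ("A", "B"), "C"))
    truth_dhp = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            truth_dhp[i, j] = np.linalg.norm(displacements[i] - displacements[j])
    truth = {"m_dhp": truth_dhp, "m_rec": np.zeros((n, n))}
    return entries, truth


# ---------------------------------------------------------------------------
# analytic SASA/BSA oracles

def sphere_sasa_isolated(r_vdw: float, probe: float = 1.4) -> float:
    """Closed-form SASA of an isolated sphere: 4π(r+p)²."""
    R = r_vdw + probe
    return 4.0 * np.pi * R * R


def two_sphere_buried_area(r1: float, r2: float, d: float,
                           probe: float = 1.4) -> tuple[float, float]:
    """Closed-form buried area on each of two intersecting probe-expanded
    spheres (spherical-cap formula); zero when they do not intersect."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 0.0, 0.0
    if d <= abs(R1 - R2):
        inner = 4.0 * np.pi * min(R1, R2) ** 2
        return (inner, 0.0) if R1 < R2 else (0.0, inner)
    x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h1 = R1 - x1
    h2 = R2 - (d - x1)
    return 2.0 * np.pi * R1 * h1, 2.0 * np.pi * R2 * h2


def make_sphere_system(radii: list, centers: list,
                       probe: float = 1.4) -> tuple[Structure, dict]:
    """Atoms as free spheres, with closed-form SASA/BSA ground truth.

    For one or two spheres the ground truth is exact (isolated-sphere and
    spherical-cap formulas); for more, only the isolated-sphere total of
    well-separated subsets is recorded.
    """
    radii = [float(r) for r in radii]
    centers = [np.asarray(c, float) for c in centers]
    if len(radii) != len(centers) or not radii:
        raise ValueError("radii and centers must match and be non-empty")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    atoms = [_atom(i + 1, "SPH", "C", "SPH", "A", i + 1, c, het=True)
             for i, c in enumerate(centers)]
    s = Structure(atoms=atoms, source_id="sphere-system")
    truth: dict = {"radii": radii,
                   "sasa_isolated": [sphere_sasa_isolated(r, probe) for r in radii]}
    if len(radii) == 2:
        d = float(np.linalg.norm(centers[1] - centers[0]))
        b1, b2 = two_sphere_buried_area(radii[0], radii[1], d, probe)
        truth["bsa_total"] = b1 + b2
        truth["sasa_total"] = sum(truth["sasa_isolated"]) - b1 - b2
    elif len(radii) == 1:
        truth["sasa_total"] = truth["sasa_isolated"][0]
        truth["bsa_total"] = 0.0
    return s, truth


@dataclass
class DotSurface:
    """A sampled surface patch: dot positions plus outward unit normals."""

    points: np.ndarray
    normals: np.ndarray


def make_sc_surfaces(gap: float = 0.5, curvature: float = 0.0,
                     half_width: float = 6.0, spacing: float = 0.35,
                     w: float = 0.5) -> tuple[DotSurface, DotSurface, dict]:
    """Two facing dot surfaces for the Sc statistic, with analytic ground truth.

    Surface A is the plane z=0 with normals +z; surface B sits at
    ``z = gap + curvature·(x²+y²)`` with inward-facing (downward) normals.
    With zero curvature the two grids are in registry, every nearest-dot
    distance equals ``gap`` and the normals are exactly antiparallel, so
    Sc = exp(−w·gap²) — approaching 1 as the gap closes.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    g = np.arange(-half_width, half_width + spacing / 2, spacing)
    X, Y = np.meshgrid(g, g)
    xy = np.column_stack([X.ravel(), Y.ravel()])
    pts_a = np.column_stack([xy, np.zeros(len(xy))])
    nrm_a = np.tile([0.0, 0.0, 1.0], (len(xy), 1))
    zb = gap + curvature * (xy[:, 0] ** 2 + xy[:, 1] ** 2)
    pts_b = np.column_stack([xy, zb])
    # downward normal of the surface z = f(x, y), normalized
    gx = 2.0 * curvature * xy[:, 0]
    gy = 2.0 * curvature * xy[:, 1]
    nrm_b = np.column_stack([gx, gy, -np.ones(len(xy))])
    nrm_b /= np.linalg.norm(nrm_b, axis=1, keepdims=True)
    truth = {"gap": gap, "w": w, "curvature": curvature,
             "sc_flat_limit": float(np.exp(-w * gap * gap)) if curvature == 0 else None}
    return DotSurface(pts_a, nrm_a), DotSurface(pts_b, nrm_b), truth


def write_fixture(s: Structure, truth: dict, path: str,
                  format: str = "pdb") -> None:
    """Write a fixture structure plus a sidecar ``<path>.json`` ground-truth
    record (matrix values listed, numpy types coerced)."""
    write_structure(s, path, format=format)

    def coerce(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    with open(os.fspath(path) + ".json", "w") as fh:
        json.dump({k: coerce(v) for k, v in truth.items()}, fh, indent=1)
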
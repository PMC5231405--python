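"""Phosphotransfer reaction-center geometry and mechanism classification.

A two-component phosphotransfer reaction center comprises the phosphorylatable
histidine Nε2 (HK side), the receiver aspartate carboxylate Oδ (RR side), the
divalent Mg²⁺ cation that organizes the RR active site, and — when present —
a phosphorus atom or surrogate marking the migrating phosphoryl group
(phospho-His P, BeF₃⁻ beryllium mimicking P~Asp, or the γ-phosphorus of a
non-hydrolyzable ATP analogue in autophosphorylation-competent kinases).

Two discriminants separate tight (associative-compatible) from loose
(dissociative) nucleophilic-substitution geometries:

* ``d_his_asp`` — the His(Nε2)–Asp(Oδ1) distance.  Short (< 6.5 Å) centers
  can accommodate a pentacoordinate transition state with simultaneous bond
  formation and rupture; beyond ~6.6 Å there is room, counting van der Waals
  radii, for a fully dissociated metaphosphate intermediate.
* ``r_mg`` — the Mg²⁺ asymmetry ratio d(Mg–AspOδ1)/d(Mg–HisNε2).  A cation
  sitting symmetrically between donor and acceptor (ratio near 1) stabilizes
  an in-line associative geometry; a cation pulled toward the Asp side
  (ratio < 0.6) marks the asymmetric, dissociative arrangement in which the
  metaphosphate migrates toward the RR's positive charges.

Group I = associative-compatible, Group II = dissociative; geometries
straddling the cuts are reported as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tcsgeom.structure import Atom, Structure, StructureError

__all__ = [
    "ReactionCenterSpec", "ReactiveAtoms", "ReactionCenterGeometry",
    "MechanismCall", "locate_reactive_atoms", "measure_center",
    "classify_mechanism", "batch_table",
    "D_CUT_DEFAULT", "R_CUT_DEFAULT", "D_RXN_DISSOCIATION_ROOM",
]

D_CUT_DEFAULT = 6.5      # Å, His(Nε2)–Asp(Oδ1) discriminant
R_CUT_DEFAULT = 0.6      # Mg–Asp / Mg–His distance-ratio discriminant
D_RXN_DISSOCIATION_ROOM = 4.9   # Å, reaction-coordinate length leaving room
                                # for a fully dissociated metaphosphate

#: residue codes recognized as phosphorylated histidine variants (configurable)
PHOSPHO_HIS_CODES = ("NEP", "HIP", "HISP")
#: ligand codes whose beryllium mimics a transferred phosphoryl on Asp
BEF_CODES = ("BEF", "BF3")
#: non-hydrolyzable ATP-analogue codes carrying a gamma-phosphorus
ATP_ANALOG_CODES = ("ACP", "ANP", "AGS", "ATP")

_MG_AUTO_CUTOFF = 8.0    # Å, search radius for an unspecified divalent cation
_DIVALENT = ("MG", "MN", "CA", "ZN")


@dataclass
class ReactionCenterSpec:
    """Where to find the reactive atoms of one HK:RR (or HK:ATP) center.

    ``mg`` is a ``(chain, resnum)`` tuple, ``"auto"`` (nearest divalent cation
    within 8 Å of the Asp Oδ pair) or ``None`` (no cation, ratio undefined).
    ``surrogate`` selects the phosphorus stand-in: ``"auto"`` probes, in
    order, a phospho-His phosphorus, a BeF₃⁻ beryllium near the Asp, and an
    ATP-analogue γ-phosphorus; ``"none"`` disables the reaction-coordinate
    distance.  ``od_policy`` is ``"OD1"`` (the conventional choice) or
    ``"nearest"`` (the carboxylate oxygen closer to the His Nε2, since
    crystallographic OD1/OD2 labeling is chemically arbitrary).
    """

    hk_chain: str
    his_resnum: int
    rr_chain: str
    asp_resnum: int
    mg: tuple[str, int] | str | None = "auto"
    surrogate: str = "auto"           # auto | p_his | bef | atp_gamma | none
    od_policy: str = "OD1"
    label: str = ""


@dataclass
class ReactiveAtoms:
    """Resolved atom handles for one reaction center."""

    ne2: Atom
    od: Atom
    mg: Atom | None = None
    surrogate: Atom | None = None
    surrogate_kind: str | None = None     # p_his | bef | atp_gamma
    bridge: Atom | None = None            # β–γ bridging atom of an ATP analogue


@dataclass
class ReactionCenterGeometry:
    """One measured reaction center (full precision; round only for display)."""

    d_his_asp: float
    d_rxn: float | None = None
    d_mg_asp: float | None = None
    d_mg_his: float | None = None
    r_mg: float | None = None
    od_used: str = "OD1"
    surrogate_kind: str | None = None
    modeled_flags: dict[str, str] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        for name in ("d_his_asp", "d_rxn", "d_mg_asp", "d_mg_his", "r_mg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass
class MechanismCall:
    """Associative/dissociative verdict with the thresholds that produced it."""

    group: str                 # "I" | "II" | "ambiguous"
    mechanism: str             # "associative-compatible" | "dissociative" | "ambiguous"
    d_cut: float
    r_cut: float
    rationale: str
    confident: bool = True


def _require_atom(s: Structure, chain: str, resnum: int, names: tuple[str, ...],
                  what: str) -> Atom:
    for name in names:
        hits = s.find_atoms(chain_id=chain, res_num=resnum, name=name)
        if hits:
            return hits[0]
    raise StructureError(
        f"{what}: atom {'/'.join(names)} of residue {chain}{resnum} not found")


def locate_reactive_atoms(s: Structure, spec: ReactionCenterSpec) -> ReactiveAtoms:
    """Resolve the Nε2, Oδ, Mg²⁺ and phospho-surrogate handles named by ``spec``.

    A missing cation under the ``"auto"`` policy is reported as an absent
    handle, not an error (the asymmetry ratio is then undefined).
    """
    ne2 = _require_atom(s, spec.hk_chain, spec.his_resnum, ("NE2",),
                        "reactive His")
    od1 = _require_atom(s, spec.rr_chain, spec.asp_resnum, ("OD1",),
                        "receiver Asp")
    od2_hits = s.find_atoms(chain_id=spec.rr_chain, res_num=spec.asp_resnum, name="OD2")
    od = od1
    if spec.od_policy == "nearest" and od2_hits:
        od = min((od1, od2_hits[0]), key=lambda a: a.distance(ne2))
    elif spec.od_policy not in ("OD1", "nearest"):
        raise ValueError(f"unknown od_policy {spec.od_policy!r}")

    mg: Atom | None = None
    if isinstance(spec.mg, tuple):
        mg = _require_atom(s, spec.mg[0], spec.mg[1], _DIVALENT, "cation")
    elif spec.mg == "auto":
        cands = [a for a in s.atoms
                 if a.name in _DIVALENT and a.element in _DIVALENT]
        ref = [od1.position] + ([od2_hits[0].position] if od2_hits else [])
        cands = [a for a in cands
                 if min(np.linalg.norm(a.position - r) for r in ref) < _MG_AUTO_CUTOFF]
        if cands:
            mg = min(cands, key=lambda a: a.distance(od))
    elif spec.mg is not None:
        raise ValueError(f"unknown mg selector {spec.mg!r}")

    surrogate = bridge = None
    kind = None
    want = spec.surrogate
    if want not in ("auto", "p_his", "bef", "atp_gamma", "none"):
        raise ValueError(f"unknown surrogate selector {want!r}")
    if want != "none":
        # phospho-His phosphorus: a P atom on the His residue itself (or a
        # phospho-His variant residue code at the same position)
        if want in ("auto", "p_his"):
            hits = [a for a in s.find_atoms(chain_id=spec.hk_chain,
                                            res_num=spec.his_resnum)
                    if a.element == "P"
                    and a.res_name in ("HIS",) + PHOSPHO_HIS_CODES]
            if hits:
                surrogate, kind = hits[0], "p_his"
        if surrogate is None and want in ("auto", "bef"):
            bes = [a for a in s.atoms if a.res_name in BEF_CODES and a.element == "BE"]
            bes = [a for a in bes if a.distance(od) < 5.0]
            if bes:
                surrogate, kind = min(bes, key=lambda a: a.distance(od)), "bef"
        if surrogate is None and want in ("auto", "atp_gamma"):
            pgs = [a for a in s.atoms
                   if a.res_name in ATP_ANALOG_CODES and a.name == "PG"]
            if pgs:
                surrogate = min(pgs, key=lambda a: a.distance(ne2))
                kind = "atp_gamma"
                bridges = [a for a in s.atoms
                           if a.res_name == surrogate.res_name
                           and a.chain_id == surrogate.chain_id
                           and a.res_num == surrogate.res_num
                           and a.name in ("O3B", "C3B")]
                bridge = bridges[0] if bridges else None
        if surrogate is None and want != "auto":
            raise StructureError(f"requested phospho-surrogate {want!r} not found")
    return ReactiveAtoms(ne2=ne2, od=od, mg=mg, surrogate=surrogate,
                         surrogate_kind=kind, bridge=bridge)


def measure_center(s: Structure, spec: ReactionCenterSpec) -> ReactionCenterGeometry:
    """Measure the reaction-center distances defined by ``spec``.

    ``d_his_asp`` is Nε2→Oδ, except for autophosphorylation centers (ATP
    analogue bound) where the Asp-equivalent position is the β–γ bridging
    atom of the analogue.  ``d_rxn`` is the phosphorus (or surrogate) to the
    entering nucleophile: Oδ for P~His→Asp transfer, Nε2 when the phosphoryl
    sits on the Asp (BeF₃⁻) or on ATP.  Full precision is retained; display
    rounding (one decimal Å, two-decimal ratios) is left to the reporting
    layer.
    """
    ra = locate_reactive_atoms(s, spec)
    modeled = {}
    for role, at in (("ne2", ra.ne2), ("od", ra.od), ("mg", ra.mg),
                     ("surrogate", ra.surrogate)):
        if at is not None and at.provenance:
            modeled[role] = at.provenance

    if ra.surrogate_kind == "atp_gamma" and ra.bridge is not None:
        d_his_asp = ra.ne2.distance(ra.bridge)
    else:
        d_his_asp = ra.ne2.distance(ra.od)

    d_rxn = None
    if ra.surrogate is not None:
        entering = ra.od if ra.surrogate_kind == "p_his" else ra.ne2
        d_rxn = ra.surrogate.distance(entering)

    d_mg_asp = d_mg_his = r_mg = None
    if ra.mg is not None:
        d_mg_asp = ra.mg.distance(ra.od)
        d_mg_his = ra.mg.distance(ra.ne2)
        r_mg = d_mg_asp / d_mg_his
    return ReactionCenterGeometry(
        d_his_asp=d_his_asp, d_rxn=d_rxn, d_mg_asp=d_mg_asp,
        d_mg_his=d_mg_his, r_mg=r_mg, od_used=ra.od.name,
        surrogate_kind=ra.surrogate_kind, modeled_flags=modeled,
        label=spec.label)


def classify_mechanism(g: ReactionCenterGeometry,
                       d_cut: float = D_CUT_DEFAULT,
                       r_cut: float = R_CUT_DEFAULT) -> MechanismCall:
    """Associative vs dissociative call from (d_his_asp, r_mg).

    Group I (associative-compatible): d < d_cut AND ratio > r_cut.
    Group II (dissociative): d > d_cut AND ratio < r_cut.
    Anything else — including either value exactly at its cut — is ambiguous.
    Without a cation the call falls back to the distance alone and is flagged
    lower-confidence.
    """
    d, r = g.d_his_asp, g.r_mg
    notes = []
    confident = True
    if r is None:
        confident = False
        if d < d_cut:
            group, mech = "I", "associative-compatible"
        elif d > d_cut:
            group, mech = "II", "dissociative"
        else:
            group, mech = "ambiguous", "ambiguous"
        notes.append("no Mg2+ cation: distance-only call")
    elif d < d_cut and r > r_cut:
        group, mech = "I", "associative-compatible"
        notes.append(f"d={d:.1f} Å < {d_cut} Å and ratio={r:.2f} > {r_cut}")
    elif d > d_cut and r < r_cut:
        group, mech = "II", "dissociative"
        notes.append(f"d={d:.1f} Å > {d_cut} Å and ratio={r:.2f} < {r_cut}")
    else:
        group, mech = "ambiguous", "ambiguous"
        notes.append("discriminants straddle or sit on the cuts")
    if g.d_rxn is not None and g.d_rxn >= D_RXN_DISSOCIATION_ROOM:
        notes.append(
            f"reaction coordinate {g.d_rxn:.1f} Å >= {D_RXN_DISSOCIATION_ROOM} Å: "
            "room for a fully dissociated metaphosphate intermediate")
    return MechanismCall(group=group, mechanism=mech, d_cut=d_cut, r_cut=r_cut,
                         rationale="; ".join(notes), confident=confident)


def batch_table(entries: list[tuple[Structure, ReactionCenterSpec, str]],
                d_cut: float = D_CUT_DEFAULT,
                r_cut: float = R_CUT_DEFAULT) -> pd.DataFrame:
    """Measure and classify a batch of reaction centers; one row per entry.

    Per-row failures are recorded in the ``error`` column and the batch
    continues.  The ``d_his_asp`` and ``r_mg`` columns are the two axes of
    the distance-vs-asymmetry scatter in which tight and loose centers
    cluster on opposite sides of (d_cut, r_cut).
    """
    rows = []
    for structure, spec, label in entries:
        row: dict = {"label": label or spec.label,
                     "pdb_id": structure.source_id,
                     "chains": f"{spec.hk_chain}:{spec.rr_chain}"}
        try:
            g = measure_center(structure, spec)
            call = classify_mechanism(g, d_cut=d_cut, r_cut=r_cut)
            row.update(
                d_his_asp=g.d_his_asp, d_rxn=g.d_rxn, d_mg_asp=g.d_mg_asp,
                d_mg_his=g.d_mg_his, r_mg=g.r_mg, od_used=g.od_used,
                surrogate=g.surrogate_kind, group=call.group,
                mechanism=call.mechanism,
                modeled_flags=";".join(f"{k}={v}" for k, v in g.modeled_flags.items()),
                error="")
        except (StructureError, ValueError) as exc:
            row.update(d_his_asp=np.nan, d_rxn=np.nan, d_mg_asp=np.nan,
                       d_mg_his=np.nan, r_mg=np.nan, od_used="", surrogate=None,
                       group="", mechanism="", modeled_flags="", error=str(exc))
        rows.append(row)
    if not rows:
        raise ValueError("batch_table needs at least one entry")
    return pd.DataFrame(rows)
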
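# tcsgeom

Geometric analysis of phosphotransfer reaction centers and protein–protein
interfaces in bacterial **two-component signaling systems** (TCS): a sensor
histidine kinase (HK) and its response regulator (RR).

## The scientific problem

When an HK:RR complex is caught crystallographically just before phosphoryl
transfer, the geometry of its reaction center encodes the chemistry it can
perform.  Two measurable discriminants separate reversible from effectively
one-way phosphotransfer:

* **d(His Nε2 – Asp Oδ1)** — the distance between the phosphorylatable
  histidine of the HK's DHp domain and the receiver aspartate of the RR's REC
  domain.  Below ~6.5 Å a pentacoordinate, *associative* transition state
  (simultaneous bond formation and rupture) is geometrically possible; above
  it, counting van der Waals radii, there is room for a fully *dissociated*
  metaphosphate intermediate.
* **r(Mg) = d(Mg²⁺–AspOδ1)/d(Mg²⁺–HisNε2)** — the asymmetry of the divalent
  cation in the active site.  A symmetric cation (ratio > 0.6) stabilizes an
  in-line associative geometry; a cation pulled toward the Asp side
  (ratio < 0.6) marks the loose arrangement in which the migrating
  metaphosphate is drawn toward the RR's positive charges.

Complexes cluster into **Group I** (associative-compatible, reversible
transfer) and **Group II** (dissociative, unidirectional His→Asp transfer)
on opposite sides of (6.5 Å, 0.6).

A second structural signature of such systems is the **"slippery" HK:RR
interface**: the partners slide against each other while each stays
internally rigid.  This is quantified by a two-regime superposition matrix:
fitting the invariant DHp region and *evaluating* the rmsd over the REC Cα
atoms without refitting (large values, up to ~2.5 Å) versus fitting the REC
domains directly (small values, ~0.3 Å).  Loose packing also shows up as a
modest buried surface (~1400 Å²) and low Lawrence–Colman shape
complementarity (Sc ≈ 0.6).

## What the package provides

| module | contents |
|---|---|
| `tcsgeom.structure` | atom/structure model, PDB + mmCIF I/O (gemmi-backed), selections, crystallographic symmetry expansion, backbone φ/ψ |
| `tcsgeom.superpose` | Kabsch least-squares superposition, rmsd over arbitrary selections, superposition-based **moiety transplants** (modeling BeF₃⁻, Mg²⁺ or phospho-His from a donor structure) |
| `tcsgeom.reaction_center` | locate reactive atoms (Nε2, Oδ, Mg²⁺, phospho-surrogates), measure distances/ratios, classify associative vs dissociative, batch tables |
| `tcsgeom.slippage` | two-regime superposition matrices and summary statistics |
| `tcsgeom.interface` | Shrake–Rupley SASA (fixed golden-spiral quadrature), buried surface area, interface footprints, Lawrence–Colman Sc |
| `tcsgeom.fixtures` | synthetic coordinate generators with analytic ground truth |
| `tcsgeom.published` | published reference measurements (reaction-center table, nine-complex slippage matrix) used as comparison data |
| `tcsgeom.cli` | `tcsgeom center / classify / slipmat / transplant / interface / symexp / simulate` |

## Worked example

A synthetic reaction center built at the loose-geometry distances
(His–Asp 7.6 Å, Mg²⁺ at 3.0 Å from Asp and 6.38 Å from His, with an in-line
phospho-His phosphorus):

```python
from tcsgeom import fixtures, reaction_center as rc

s, _ = fixtures.make_reaction_center(7.6, 3.0, 6.38, with_surrogate=True)
g = rc.measure_center(s, rc.ReactionCenterSpec("A", 188, "B", 54))
call = rc.classify_mechanism(g)
print(f"d(His Ne2 - Asp Od1) = {g.d_his_asp:.1f} A")
print(f"d(P - entering Od1)  = {g.d_rxn:.1f} A")
print(f"r(Mg-Asp / Mg-His)   = {g.r_mg:.2f}")
print(f"Group {call.group}: {call.mechanism}")
print(call.rationale)
```

prints

```
d(His Ne2 - Asp Od1) = 7.6 A
d(P - entering Od1)  = 5.7 A
r(Mg-Asp / Mg-His)   = 0.47
Group II: dissociative
d=7.6 Å > 6.5 Å and ratio=0.47 < 0.6; reaction coordinate 5.7 Å >= 4.9 Å: room for a fully dissociated metaphosphate intermediate
```

i.e. the center is too long for an associative mechanism, the cation sits
asymmetrically on the Asp side, and the 5.7 Å reaction coordinate leaves
room for a fully dissociated metaphosphate — the geometry of unidirectional
His→Asp transfer.

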
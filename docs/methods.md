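# Methods

This note documents the models, conventions and numerical choices behind
`tcsgeom`, and what the synthetic fixtures do and do not establish.

## Coordinate model and I/O

Structures are ordered atom lists with author-numbered residues (insertion
codes kept), because reactive residues in the TCS literature are cited by
author numbering (His188, Asp54, Pro85).  Parsing and writing of PDB and
mmCIF delegate to gemmi; one model is read (the first by default).
Alternate locations are resolved at read time to the highest-occupancy
conformer, ties broken alphabetically ('A' first) — deterministic and
matching common practice.  Hydrogens are retained on read but excluded from
selections, geometry and surface calculations unless explicitly requested;
the crystal structures this package targets have none.  Waters and other
hetero atoms enter a calculation only when a selection asks for them.

Crystallographic symmetry expansion parses operators in fractional notation
("-y,x-y,z+2/3"), converts positions to fractional coordinates in the
standard PDB orthogonalization frame (a along x, b in the xy-plane),
applies the operator and converts back.  Distances are preserved exactly
only for operators that are isometries of the given lattice; the package
applies whatever operator it is given and the caller is responsible for
using one that belongs to the crystal's space group (the intended use:
regenerating the symmetry-mate half of a phosphatase-state complex from its
two-fold axis).

Backbone dihedrals use the IUPAC sign convention (verified against gemmi's
torsion routine), with ψ defined by N(i), CA(i), C(i), N(i+1); a missing
atom or chain break raises rather than returning a silent value.

## Superposition and transplants

The Kabsch solver is SVD-based with the usual determinant correction, so a
reflection is never returned even for 180° rotations.  Collinear fitting
sets are rejected (covariance rank < 2).  Atom pairs are matched on
(mapped chain, author residue number, insertion code, atom name); unmatched
atoms are dropped but counted.  There is no outlier rejection or iterative
trimming: published interface rmsd figures of this kind read as plain
all-pairs fits.

When an evaluation selection is given, its rmsd is computed **with the
fitted transform, without refitting**.  This is the load-bearing choice of
the slippage analysis: refitting (the default in many toolkits) would
collapse the contrast between the two regimes.

Moiety transplants fit a donor structure onto a target over a shared region
and carry donor-only atoms across with the fitted transform, preserving the
donor's internal geometry exactly and flagging each grafted atom with the
donor's identifier.  A grafted atom closer than 1.5 Å to a target atom
produces a warning, not an error: superposition models of reaction centers
may bump slightly into the host, and no energy minimization is performed
(minimizing such models is known to shift them by only ~0.1 Å rmsd, which
is why the pre-minimization model is an adequate basis for distance
measurements at the reported 0.1 Å display precision).

## Reaction-center geometry and classification

`measure_center` reports full-precision distances; display rounding is one
decimal for Å and two for ratios.  Conventions:

* The His reference atom is Nε2; the Asp reference is Oδ1 by default, with
  a "nearest" policy available because crystallographic Oδ1/Oδ2 labeling is
  chemically arbitrary.  Reports state which atom was used.
* Phospho-surrogates: a phosphorus on the His residue itself (phospho-His,
  configurable residue codes), the beryllium of an Asp-bound BeF₃⁻, or the
  γ-phosphorus of a non-hydrolyzable ATP analogue.  The reaction-coordinate
  distance runs from the surrogate to the entering nucleophile: Oδ for
  His→Asp transfer, Nε2 when the phosphoryl sits on the Asp or on ATP.  For
  ATP-analogue centers the His–"Asp" distance is measured to the β–γ
  bridging atom (O3B, or C3B in methylene analogues), the position the
  leaving-group oxygen occupies.
* The Mg²⁺ selector accepts an explicit (chain, residue), "auto" (nearest
  divalent cation within 8 Å of the Asp carboxylate), or none.  Without a
  cation the classification falls back to distance alone and is flagged
  lower-confidence.

Classification is a pure threshold function: Group I requires
d < 6.5 Å **and** ratio > 0.6, Group II requires d > 6.5 Å **and**
ratio < 0.6, and anything else — including values exactly at a cut — is
ambiguous.  A single distance cut of 6.5 Å is used; the ~6.6 Å figure
sometimes quoted as the onset of full dissociation is a van-der-Waals
bound, reported in the rationale, not a second threshold.  When the
reaction coordinate is ≥ 4.9 Å the call also notes that the geometry leaves
room for a fully dissociated metaphosphate.  Each HK:RR pair in an
asymmetric unit is an independent row in batch tables.

## Slippage matrices

For every entry pair, the DHp-regime cell fits the kinase DHp Cα atoms
(residues 190–234 by default; the range is configurable because reported
descriptions vary by one residue at the C-terminal end) and evaluates over
REC Cα 1–129; the REC-regime cell fits the REC domains directly.  Residues
missing from any entry are removed from every entry's fit/eval sets, so all
cells are computed over identical residue sets and stay comparable; pair
counts are reported.  Matrices are stored symmetrically; the printed-layout
export places the DHp regime below the diagonal and the REC regime above.
Symmetry-mate complexes (e.g. the half-complex completed by a crystal
two-fold) are generated through the symmetry-operator machinery with the
operator supplied in configuration, since depositions do not print it.

## Surface metrics

SASA is Shrake–Rupley with a fixed golden-angle spiral of quadrature points
per atom (default 960, probe 1.4 Å), making results bit-reproducible for a
given point count; the quadrature grid is fixed in the laboratory frame, so
rigid motion of a structure perturbs totals only at the sub-percent
re-binning level.  The default radius table is Chothia-like (C 1.87, N
1.65, O 1.40, S 1.85 Å); a Bondi element table is also registered, and
per-atom radii can be passed explicitly (used by the analytic sphere
oracles).  Unknown elements raise unless a fallback radius is configured.

BSA follows SASA(A) + SASA(B) − SASA(A∪B), reported as the headline
*total* (both partners summed); the halved "interface area" is emitted
alongside for cross-tool comparison, and per-domain decompositions restrict
the A-side burial to named sub-selections.  Hetero ligands are excluded
from interface SASA unless requested, so a bound nucleotide does not
inflate a protein:protein burial; reports carry the toggle.  Expected
accuracy against closed-form two-sphere oracles is ~2% at default
quadrature.

Shape complementarity follows Lawrence & Colman: dots on each partner's
molecular surface (approximated by van-der-Waals-surface sampling with
occlusion, default 15 dots/Å²), buried-patch selection within 1.5 Å of the
partner's surface, a 1.5 Å peripheral trim band, per-dot score
(−n̂_a·n̂_b)·exp(−w·d²) with w = 0.5 Å⁻², and Sc = mean of the two patch
medians.  The dot-level core is exposed separately
(`shape_complementarity_dots`) so that analytic dot-plane fixtures can be
scored exactly: facing flat grids in registry give Sc = exp(−w·gap²), the
fixture family's closed-form ground truth.  The reentrant (toroidal) part
of the solvent-excluded surface is not sampled; for the flat-to-gently-
curved interface patches this statistic is applied to, the approximation
affects the trimmed patch interior little, but Sc values for deeply
interdigitated interfaces would be less faithful.

## Synthetic fixtures

Generators produce legal PDB files (exercising the real I/O path) with
minimal — not physical — residue geometry and deterministic placement from
a documented default seed (20161212).  They emulate: reaction centers at
exact requested distances (including an in-line ~180° donor–P–acceptor
axis), rigid-motion pairs with known transforms, slippage series with a
shared DHp-like scaffold and rigidly displaced REC-like domains
(ground-truth DHp cells |δᵢ−δⱼ|, REC cells 0), sphere systems with
closed-form SASA/BSA, and facing dot planes with closed-form Sc.  What
passing these tests shows: the measurement, superposition, burial and
complementarity machinery is numerically correct and self-consistent.  What
they do not show: agreement with deposited crystal structures, which
involves real side-chain geometry, missing residues, altlocs and
crystal-specific chain arrangements; those checks live in the acceptance
suite and require locally fetched depositions.

## Problem sizes and determinism

Default test and acceptance-script problem sizes are intentionally small —
30–150-atom clouds for superposition recovery, 219-atom slippage entries,
one- and two-sphere SASA systems, ~1200-dot Sc planes — chosen as the
smallest sizes at which every analytic oracle is meaningful.  All
randomness flows through explicit seeds; quadrature and dot grids are
deterministic functions of their point counts.

## Known limitations

* No energy minimization after transplants; modeled reaction centers are
  pure superposition models.
* Sc on atom structures uses a van-der-Waals-surface dot approximation (no
  reentrant surface patches).
* Symmetry operators are applied as given; lattice compatibility is the
  caller's responsibility.
* Sequence-based pairing, flexible superposition, electrostatics,
  hydrogen-bond enumeration and cavity volumes are out of scope.
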
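"""Published reference measurements for TCS phosphotransfer reaction centers.

Curated from deposited crystal structures of two-component phosphotransfer
complexes (phosphorelays, autophosphorylating kinases, imidazole-phosphorylating
CheY, and HK:RR complexes), these per-complex values — His(Nε2)–Asp(Oδ1)
distance, reaction-coordinate distance, and the Mg²⁺ asymmetry ratio — are the
standard comparison set for placing a new complex on the associative vs
dissociative axis.  They serve as *input data*: the classifier is run on them,
it does not read the reported group labels.

Also included is the published 9×9 two-regime superposition matrix over the
nine independently refined DesKC:DesR-REC pairs (three complexes from the
phosphatase asymmetric unit, STAB1–3, plus two per phosphotransferase
structure, E188-1..6): DHp-regime cells below the diagonal, REC-regime cells
above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tcsgeom.slippage import SlippageMatrix, matrix_from_values

__all__ = ["ReferenceCenter", "REFERENCE_CENTERS", "reference_slippage_matrix"]


@dataclass(frozen=True)
class ReferenceCenter:
    """One reported reaction-center measurement.

    ``d_rxn`` or ``r_mg`` is ``None`` where not determined in the deposition.
    ``group`` is the reported assignment, kept for comparison against the
    classifier's independent call.
    """

    label: str
    pdb_id: str
    d_his_asp: float
    d_rxn: float | None
    r_mg: float | None
    group: str
    direction: str


REFERENCE_CENTERS: tuple[ReferenceCenter, ...] = (
    # phosphorelays
    ReferenceCenter("Spo0F:Spo0B/1", "2FTK", 5.7, 4.1, 0.82, "I", "P~Asp->His"),
    ReferenceCenter("Spo0F:Spo0B/2", "2FTK", 5.3, 3.8, 0.74, "I", "P~Asp->His"),
    ReferenceCenter("Spo0F:Spo0B/3", "2FTK", 5.1, 3.6, 0.65, "I", "P~Asp->His"),
    ReferenceCenter("Spo0F:Spo0B/4", "2FTK", 5.1, 3.5, 0.67, "I", "P~Asp->His"),
    ReferenceCenter("SLN1:YPD1", "2R25", 4.9, 3.2, 0.67, "I", "P~Asp->His"),
    ReferenceCenter("AHK5:AHP1", "4EUK", 6.4, None, 0.72, "I", "P~Asp->His"),
    ReferenceCenter("ChpT:CtrA", "4QPJ", 5.9, None, 0.64, "I", "P~His->Asp"),
    # autophosphorylating HKs (ATP-analogue gamma-phosphorus)
    ReferenceCenter("CpxA:ATP", "4BIW", 5.0, 3.4, 0.82, "I", "ATP->His"),
    ReferenceCenter("HK853/EnvZ:ATP", "4KP4", 5.3, 3.6, 0.72, "I", "ATP->His"),
    # RR-mediated phosphorylation of imidazole
    ReferenceCenter("Imidazole:CheY/1", "5DKF", 5.1, 3.3, 0.71, "I", "P~Asp->Im"),
    ReferenceCenter("Imidazole:CheY/2", "5DKF", 5.1, 3.3, 0.73, "I", "P~Asp->Im"),
    # HK:RR complexes
    ReferenceCenter("HK853:RR468/1", "3DGE", 7.6, 5.7, 0.51, "II", "P~His->Asp"),
    ReferenceCenter("HK853:RR468/2", "3DGE", 8.0, 6.1, 0.48, "II", "P~His->Asp"),
    ReferenceCenter("DesK:DesR", "5IUK", 7.6, 5.8, 0.47, "II", "P~His->Asp"),
    ReferenceCenter("CheA3:CheY6", "3KYJ", 7.3, None, 0.52, "II", "P~His->Asp"),
)


_SLIP_LABELS = ["STAB1", "STAB2", "STAB3",
                "E188-1", "E188-2", "E188-3", "E188-4", "E188-5", "E188-6"]

# DHp-regime cells (row i vs column j, i > j), Å
_LOWER_DHP = [
    [0.0] * 9,
    [0.826, 0.0] + [0.0] * 7,
    [1.362, 1.917, 0.0] + [0.0] * 6,
    [1.168, 1.133, 1.682, 0.0] + [0.0] * 5,
    [0.909, 1.140, 1.224, 0.584, 0.0] + [0.0] * 4,
    [1.085, 1.110, 1.530, 0.233, 0.459, 0.0] + [0.0] * 3,
    [1.548, 1.140, 2.453, 0.893, 1.316, 1.040, 0.0] + [0.0] * 2,
    [1.295, 0.978, 2.096, 0.593, 0.969, 0.716, 0.449, 0.0, 0.0],
    [1.424, 1.058, 2.300, 0.770, 1.182, 0.905, 0.193, 0.306, 0.0],
]

# REC-regime cells (row i vs column j, i < j), Å
_UPPER_REC = [
    [0.0, 0.229, 0.158, 0.414, 0.349, 0.442, 0.361, 0.344, 0.343],
    [0.0, 0.0, 0.188, 0.496, 0.459, 0.512, 0.334, 0.343, 0.333],
    [0.0, 0.0, 0.0, 0.393, 0.343, 0.414, 0.292, 0.287, 0.277],
    [0.0, 0.0, 0.0, 0.0, 0.275, 0.146, 0.305, 0.301, 0.301],
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.301, 0.351, 0.309, 0.341],
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.346, 0.315, 0.313],
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.175, 0.117],
    [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.140],
    [0.0] * 9,
]


def reference_slippage_matrix() -> SlippageMatrix:
    """The published nine-complex DesKC:DesR-REC two-regime rmsd matrix."""
    return matrix_from_values(_SLIP_LABELS, np.array(_LOWER_DHP),
                              np.array(_UPPER_REC))
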
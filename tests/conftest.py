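import numpy as np
import pytest

from tcsgeom.structure import Atom, Structure


def minimal_protein(n_res: int = 6, chain: str = "A", start: int = 1,
                    res_name: str = "ALA") -> Structure:
    """Fully-extended poly-peptide backbone (trans, planar): every ψ and φ
    is 180°.  Idealized bond geometry on a zig-zag in the xy-plane."""
    atoms = []
    sn = 0
    # repeating N-CA-C pattern along x with alternating y: torsions are 180
    step = 1.3
    for i in range(n_res):
        for j, name in enumerate(["N", "CA", "C"]):
            sn += 1
            x = (3 * i + j) * step
            y = 0.7 if (3 * i + j) % 2 else 0.0
            atoms.append(Atom(sn, name, name[0], res_name, chain, start + i,
                              np.array([x, y, 0.0])))
    return Structure(atoms=atoms, source_id="extended")


@pytest.fixture
def extended_chain() -> Structure:
    return minimal_protein()


@pytest.fixture
def his_fixture() -> Structure:
    """One His + one Asp residue with the reactive atoms present."""
    from tcsgeom.fixtures import make_reaction_center

    s, _ = make_reaction_center(6.0, 3.0, 5.0)
    return s
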
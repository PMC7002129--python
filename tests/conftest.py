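import numpy as np
import pytest
from hypothesis import settings

from psipig.structure_io import Atom, Residue, StructureModel
from psipig.synthetic import (
    AxialSpec,
    DonorSpec,
    PlacementSpec,
    build_toy_structure,
    ideal_chlorin_template,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def template():
    return ideal_chlorin_template()


@pytest.fixture
def toy_pair():
    """Two stacked pigments; first has a 2.5-A Tyr donor and a 2.15-A axial His."""
    specs = [
        PlacementSpec(donors=(DonorSpec(distance=2.5),), axial=AxialSpec(distance=2.15)),
        PlacementSpec(translation=(0.0, 0.0, 6.0)),
    ]
    return build_toy_structure(specs)


def make_peptide(chain_id="A", start=1, residues=("SER", "GLY")):
    """A minimal peptide with backbone N/CA/C/O plus key side-chain atoms."""
    sidechains = {
        "SER": [("OG", "O")],
        "THR": [("OG1", "O")],
        "TYR": [("OH", "O")],
        "HIS": [("ND1", "N"), ("NE2", "N")],
        "GLY": [],
        "ALA": [],
    }
    out = []
    for i, name in enumerate(residues):
        num = start + i
        base = np.array([4.0 * i, 0.0, 0.0])
        atoms = []
        for j, (aname, elem) in enumerate(
            [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")] + sidechains[name]
        ):
            pos = base + np.array([0.5 * j, 0.3 * j, 0.0])
            atoms.append(
                Atom(
                    chain_id=chain_id,
                    residue_name=name,
                    residue_number=num,
                    atom_name=aname,
                    element=elem,
                    position=tuple(pos),
                )
            )
        out.append(Residue((chain_id, num, ""), name, atoms))
    return out


@pytest.fixture
def peptide_model():
    return StructureModel(make_peptide())
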
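import numpy as np
import pytest

from mdflex.structure_io import AtomRecord, StructureModel
from mdflex.synthetic_data import ToyProteinSpec, generate_toy_structure


def make_model(spec_rows, model_id=1):
    """Build a StructureModel from (resnum, resname, atomname, xyz) rows."""
    atoms = []
    for i, (rn, resname, name, xyz) in enumerate(spec_rows):
        atoms.append(AtomRecord(
            serial=i + 1, name=name, residue_name=resname, chain="A",
            residue_number=rn, coords=np.asarray(xyz, dtype=float),
            element=name[0],
        ))
    return StructureModel(atoms=atoms, model_id=model_id)


@pytest.fixture
def ten_residue_model():
    """10 residues x 4 backbone atoms on a line."""
    rows = []
    for rn in range(1, 11):
        base = np.array([rn * 4.0, 0.0, 0.0])
        for j, name in enumerate(["N", "CA", "C", "O"]):
            rows.append((rn, "ALA", name, base + [0.0, j * 1.2, 0.0]))
    return make_model(rows)


@pytest.fixture
def toy_spec():
    return ToyProteinSpec()


@pytest.fixture
def toy_structure(toy_spec):
    return generate_toy_structure(toy_spec, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
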
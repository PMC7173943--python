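import numpy as np
import pytest
from hypothesis import settings as _hypothesis_settings

_hypothesis_settings.register_profile("xlgeom", database=None)
_hypothesis_settings.load_profile("xlgeom")

from xlgeom.struct_io import AtomRecord, ResidueRecord, StructureModel
from xlgeom.synthetic_data import SimulationSpec, generate_toy_complex


@pytest.fixture(scope="session")
def toy():
    """Default toy complex with planted pose and true distance matrix."""
    return generate_toy_complex(SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def spec():
    return SimulationSpec(seed=1)


def make_residue(chain, seq, res_type, atom_positions, insertion_code=""):
    """Quick residue: atom_positions is {name: (x, y, z)}."""
    elements = {"N": "N", "O": "O", "OXT": "O", "SG": "S"}
    atoms = [
        AtomRecord(name=name, element=elements.get(name, "C"), position=np.asarray(p, float))
        for name, p in atom_positions.items()
    ]
    return ResidueRecord(
        chain_id=chain, seq_number=seq, res_type=res_type, atoms=atoms,
        insertion_code=insertion_code,
    )


def make_model(residues, roles=None, model_id="m", resolution=None):
    return StructureModel(
        model_id=model_id, residues=residues, chain_roles=dict(roles or {}),
        resolution=resolution,
    )
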
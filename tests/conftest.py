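import pytest

from detbelt import FixtureParams, load_database, make_ring_fixture
from detbelt.pdb_io import AtomRecord


@pytest.fixture(scope="session")
def db():
    return load_database()


@pytest.fixture(scope="session")
def ring_fixture():
    """Jitter-free cylindrical shell: 5 rings x 36 carbons at radius 20 Å."""
    return make_ring_fixture(FixtureParams())


def carbon_atoms(coords):
    """Bare carbon pseudo-atoms at the given (x, y, z) positions."""
    return [
        AtomRecord(
            serial=i + 1,
            atom_name="CA",
            element="C",
            residue_name="ALA",
            chain_id="A",
            residue_number=i + 1,
            x=float(x),
            y=float(y),
            z=float(z),
        )
        for i, (x, y, z) in enumerate(coords)
    ]
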
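import numpy as np
import pytest

from micellekit.core import Frame, Selection, Topology
from micellekit.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_micelle():
    """A fast tetrahedral micelle: few cage atoms, one chain per cage."""
    spec = SyntheticSpec(n_frames=8, n_cage_atoms=12, chains_per_cage=1,
                         water_density=0.05, com_jitter=0.02, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def default_micelle():
    """Full-scale defaults: 60-atom cages, five chains, tetrahedral."""
    spec = SyntheticSpec(n_frames=5, water_density=0.1, seed=11)
    return generate(spec)


def point_topology(coords, masses=None, charges=None, bonds=(),
                   elements=None, molecule_ids=None):
    """Minimal topology for bare point clouds used across tests."""
    n = len(coords)
    masses = np.ones(n) if masses is None else np.asarray(masses, float)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    elements = ["C"] * n if elements is None else list(elements)
    molecule_ids = np.zeros(n, int) if molecule_ids is None \
        else np.asarray(molecule_ids, int)
    return Topology(names=[f"A{i}" for i in range(n)], elements=elements,
                    masses=masses, charges=charges, molecule_ids=molecule_ids,
                    roles=["other"] * n, bonds=list(bonds))


def cloud_frame(coords, box=(10.0, 10.0, 10.0), time=0.0):
    return Frame(time=time, coords=np.asarray(coords, float),
                 box=np.asarray(box, float))


def full_selection(n, label="all"):
    return Selection(tuple(range(n)), label)
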
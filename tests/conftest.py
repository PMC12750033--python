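import numpy as np
import pytest

from cryofit.core import Atom, AtomicModel, DensityGrid, Residue
from cryofit.mapsim import SimulationParams, simulate_density
from cryofit.synth import make_polymer


@pytest.fixture(scope="session")
def helix20() -> AtomicModel:
    return make_polymer(20, "helix", seed=1)


@pytest.fixture(scope="session")
def helix30() -> AtomicModel:
    return make_polymer(30, "helix", seed=1)


@pytest.fixture(scope="session")
def sim_params() -> SimulationParams:
    return SimulationParams(resolution=4.0)


@pytest.fixture(scope="session")
def helix20_map(helix20, sim_params) -> DensityGrid:
    return simulate_density(helix20, sim_params)


def make_toy_residue(chain_id, seq_id, positions, res_name="ALA", kind="amino",
                     names=None, elements=None):
    """A residue from bare coordinate rows (first atom is CA by default)."""
    n = len(positions)
    names = names or (["CA", "N", "C", "O", "CB"][:n])
    elements = elements or [("N" if nm.startswith("N") else "O" if nm.startswith("O") else "C")
                            for nm in names]
    atoms = [Atom(nm, el, np.asarray(p, float))
             for nm, el, p in zip(names, elements, positions)]
    return Residue(chain_id, seq_id, "", res_name, atoms, kind)


def make_toy_model(residue_positions, model_id="toy", chain_id="A"):
    """A minimal model: one CA-only residue per coordinate row."""
    residues = [make_toy_residue(chain_id, i + 1, [p]) for i, p in enumerate(residue_positions)]
    return AtomicModel(model_id, {chain_id: residues})
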
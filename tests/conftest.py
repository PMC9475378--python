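import numpy as np
import pytest

import hydroscore as hs


@pytest.fixture(scope="session")
def single_atom():
    return hs.make_single_atom(element="O", radius=1.52)


@pytest.fixture(scope="session")
def gag_fixture():
    return hs.make_ideal_peptide("GAG", seed=11)


@pytest.fixture(scope="session")
def gavlw_fixture():
    return hs.make_ideal_peptide("GAVLW", seed=11)


@pytest.fixture(scope="session")
def all20_fixture():
    return hs.make_ideal_peptide("ACDEFGHIKLMNPQRSTVWY", seed=11)


@pytest.fixture(scope="session")
def kd_scale():
    return hs.load_scale("kyte-doolittle")


@pytest.fixture(scope="session")
def single_atom_mesh(single_atom):
    grid = hs.build_distance_grid(single_atom.structure, spacing=0.5)
    return hs.extract_ses(grid, structure=single_atom.structure)


def two_atom_toy(h_values=(1.0, -1.0), separation=20.0, radius=1.52):
    """Two well-separated identical atoms; returns (structure, h array)."""
    from hydroscore.structure import Atom, Structure

    atoms = [
        Atom(0, "O", "O", "GLY", 1, "A", np.zeros(3), radius, False),
        Atom(1, "O", "O", "GLY", 2, "A", np.array([separation, 0.0, 0.0]), radius, False),
    ]
    return Structure(atoms, label="two-atom"), np.array(h_values, dtype=float)
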
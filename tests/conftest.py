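"""Shared fixtures: small crystal cells and potentials.

All structures are generated programmatically — nothing is read from disk.
"""

import numpy as np
import pytest

from nanocarve import (
    EllipsoidSpec,
    ParticleStructure,
    generate_fixture,
    lennard_jones,
    substitute_element,
)

# LJ sigma that puts the dimer minimum at the FCC nearest-neighbour
# distance of the a=4.05 fixture: sigma = (a/sqrt(2)) / 2^(1/6)
FCC_A = 4.05
FCC_SIGMA = (FCC_A / np.sqrt(2.0)) / 2.0 ** (1.0 / 6.0)


@pytest.fixture(scope="session")
def rutile_cell():
    """Rutile-type TiO2 cell (6 sites, charges 4+/2-)."""
    _, cell = generate_fixture("rutile_MO2")
    return cell


@pytest.fixture(scope="session")
def zirconia_cell(rutile_cell):
    """Rutile-like ZrO2: the Ti→Zr substituted rutile cell."""
    return substitute_element(rutile_cell, "Ti", "Zr")


@pytest.fixture(scope="session")
def rocksalt_cell():
    _, cell = generate_fixture("rocksalt")
    return cell


@pytest.fixture(scope="session")
def fcc_cell():
    _, cell = generate_fixture("fcc")
    return cell


@pytest.fixture(scope="session")
def lj_argon():
    """Reduced-unit LJ potential for single-species toy clusters."""
    return lennard_jones(["Ar"], eps=1.0, sigma=1.0)


@pytest.fixture(scope="session")
def lj_aluminium():
    """LJ potential whose dimer minimum sits at the FCC fixture's
    nearest-neighbour distance."""
    return lennard_jones(["Al"], eps=0.4, sigma=FCC_SIGMA)


@pytest.fixture
def sphere_spec():
    return EllipsoidSpec(2.0, 2.0, 2.0)


def make_cluster(elements, positions, charges=None, minimized=False):
    s = ParticleStructure(
        np.array(elements, dtype=object), np.array(positions, dtype=float),
        None if charges is None else np.array(charges, dtype=float),
    )
    s.provenance["minimized"] = minimized
    return s


def fcc_block(ncells=3, a=FCC_A, element="Al"):
    """Perfect FCC block of ncells^3 conventional cells (no carving)."""
    basis = np.array(
        [[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]
    )
    pos = []
    for i in range(ncells):
        for j in range(ncells):
            for k in range(ncells):
                pos.extend((basis + [i, j, k]) * a)
    pos = np.array(pos)
    return make_cluster([element] * len(pos), pos, minimized=True)
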
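import itertools

import numpy as np
import pytest

from spscore import load_structure, default_rotamer_library
from spscore.fixtures import FixtureSpec, make_structure
from spscore.properties import CANONICAL_AA

ALL_ORDERED_PAIRS = [
    (w, m) for w, m in itertools.product(CANONICAL_AA, repeat=2) if w != m
]


@pytest.fixture(scope="session")
def rotamer_lib():
    return default_rotamer_library()


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("structs") / "helix20.pdb"
    make_structure(FixtureSpec(n_residues=20, geometry="helix"), path)
    return path


@pytest.fixture(scope="session")
def helix_ctx(helix_pdb):
    return load_structure(helix_pdb, fmt="pdb")


@pytest.fixture(scope="session")
def cavity_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("structs") / "cavity.pdb"
    make_structure(
        FixtureSpec(n_residues=9, geometry="cavity", target_position=5,
                    target_mut="W"),
        path,
    )
    return path


@pytest.fixture(scope="session")
def cavity_ctx(cavity_pdb):
    return load_structure(cavity_pdb, fmt="pdb")


@pytest.fixture(scope="session")
def relief_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("structs") / "relief.pdb"
    make_structure(
        FixtureSpec(n_residues=1, geometry="relief", target_mut="V"), path
    )
    return path


@pytest.fixture(scope="session")
def relief_ctx(relief_pdb):
    return load_structure(relief_pdb, fmt="pdb")


def brute_force_overlaps(coords_a, radii_a, elems_a, coords_b, radii_b, elems_b,
                         hbond_allowance):
    """Independent all-pairs overlap oracle (pure python loops)."""
    polar = {"N", "O", "S"}
    out = np.empty((len(coords_a), len(coords_b)))
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            d = float(np.linalg.norm(np.asarray(coords_a[i]) - np.asarray(coords_b[j])))
            ov = radii_a[i] + radii_b[j] - d
            if elems_a[i] in polar and elems_b[j] in polar:
                ov -= hbond_allowance
            out[i, j] = ov
    return out
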
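import numpy as np
import pytest

from thiopair import hashdb as hd
from thiopair import synthfix as sf


@pytest.fixture(scope="session")
def exemplar_grid():
    return sf.exemplar_grid()


@pytest.fixture(scope="session")
def small_db(exemplar_grid):
    """Grid database with light augmentation (kept small for speed)."""
    cfg = hd.HashDbConfig(n_perturb=10, rng_seed=7)
    return hd.build_database(exemplar_grid, cfg)


@pytest.fixture(scope="session")
def helix12():
    return sf.ideal_helix("A" * 12)


@pytest.fixture(scope="session")
def hairpin4():
    return sf.ideal_hairpin("AAAA", "AAAA")


def random_rigid(rng):
    """A random proper rotation and translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans


def move_structure(s, rot, trans):
    out = s.copy()
    for res in out.residues():
        for a in res.atoms:
            a.coord = rot @ a.coord + trans
    return out
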
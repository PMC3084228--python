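import numpy as np
import pytest

from offpipe import structio
from offpipe.energetics import build_system, load_forcefield, synthetic_parameter_block


@pytest.fixture(scope="session")
def small_complex():
    return structio.make_synthetic_complex(seed=3, n_residues=12, n_ligand_atoms=6)


@pytest.fixture(scope="session")
def small_system(small_complex):
    ff = load_forcefield(synthetic_parameter_block(small_complex))
    return build_system(small_complex, ff)


@pytest.fixture(scope="session")
def small_ff(small_complex):
    return load_forcefield(synthetic_parameter_block(small_complex))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_cluster(rng, n, min_sep=3.0, sigma=4.0):
    """Blob of points with a minimum separation (shared by SASA tests)."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        cand = rng.normal(0.0, sigma, 3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    return np.array(pts)
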
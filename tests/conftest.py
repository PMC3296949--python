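import numpy as np
import pytest

import spinlabel as sl
from spinlabel.fixtures import GXG_SITE


@pytest.fixture(scope="session")
def template():
    return sl.mtssl_template()


@pytest.fixture(scope="session")
def gxg():
    return sl.fixtures.make_gxg_peptide()


@pytest.fixture(scope="session")
def attached(template, gxg):
    return sl.attach(template, gxg, GXG_SITE)


@pytest.fixture(scope="session")
def gxg_ensemble(gxg):
    """Normal-depth search on the exposed tripeptide site (seed 1)."""
    return sl.run_search(gxg, GXG_SITE, sl.SearchParams(thoroughness="normal", seed=1))


@pytest.fixture(scope="session")
def dimer():
    return sl.fixtures.make_symmetric_dimer()


@pytest.fixture(scope="session")
def random_atoms():
    """1000 pseudo-atoms uniform in a 50 A box, for spatial-index oracles."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0.0, 50.0, size=(1000, 3))
    return [
        sl.Atom(
            name="C", element="C", position=p, residue_number=i,
            insertion_code="", chain_id="X", residue_name="PSD",
        )
        for i, p in enumerate(coords)
    ]


def brute_force_radius(atoms, point, r):
    """O(n) reference for radius queries (closed ball)."""
    point = np.asarray(point, dtype=float)
    return {
        i for i, a in enumerate(atoms)
        if np.linalg.norm(a.position - point) <= r
    }
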
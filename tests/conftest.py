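import numpy as np
import pytest

import pepgrasp as pg


@pytest.fixture(scope="session")
def matrix():
    return pg.blosum62()


@pytest.fixture(scope="session")
def alphabet():
    return pg.gbmr10()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiled_db_and_protein():
    """A 300-aa protein tiled into 15-aa fragments at step 5."""
    rng = np.random.default_rng(5)
    protein = pg.random_protein(rng, 300)
    frags = [protein[i:i + 15] for i in range(0, 286, 5)]
    return pg.PeptideDatabase(frags), protein


@pytest.fixture(scope="session")
def tiled_bundle(tiled_db_and_protein):
    db, _ = tiled_db_and_protein
    return pg.build_index(db)
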
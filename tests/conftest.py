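import numpy as np
import pytest

import landgen as lg


@pytest.fixture(scope="session")
def small_landscape():
    """Shared 20x20 elevation surface with 10 well-separated sites."""
    elev = lg.gen_elevation(lg.LandscapeSimConfig(nrows=20, ncols=20,
                                                  cellsize=1000.0, seed=11))
    sites = lg.gen_sites(elev, n_sites=10, min_separation=3, seed=12)
    return elev, sites


@pytest.fixture(scope="session")
def tri_surface(small_landscape):
    elev, sites = small_landscape
    return lg.terrain_ruggedness(elev), sites


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     alphabet: str = "ACGT") -> lg.SequenceAlignment:
    mat = rng.choice(list(alphabet), size=(n, L))
    return lg.SequenceAlignment(ids=[f"s{i}" for i in range(n)],
                                seqs=["".join(r) for r in mat])
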
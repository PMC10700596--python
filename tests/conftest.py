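import numpy as np
import pytest

from aniondock.receptor import Atom, ReceptorModel
from aniondock.synthetic import SyntheticLibrarySpec, make_compound_library, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(40, 15.0, seed=1)


@pytest.fixture(scope="session")
def small_library():
    return make_compound_library(SyntheticLibrarySpec(n_total=60, seed=11))


@pytest.fixture()
def random_receptor():
    """30 random pseudo-atoms in a 10 Å cube, mixed radii and charges."""
    rng = np.random.default_rng(42)
    atoms = [
        Atom(
            "C",
            tuple(rng.uniform(-5, 5, 3)),
            float(rng.choice([1.5, 1.9])),
            float(rng.choice([-0.4, 0.0, 0.4, 1.0])),
            name="CB",
            res_name="UNK",
            res_num=i + 1,
        )
        for i in range(30)
    ]
    return ReceptorModel(atoms)
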
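import numpy as np
import pytest

from mtbinder.structures import Structure
from mtbinder.synthetic import SyntheticSystemSpec, generate_system


def make_structure(coords, charges=None, radii=None, names=None,
                   res_names=None, res_numbers=None, chain="A",
                   segments=None) -> Structure:
    """Tiny ad-hoc Structure for fixtures."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return Structure(
        names=np.array(names if names is not None else ["CA"] * n,
                       dtype="U6"),
        elements=np.full(n, "C", dtype="U2"),
        coords=coords,
        charges=np.asarray(charges if charges is not None else np.zeros(n),
                           dtype=float),
        radii=np.asarray(radii if radii is not None else np.full(n, 2.0),
                         dtype=float),
        chain_ids=np.full(n, chain, dtype="U4"),
        res_numbers=np.asarray(
            res_numbers if res_numbers is not None else np.arange(1, n + 1),
            dtype=int),
        res_names=np.array(res_names if res_names is not None
                           else ["ALA"] * n, dtype="U4"),
        segments=np.array(segments if segments is not None
                          else ["OTHER"] * n, dtype="U8"),
    )


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSystemSpec(n_frames=25, n_runs=2, seed=7)


@pytest.fixture(scope="session")
def base_system(small_spec):
    return generate_system(small_spec)
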
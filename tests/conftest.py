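import numpy as np
import pytest

from ramdfp.synthetic import gen_compound_set, gen_toy_complex
from ramdfp.traj_contacts import read_trajectory

FULL_RECIPE = {"hb": 4, "apolar": 6, "ionic": 8, "aro_face": 9,
               "aro_edge": 10, "egress": 12}


@pytest.fixture(scope="session")
def toy_complex(tmp_path_factory):
    """Toy complex covering all five contact archetypes with scripted breaks."""
    return gen_toy_complex(FULL_RECIPE, tmp_path_factory.mktemp("toy"),
                           n_frames=16)


@pytest.fixture(scope="session")
def toy_series(toy_complex):
    return read_trajectory(toy_complex.topology_path,
                           toy_complex.trajectory_path,
                           ligand_typing=toy_complex.ligand_typing,
                           compound_id="toy", replica_id="r1",
                           trajectory_id="t1")


@pytest.fixture(scope="session")
def planted_matrix():
    """94 x 47 compound set with a planted linear law (noise SD 0.3)."""
    return gen_compound_set(seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
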
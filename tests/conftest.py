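import numpy as np
import pytest

from xipore import XiSpec, build_membrane, popc_spec, rbc_spec
from xipore.backmap import bundled_tables
from xipore.core import BeadConfiguration
from xipore.membrane import _LIPID_STACKS


@pytest.fixture(scope="session")
def rbc_membrane():
    return build_membrane(rbc_spec(), seed=1)


@pytest.fixture(scope="session")
def popc_membrane():
    return build_membrane(popc_spec(), seed=1)


@pytest.fixture(scope="session")
def cg_xispec():
    return XiSpec.cg_default()


@pytest.fixture(scope="session")
def mapping_tables():
    return bundled_tables()


@pytest.fixture
def random_polar_config():
    """Factory: n polar beads uniformly random in a box, W/PO4 names."""

    def make(n=500, seed=0, box=(10.0, 10.0, 10.0)):
        rng = np.random.default_rng(seed)
        box_arr = np.array(box)
        names = rng.choice(["W", "PO4"], size=n)
        return BeadConfiguration(
            names=names.astype(object),
            residue_names=np.array(["W"] * n, dtype=object),
            residue_ids=np.arange(1, n + 1),
            positions=rng.uniform(0, 1, size=(n, 3)) * box_arr,
            box=box_arr,
        )

    return make


@pytest.fixture
def cg_single_residue():
    """Factory: one CG residue from the builder's bead stack, optionally rotated."""

    def make(res, seed=0, center=(10.0, 10.0, 5.0), box=(20.0, 20.0, 10.0)):
        from scipy.spatial.transform import Rotation

        stack = _LIPID_STACKS[res]
        names = [b for b, _ in stack]
        pos = np.array([
            [0.05 * np.cos(i), 0.05 * np.sin(i), z] for i, (_, z) in enumerate(stack)
        ])
        rot = Rotation.random(random_state=seed).as_matrix()
        return BeadConfiguration(
            names=np.array(names, dtype=object),
            residue_names=np.array([res] * len(names), dtype=object),
            residue_ids=np.array([1] * len(names)),
            positions=pos @ rot.T + np.asarray(center),
            box=np.asarray(box, dtype=float),
        )

    return make
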
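import numpy as np
import pytest
import trimesh

from cortexvasc.geometry import build_shell
from cortexvasc.fixtures import (
    ToyNetworkSpec,
    make_toy_network,
    standard_patch_shell,
    standard_patch_tree,
)


@pytest.fixture(scope="session")
def sphere():
    return trimesh.creation.icosphere(subdivisions=3, radius=1.0)


@pytest.fixture(scope="session")
def sphere_shell(sphere):
    return build_shell(sphere, thickness=0.2, outward_fraction=0.75)


@pytest.fixture(scope="session")
def patch_shell():
    return standard_patch_shell(seed=3)


@pytest.fixture(scope="session")
def small_tree(patch_shell):
    """50-terminal volumetric-cost tree on the standard patch (seeded)."""
    return standard_patch_tree(n_terminals=50, seed=11, shell=patch_shell)


@pytest.fixture(scope="session")
def demo_case():
    """30-terminal simulatable network used by the solver-level tests."""
    return make_toy_network(
        ToyNetworkSpec(kind="cco_patch", n_terminals=30, seed=7,
                       pulsatility=0.9)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
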
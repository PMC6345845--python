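import numpy as np
import pytest

from flexsaxs.energy import EnergyModel
from flexsaxs.synthetic import SyntheticSpec, make_toy_complex
from flexsaxs.topology import Bead, ComplexTopology, LinkerChain, RigidBody


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dumbbell():
    """Small two-body dumbbell with a 10-bead linker."""
    topo, ref = make_toy_complex(
        SyntheticSpec(beads_per_body=15, linker_length=10, seed=11))
    return topo, ref


@pytest.fixture(scope="session")
def anchored_dumbbell():
    topo, ref = make_toy_complex(
        SyntheticSpec(beads_per_body=12, linker_length=8, anchored=True, seed=5))
    return topo, ref


@pytest.fixture
def energy_model():
    return EnergyModel()


@pytest.fixture
def single_bead_topology():
    """One free bead (a one-bead unanchored chain)."""
    beads = [Bead(0, "G", np.zeros(3), 0.0, "l0")]
    return ComplexTopology(beads, [], [LinkerChain("l0", np.array([0]))])


def make_two_body_toy(d_inter: float = 10.0):
    """Two one-bead rigid bodies a fixed distance apart (no linkers)."""
    beads = [
        Bead(0, "A", np.zeros(3), 0.0, "b0"),
        Bead(1, "A", np.array([d_inter, 0.0, 0.0]), 0.0, "b1"),
    ]
    bodies = [
        RigidBody("b0", np.array([0]), np.zeros((1, 3))),
        RigidBody("b1", np.array([1]), np.zeros((1, 3)),
                  pose_translation=np.array([d_inter, 0.0, 0.0])),
    ]
    return ComplexTopology(beads, bodies, [])


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    return rot, rng.uniform(-50, 50, 3)
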
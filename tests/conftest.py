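import numpy as np
import pytest
from hypothesis import settings

from synaptomap.morphology import MorphNode, NeuronTree, StructureType
from synaptomap.synthetic_data import TreeGenParams, generate_tree

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_chain_tree(n_nodes: int = 11, spacing: float = 10.0) -> NeuronTree:
    """Straight basal cable along +x: soma at origin, n_nodes-1 dendrite
    nodes every `spacing` µm."""
    nodes = [MorphNode(1, StructureType.SOMA, 0, 0, 0, 5.0, -1)]
    for k in range(1, n_nodes):
        nodes.append(
            MorphNode(k + 1, StructureType.BASAL_DENDRITE, k * spacing, 0, 0, 0.5, k)
        )
    return NeuronTree(nodes)


def make_bifurcating_tree() -> NeuronTree:
    """Soma -> 30 µm trunk along +x, splitting into two 50 µm daughters."""
    nodes = [
        MorphNode(1, StructureType.SOMA, 0, 0, 0, 5.0, -1),
        MorphNode(2, StructureType.BASAL_DENDRITE, 30, 0, 0, 0.5, 1),
        MorphNode(3, StructureType.BASAL_DENDRITE, 30, 50, 0, 0.5, 2),
        MorphNode(4, StructureType.BASAL_DENDRITE, 30, -50, 0, 0.5, 2),
    ]
    return NeuronTree(nodes)


def random_tree(seed: int, total_length: float = 600.0) -> NeuronTree:
    return generate_tree(
        TreeGenParams(
            total_length=total_length,
            branch_length_mean=40.0,
            branch_length_sd=15.0,
            basal_fraction=1.0,
            step=4.0,
            seed=seed,
        )
    )


@pytest.fixture
def chain_tree():
    return make_chain_tree()


@pytest.fixture
def bif_tree():
    return make_bifurcating_tree()


@pytest.fixture(scope="session")
def ref_tree():
    """Reference neuron at the study scale (~4.7 mm dendrite, 70% basal)."""
    return generate_tree(TreeGenParams(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
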
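import math

import numpy as np
import pytest

from aiiconn import (
    CellType,
    IPLFrame,
    K0725_SCALE,
    Plane,
    Skeleton,
    SkeletonForest,
    SkeletonNode,
    VoxelScale,
)
from aiiconn.geometry import frame_from_sac_skeletons
from aiiconn.synthetic_data import SynthParams, generate


def make_skeleton(sid, positions, edges, comments=None, name="sk", soma=None):
    """Build a skeleton from {node_id: (x, y, z)} and edge pairs."""
    sk = Skeleton(skeleton_id=sid, name=name, soma_node=soma)
    comments = comments or {}
    for nid, pos in positions.items():
        sk.add_node(SkeletonNode(node_id=nid, position=tuple(map(float, pos)),
                                 comment=comments.get(nid)))
    for a, b in edges:
        sk.add_edge(a, b)
    return sk


def random_tree_skeleton(rng, n_nodes, sid=1, span=1000.0):
    """Random tree: each node links to a random earlier node."""
    positions = {i: tuple(rng.uniform(0, span, size=3)) for i in range(1, n_nodes + 1)}
    edges = [(int(rng.integers(1, i)), i) for i in range(2, n_nodes + 1)]
    return make_skeleton(sid, positions, edges)


@pytest.fixture
def unit_scale():
    return VoxelScale(1.0, 1.0, 1.0)


@pytest.fixture
def k_scale():
    return K0725_SCALE


@pytest.fixture
def flat_frame():
    """Parallel horizontal planes: OFF at z=0, ON at z=1000 nm; GCL at +z."""
    return IPLFrame(
        plane_off=Plane((0.0, 0.0, 1.0), 0.0),
        plane_on=Plane((0.0, 0.0, 1.0), 1000.0),
        orientation_ref=(0.0, 0.0, 5000.0),
    )


@pytest.fixture(scope="session")
def default_volume():
    """One generated volume shared across tests (quota mode, seed 7)."""
    params = SynthParams(seed=7)
    forest, truth = generate(params)
    return params, forest, truth


@pytest.fixture(scope="session")
def default_frame(default_volume):
    _, forest, truth = default_volume
    return frame_from_sac_skeletons(
        forest,
        truth.sac_ids["SAC_OFF"],
        truth.sac_ids["SAC_ON"],
        orientation_ref=truth.orientation_ref,
    )


@pytest.fixture(scope="session")
def default_types(default_volume):
    _, _, truth = default_volume
    return truth_types(truth)


def truth_types(truth):
    out = {}
    for sid, label in truth.types.items():
        try:
            out[int(sid)] = CellType(label)
        except ValueError:
            out[int(sid)] = CellType.UNIDENTIFIED
    return out
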
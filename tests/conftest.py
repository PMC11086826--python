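import numpy as np
import pandas as pd
import pytest

from backbones import BipartiteGraph, generate_preschool


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def toy_graph():
    # two agents, three artifacts, one shared artifact
    return BipartiteGraph(np.array([[1, 1, 0], [1, 0, 1]]))


@pytest.fixture
def random_graph(rng):
    B = (rng.random((10, 20)) < 0.4).astype(int)
    return BipartiteGraph(B)


@pytest.fixture
def toy_tables():
    """Four children (two per classroom, all FULL) and three groups; small
    enough that every constraint rule can be enumerated by hand."""
    children = pd.DataFrame(
        {
            "child_id": ["a", "b", "c", "d"],
            "classroom": ["3yo", "3yo", "4yo", "4yo"],
            "schedule": ["FULL", "FULL", "FULL", "FULL"],
        }
    )
    groups = pd.DataFrame(
        {
            "group_id": ["g1", "g2", "g3"],
            "classroom": ["3yo", "4yo", "3yo"],
            "session": ["AM", "PM", "PM"],
            "focal_child_id": ["a", "c", "b"],
        }
    )
    B = np.array(
        [
            [1, 0, 0],
            [1, 0, 1],
            [0, 1, 0],
            [0, 1, 0],
        ]
    )
    graph = BipartiteGraph(B, children["child_id"].tolist(), groups["group_id"].tolist())
    return children, groups, graph


@pytest.fixture(scope="session")
def small_world():
    return generate_preschool(
        n_children=16,
        n_groups=200,
        classroom_split=(8, 8),
        truth_density=0.25,
        assortativity=8.0,
        seed=11,
    )
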
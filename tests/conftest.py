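import pandas as pd
import pytest

from carpath.fixtures import make_coa_case, make_hub_shortcut, make_random_graph
from carpath.graph_model import build_graph
from carpath.pair_weighting import ReactantProductPair


def weighted_pairs(edges):
    """[(reaction_id, a, b, car), ...] -> list of ReactantProductPair."""
    return [
        ReactantProductPair(reaction_id=r, substrate_id=a, product_id=b, car=c)
        for r, a, b, c in edges
    ]


def graph_from_edges(edges, **kwargs):
    kwargs.setdefault("exclusions", ())
    return build_graph(weighted_pairs(edges), **kwargs)


@pytest.fixture
def hub_fixture():
    return make_hub_shortcut()


@pytest.fixture
def coa_fixture():
    return make_coa_case()


@pytest.fixture
def diamond_graph():
    """4-node diamond: A-B-D conserves everything, A-C-D only half."""
    return graph_from_edges([
        ("R1", "A", "B", 1.0),
        ("R2", "B", "D", 1.0),
        ("R3", "A", "C", 0.5),
        ("R4", "C", "D", 0.5),
    ])


@pytest.fixture
def two_triangles_graph():
    return graph_from_edges([
        ("R1", "A", "B", 0.9), ("R2", "B", "C", 0.9), ("R3", "C", "A", 0.9),
        ("R4", "X", "Y", 0.9), ("R5", "Y", "Z", 0.9), ("R6", "Z", "X", 0.9),
    ])


@pytest.fixture
def random_graph_factory():
    return make_random_graph


@pytest.fixture
def compound_table():
    return pd.DataFrame({
        "compound_id": ["C00001", "C00002", "C00003", "C00004"],
        "inchikey": [
            "ABCDEFGHIJKLMN-UHFFFAOYSA-N",   # same connectivity block...
            "ABCDEFGHIJKLMN-ZZZZZAOYSA-N",   # ...different stereo block
            "OPQRSTUVWXYZAB-UHFFFAOYSA-N",
            None,
        ],
        "name": ["d-form", "l-form", "other", "keyless"],
    })
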
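import pytest

from fragspace.benchmark import SyntheticSpaceSpec, generate_space
from fragspace.data import bundled_molecules
from fragspace.space import parse_space_dict


def make_space(graphs, name="test"):
    return parse_space_dict(
        {"format": "fragspace-json", "version": 1, "name": name, "graphs": graphs}
    )


def chain2(fragments_a, fragments_b, graph_id="g1"):
    """Two-node chain graph joined via linker R1."""
    return {
        "id": graph_id,
        "nodes": [
            {"id": "n1", "fragments": fragments_a},
            {"id": "n2", "fragments": fragments_b},
        ],
        "edges": [
            {"a": "n1", "b": "n2", "linker_a": "R1", "linker_b": "R1",
             "kind": "single_bond", "order": "single"}
        ],
    }


@pytest.fixture(scope="session")
def sources():
    return bundled_molecules()


@pytest.fixture
def minimal_space():
    """Smallest valid space: one product, CC-O."""
    return make_space([chain2(["CC[*:1]"], ["[*:1]O"])])


@pytest.fixture(scope="session")
def synthetic_space(sources):
    spec = SyntheticSpaceSpec(tuple(sources[:20]), (1, 2), seed=11)
    return generate_space(spec)


@pytest.fixture(scope="session")
def ring_space():
    """Fig-1-style space: chain node + an aromatic ring formed from two halves."""
    return make_space(
        [
            {
                "id": "g1",
                "nodes": [
                    {"id": "A", "fragments": ["CC[*:1]"]},
                    {"id": "B", "fragments": ["c1([*:1])cc[*:2]*[*:3]1"]},
                    {"id": "C", "fragments": ["c1cc[*:5]*[*:4]1"]},
                ],
                "edges": [
                    {"a": "A", "b": "B", "linker_a": "R1", "linker_b": "R1",
                     "kind": "single_bond", "order": "single"},
                    {"a": "B", "b": "C", "linker_a": "R2", "linker_b": "R4",
                     "kind": "ring_formation", "order": "aromatic"},
                    {"a": "B", "b": "C", "linker_a": "R3", "linker_b": "R5",
                     "kind": "ring_formation", "order": "aromatic"},
                ],
            }
        ]
    )
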
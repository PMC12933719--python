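"""Topological fragment spaces: data model, JSON I/O, assembly, enumeration.

A fragment space encodes a combinatorial compound library without
enumerating it.  It consists of topology graphs; each graph's nodes hold
interchangeable fragments and its edges say how fragments of adjacent
nodes are bonded together (via named linker placeholders).  The number of
products of a graph is the product of its node pool sizes.

The on-disk format is a small versioned JSON dialect::

    {
      "format": "fragspace-json",
      "version": 1,
      "name": "...",
      "graphs": [
        {"id": "g1",
         "nodes": [{"id": "n1", "fragments": ["CC[*:1]", ...]}, ...],
         "edges": [{"a": "n1", "b": "n2",
                    "linker_a": "R1", "linker_b": "R1",
                    "kind": "single_bond", "order": "single"}, ...]}
      ]
    }

Fragment SMILES use mapped dummy atoms for linkers (``[*:1]`` = ``R1``)
and unmapped dummy atoms for ring placeholders.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from .molgraph import ATOM, LINKER, RING, Bond, MoleculeGraph, MolParseError

__all__ = [
    "Fragment",
    "TopologyNode",
    "TopologyEdge",
    "TopologyGraph",
    "FragmentSpace",
    "Provenance",
    "SpaceFormatError",
    "SpaceValidationError",
    "AssemblyError",
    "parse_space",
    "parse_space_dict",
    "write_space",
    "space_to_dict",
    "space_size",
    "assemble_product",
    "enumerate_products",
    "iter_products",
]

FORMAT_NAME = "fragspace-json"
FORMAT_VERSION = 1

CONNECTION_KINDS = ("single_bond", "ring_formation")


class SpaceFormatError(ValueError):
    """Malformed space file (bad JSON structure or unparsable SMILES)."""


class SpaceValidationError(ValueError):
    """Structurally valid file that violates a fragment-space invariant."""


class AssemblyError(ValueError):
    """Product assembly failed (e.g. unresolved placeholder)."""


@dataclass
class Fragment:
    id: str
    graph: MoleculeGraph
    smiles: str  # as authored; round-trips through write_space

    @property
    def heavy_atom_count(self) -> int:
        """Real atoms only; placeholders are excluded from the count."""
        return self.graph.heavy_atom_count

    def linker_names(self) -> set[str]:
        return set(self.graph.linker_names())

    def validate(self) -> None:
        # note: a fragment of a single-node topology graph legitimately has
        # zero linkers; the required linker set is enforced per node against
        # the incident edges in TopologyGraph.validate.
        self.graph.validate()
        names = self.graph.linker_names()
        if len(names) != len(set(names)):
            raise SpaceValidationError(
                f"fragment {self.id!r} has duplicate linker names {sorted(names)}"
            )


@dataclass
class TopologyNode:
    id: str
    fragments: list[Fragment]

    def validate(self) -> None:
        if not self.fragments:
            raise SpaceValidationError(f"topology node {self.id!r} has no fragments")
        for frag in self.fragments:
            frag.validate()


@dataclass(frozen=True)
class TopologyEdge:
    node_a: str
    node_b: str
    linker_a: str
    linker_b: str
    kind: str = "single_bond"
    order: str = "single"

    def validate(self) -> None:
        if self.node_a == self.node_b:
            raise SpaceValidationError(
                f"topology edge connects node {self.node_a!r} to itself"
            )
        if self.kind not in CONNECTION_KINDS:
            raise SpaceValidationError(f"unknown connection kind {self.kind!r}")


@dataclass
class TopologyGraph:
    id: str
    nodes: list[TopologyNode]
    edges: list[TopologyEdge]

    def node(self, node_id: str) -> TopologyNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def incident_linkers(self, node_id: str) -> list[str]:
        """Linker names the node's fragments must provide, one per edge end."""
        names = []
        for e in self.edges:
            if e.node_a == node_id:
                names.append(e.linker_a)
            if e.node_b == node_id:
                names.append(e.linker_b)
        return names

    @property
    def product_count(self) -> int:
        size = 1
        for n in self.nodes:
            size *= len(n.fragments)
        return size

    def has_ring_formation(self) -> bool:
        return any(e.kind == "ring_formation" for e in self.edges)

    def validate(self) -> None:
        node_ids = [n.id for n in self.nodes]
        if len(node_ids) != len(set(node_ids)):
            raise SpaceValidationError(f"graph {self.id!r} has duplicate node ids")
        for n in self.nodes:
            n.validate()
        known = set(node_ids)
        for e in self.edges:
            e.validate()
            for nid in (e.node_a, e.node_b):
                if nid not in known:
                    raise SpaceValidationError(
                        f"graph {self.id!r} edge references unknown node {nid!r}"
                    )
        # connectivity of the node/edge graph
        if self.nodes:
            adj: dict[str, set[str]] = {nid: set() for nid in node_ids}
            for e in self.edges:
                adj[e.node_a].add(e.node_b)
                adj[e.node_b].add(e.node_a)
            seen = {node_ids[0]}
            stack = [node_ids[0]]
            while stack:
                v = stack.pop()
                for u in adj[v]:
                    if u not in seen:
                        seen.add(u)
                        stack.append(u)
            if len(seen) != len(node_ids):
                raise SpaceValidationError(f"graph {self.id!r} topology is not connected")
        # every fragment carries exactly the linker set demanded by its edges
        for n in self.nodes:
            demanded = self.incident_linkers(n.id)
            if len(demanded) != len(set(demanded)):
                raise SpaceValidationError(
                    f"graph {self.id!r} node {n.id!r}: incident edges demand "
                    f"duplicate linker names {sorted(demanded)}"
                )
            for frag in n.fragments:
                if frag.linker_names() != set(demanded):
                    raise SpaceValidationError(
                        f"fragment {frag.id!r} carries linkers "
                        f"{sorted(frag.linker_names())} but node {n.id!r} "
                        f"demands {sorted(demanded)}"
                    )


@dataclass
class FragmentSpace:
    name: str
    topology_graphs: list[TopologyGraph]
    metadata: dict = field(default_factory=dict)

    def graph(self, graph_id: str) -> TopologyGraph:
        for g in self.topology_graphs:
            if g.id == graph_id:
                return g
        raise KeyError(graph_id)

    def validate(self) -> None:
        if not self.topology_graphs:
            raise SpaceValidationError("fragment space has no topology graphs")
        ids = [g.id for g in self.topology_graphs]
        if len(ids) != len(set(ids)):
            raise SpaceValidationError("duplicate topology graph ids")
        for g in self.topology_graphs:
            g.validate()


@dataclass(frozen=True)
class Provenance:
    """Where a product came from: graph id + fragment id per node."""

    graph_id: str
    selection: tuple[tuple[str, str], ...]  # sorted (node id, fragment id) pairs


# ---------------------------------------------------------------------------
# JSON I/O
# ---------------------------------------------------------------------------


def _require(d: Mapping, key: str, context: str):
    if key not in d:
        raise SpaceFormatError(f"missing key {key!r} in {context}")
    return d[key]


def parse_space_dict(data: Mapping) -> FragmentSpace:
    if not isinstance(data, Mapping):
        raise SpaceFormatError("top-level value must be a JSON object")
    if data.get("format", FORMAT_NAME) != FORMAT_NAME:
        raise SpaceFormatError(f"unknown format {data.get('format')!r}")
    version = data.get("version", FORMAT_VERSION)
    if version != FORMAT_VERSION:
        raise SpaceFormatError(f"unsupported version {version!r}")
    name = _require(data, "name", "space")
    graphs_raw = _require(data, "graphs", "space")
    graphs: list[TopologyGraph] = []
    for graw in graphs_raw:
        gid = _require(graw, "id", "graph")
        nodes: list[TopologyNode] = []
        for nraw in _require(graw, "nodes", f"graph {gid!r}"):
            nid = _require(nraw, "id", f"node of graph {gid!r}")
            fragments: list[Fragment] = []
            for i, smi in enumerate(_require(nraw, "fragments", f"node {nid!r}")):
                fid = f"{gid}:{nid}:{i}"
                try:
                    graph = MoleculeGraph.from_smiles(smi)
                except MolParseError as exc:
                    raise SpaceFormatError(
                        f"fragment {fid!r}: {exc}"
                    ) from exc
                fragments.append(Fragment(fid, graph, smi))
            nodes.append(TopologyNode(nid, fragments))
        edges = [
            TopologyEdge(
                _require(eraw, "a", f"edge of graph {gid!r}"),
                _require(eraw, "b", f"edge of graph {gid!r}"),
                _require(eraw, "linker_a", f"edge of graph {gid!r}"),
                _require(eraw, "linker_b", f"edge of graph {gid!r}"),
                eraw.get("kind", "single_bond"),
                eraw.get("order", "single"),
            )
            for eraw in _require(graw, "edges", f"graph {gid!r}")
        ]
        graphs.append(TopologyGraph(gid, nodes, edges))
    space = FragmentSpace(name, graphs, dict(data.get("metadata", {})))
    space.validate()
    return space


def parse_space(path: str | Path) -> FragmentSpace:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SpaceFormatError(f"{path}: invalid JSON: {exc}") from exc
    return parse_space_dict(data)


def space_to_dict(space: FragmentSpace) -> dict:
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "name": space.name,
        "metadata": space.metadata,
        "graphs": [
            {
                "id": g.id,
                "nodes": [
                    {"id": n.id, "fragments": [f.smiles for f in n.fragments]}
                    for n in g.nodes
                ],
                "edges": [
                    {
                        "a": e.node_a,
                        "b": e.node_b,
                        "linker_a": e.linker_a,
                        "linker_b": e.linker_b,
                        "kind": e.kind,
                        "order": e.order,
                    }
                    for e in g.edges
                ],
            }
            for g in space.topology_graphs
        ],
    }


def write_space(space: FragmentSpace, path: str | Path) -> None:
    Path(path).write_text(json.dumps(space_to_dict(space), indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Size and assembly
# ---------------------------------------------------------------------------


def space_size(space: FragmentSpace) -> int:
    """Total product count: sum over graphs of the product of node pool sizes."""
    return sum(g.product_count for g in space.topology_graphs)


def assemble_product(
    graph: TopologyGraph, selection: Mapping[str, Fragment]
) -> MoleculeGraph:
    """Assemble one product molecule from a per-node fragment selection.

    For every topology edge, the named linker placeholder on each side is
    replaced by the real atom adjacent to the partner side's linker, and the
    connecting bond receives the edge's bond order.  Unnamed ring
    placeholders of fragments participating in ring-forming connections are
    removed once the partner atoms complete the ring.
    """
    missing = [n.id for n in graph.nodes if n.id not in selection]
    if missing:
        raise AssemblyError(f"selection is missing nodes {missing}")

    product = MoleculeGraph()
    offsets: dict[str, int] = {}
    for node in graph.nodes:
        frag = selection[node.id]
        offsets[node.id] = len(product.atoms)
        product.atoms.extend(frag.graph.atoms)
        product.bonds.extend(
            Bond(b.a + offsets[node.id], b.b + offsets[node.id], b.order)
            for b in frag.graph.bonds
        )

    def _linker_index(node_id: str, linker: str) -> int:
        frag = selection[node_id]
        for i, atom in enumerate(frag.graph.atoms):
            if atom.kind == LINKER and atom.linker_name == linker:
                return offsets[node_id] + i
        raise AssemblyError(
            f"fragment {frag.id!r} has no linker {linker!r}"
        )

    adj = product.adjacency()

    def _anchor(placeholder_idx: int) -> int:
        """The unique real atom adjacent to a linker placeholder."""
        real = [u for u, _ in adj[placeholder_idx] if not product.atoms[u].is_placeholder]
        if len(real) != 1:
            raise AssemblyError(
                f"linker placeholder at atom {placeholder_idx} must have exactly "
                f"one real neighbor, found {len(real)}"
            )
        return real[0]

    to_delete: set[int] = set()
    ring_nodes: set[str] = set()
    for edge in graph.edges:
        ia = _linker_index(edge.node_a, edge.linker_a)
        ib = _linker_index(edge.node_b, edge.linker_b)
        product.bonds.append(Bond(_anchor(ia), _anchor(ib), edge.order))
        to_delete.update((ia, ib))
        if edge.kind == "ring_formation":
            ring_nodes.update((edge.node_a, edge.node_b))

    # ring placeholders stood in for partner atoms that are now present
    for node in graph.nodes:
        if node.id in ring_nodes:
            frag = selection[node.id]
            for i, atom in enumerate(frag.graph.atoms):
                if atom.kind == RING:
                    to_delete.add(offsets[node.id] + i)

    result = product.without_atoms(to_delete)
    leftovers = result.placeholder_indices()
    if leftovers:
        names = [
            result.atoms[i].linker_name or "<ring placeholder>" for i in leftovers
        ]
        raise AssemblyError(f"unresolved placeholder(s) after assembly: {names}")
    if not result.is_connected():
        raise AssemblyError("assembled product is not connected")
    return result


def iter_products(space: FragmentSpace) -> Iterator[tuple[MoleculeGraph, Provenance]]:
    """Yield every product with its provenance (no size guard)."""
    for graph in space.topology_graphs:
        node_ids = [n.id for n in graph.nodes]
        pools = [n.fragments for n in graph.nodes]
        for combo in itertools.product(*pools):
            selection = dict(zip(node_ids, combo))
            prov = Provenance(
                graph.id,
                tuple(sorted((nid, frag.id) for nid, frag in selection.items())),
            )
            yield assemble_product(graph, selection), prov


def enumerate_products(
    space: FragmentSpace, limit: int
) -> list[tuple[MoleculeGraph, Provenance]]:
    """Brute-force enumeration of every product, refused above ``limit``."""
    size = space_size(space)
    if size > limit:
        raise ValueError(
            f"space holds {size} products, above the enumeration limit {limit}"
        )
    return list(iter_products(space))
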
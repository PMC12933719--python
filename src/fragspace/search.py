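"""Similarity search over fragment spaces without product enumeration.

The pipeline has four stages plus a final global re-ranking:

1. *Partitioning*: the query is cut at acyclic single bonds into connected
   partition classes, keeping only partitions whose class adjacency matches
   the topology of at least one topology graph.
2. *Matching*: partition classes are assigned to topology nodes by exhaustive
   bijection search, requiring identical topology including bond types and a
   per-class size criterion (within ``size_slack`` heavy atoms of at least
   one fragment of the node).
3. *Comparison*: for every matching, the fragments of each node are ranked
   by (weighted) Tanimoto similarity against the wildcard-capped partition
   class.  The marked feature set is built per class, from features fully
   marked *and* present in the class fingerprint.
4. *Combination*: the best fragment combinations across all matchings are
   produced by lazy best-first enumeration over the ranked lists, scored by
   the share-weighted sum of partial similarities.  Marked query atoms count
   as ``weight / correction`` atoms in the shares.

Finally, the candidate pool is assembled into full products and re-ranked by
global (weighted) fingerprint similarity against the whole query.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from rdkit import Chem

from .fingerprints import (
    FeatureWeighting,
    Fingerprint,
    compute_fingerprint,
    weighted_tanimoto,
)
from .molgraph import RING, Atom, Bond, MoleculeGraph
from .space import AssemblyError, Fragment, FragmentSpace, TopologyGraph, TopologyNode, assemble_product

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "QueryPartition",
    "PartitionClass",
    "Matching",
    "Combination",
    "SearchHit",
    "SearchResult",
    "MarkingError",
    "SpaceSearcher",
    "enumerate_partitions",
    "match_partition",
    "score_node_fragments",
    "adjusted_atom_count",
    "adjusted_shares",
    "combine_top",
    "search",
    "mark_atoms_by_smarts",
]


class MarkingError(ValueError):
    """Raised when a marking pattern selects no query atoms."""


@dataclass(frozen=True)
class SearchConfig:
    """Search parameters; the defaults reproduce the reference configuration."""

    n_results: int = 100
    descriptor: str = "csfp1.4"
    weight: float = 1.0  # weighting factor k applied to marked features
    correction: float = 3.0  # correction factor c for the adjusted atom counts
    min_feature_size: int = 1
    weight_by_size: bool = False
    size_slack: int = 5  # max heavy-atom difference class vs node fragment
    pool_multiplier: int = 10  # candidate pool size = multiplier * n_results

    def __post_init__(self):
        if self.n_results < 1:
            raise ValueError("n_results must be positive")
        if self.weight < 1:
            raise ValueError("weighting factor must be >= 1")
        if self.correction <= 0:
            raise ValueError("correction factor must be > 0")
        if self.pool_multiplier < 1:
            raise ValueError("pool_multiplier must be >= 1")

    @property
    def pool_size(self) -> int:
        return self.n_results * self.pool_multiplier


@dataclass(frozen=True)
class PartitionClass:
    """A connected query substructure matched against one topology node."""

    atoms: frozenset[int]  # query atom indices
    capped: MoleculeGraph  # induced subgraph + one wildcard per cut bond
    to_capped: tuple[tuple[int, int], ...]  # query idx -> capped idx pairs
    cut_bonds: tuple[Bond, ...]  # incident cut bonds, in query indices

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atoms)

    def capped_index(self, query_idx: int) -> int:
        return dict(self.to_capped)[query_idx]


@dataclass(frozen=True)
class QueryPartition:
    query: MoleculeGraph
    cut_bonds: tuple[Bond, ...]
    classes: tuple[PartitionClass, ...]


@dataclass(frozen=True)
class Matching:
    """A bijection between partition classes and the nodes of one graph.

    ``node_order[i]`` is the node id assigned to ``partition.classes[i]``.
    """

    partition: QueryPartition
    graph: TopologyGraph
    node_order: tuple[str, ...]


@dataclass(frozen=True)
class Combination:
    """One fragment selection for a matching, with its combination score."""

    graph_id: str
    node_order: tuple[str, ...]
    fragments: tuple[Fragment, ...]
    score: float
    partials: tuple[float, ...]
    matching_index: int

    @property
    def frag_ids(self) -> tuple[str, ...]:
        return tuple(f.id for f in self.fragments)

    @property
    def selection(self) -> dict[str, Fragment]:
        return dict(zip(self.node_order, self.fragments))

    def sort_key(self):
        return (-self.score, self.graph_id, self.frag_ids, self.matching_index)


@dataclass(frozen=True)
class SearchHit:
    smiles: str
    score: float
    graph_id: str
    selection: tuple[tuple[str, str], ...]  # sorted (node id, fragment id)
    combination_score: float


@dataclass
class SearchResult:
    query_smiles: str
    config: SearchConfig
    hits: list[SearchHit]
    marked_atoms: frozenset[int] = frozenset()
    details: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.hits)

    def smiles(self) -> list[str]:
        return [h.smiles for h in self.hits]

    def to_json_dict(self) -> dict:
        return {
            "query": self.query_smiles,
            "marked_atoms": sorted(self.marked_atoms),
            "config": {
                "n_results": self.config.n_results,
                "descriptor": self.config.descriptor,
                "weight": self.config.weight,
                "correction": self.config.correction,
                "min_feature_size": self.config.min_feature_size,
                "weight_by_size": self.config.weight_by_size,
                "size_slack": self.config.size_slack,
                "pool_multiplier": self.config.pool_multiplier,
            },
            "hits": [
                {
                    "smiles": h.smiles,
                    "score": h.score,
                    "graph": h.graph_id,
                    "fragments": [fid for _, fid in h.selection],
                    "combination_score": h.combination_score,
                }
                for h in self.hits
            ],
        }

    def to_tsv(self) -> str:
        lines = ["smiles\tscore\tgraph\tfragments"]
        for h in self.hits:
            frags = ",".join(fid for _, fid in h.selection)
            lines.append(f"{h.smiles}\t{h.score:.6f}\t{h.graph_id}\t{frags}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# step 1: partitioning
# ---------------------------------------------------------------------------


def _build_partition(query: MoleculeGraph, cut_bonds: Sequence[Bond]) -> QueryPartition:
    cut_set = {frozenset((b.a, b.b)) for b in cut_bonds}
    adj = [[] for _ in query.atoms]
    for b in query.bonds:
        if frozenset((b.a, b.b)) not in cut_set:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
    unseen = set(range(len(query.atoms)))
    components: list[list[int]] = []
    while unseen:
        start = min(unseen)
        comp = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u not in comp:
                    comp.add(u)
                    stack.append(u)
        unseen -= comp
        components.append(sorted(comp))

    classes = []
    for comp in components:
        sub, remap = query.induced_subgraph(comp)
        incident = tuple(
            b for b in cut_bonds if b.a in remap or b.b in remap
        )
        # cap each cut bond with a wildcard atom
        for b in incident:
            inside = b.a if b.a in remap else b.b
            sub.atoms.append(Atom("*", kind=RING))
            sub.bonds.append(Bond(remap[inside], len(sub.atoms) - 1, b.order))
        classes.append(
            PartitionClass(
                frozenset(comp), sub, tuple(sorted(remap.items())), incident
            )
        )
    return QueryPartition(query, tuple(cut_bonds), tuple(classes))


def _class_adjacency(partition: QueryPartition) -> Counter:
    """Multiset of (class index pair, bond order) induced by the cut bonds."""
    owner = {}
    for i, cls in enumerate(partition.classes):
        for a in cls.atoms:
            owner[a] = i
    counter: Counter = Counter()
    for b in partition.cut_bonds:
        i, j = sorted((owner[b.a], owner[b.b]))
        counter[(i, j, b.order)] += 1
    return counter


def _topology_bijections(
    partition: QueryPartition, graph: TopologyGraph
) -> Iterator[tuple[str, ...]]:
    """All class->node bijections with identical topology incl. bond types."""
    if graph.has_ring_formation():
        return
    if len(partition.classes) != len(graph.nodes):
        return
    class_adj = _class_adjacency(partition)
    node_ids = [n.id for n in graph.nodes]
    for perm in itertools.permutations(range(len(node_ids))):
        # class i is assigned node node_ids[perm[i]]
        mapped: Counter = Counter()
        pos = {node_ids[perm[i]]: i for i in range(len(node_ids))}
        ok = True
        for e in graph.edges:
            i, j = sorted((pos[e.node_a], pos[e.node_b]))
            mapped[(i, j, e.order)] += 1
        if mapped == class_adj:
            yield tuple(node_ids[perm[i]] for i in range(len(node_ids)))


def enumerate_partitions(
    query: MoleculeGraph, space: FragmentSpace
) -> list[QueryPartition]:
    """All partitions whose class adjacency matches >= 1 topology graph.

    Only acyclic single bonds are cut; graphs with ring-forming edges are
    not considered by the matcher.
    """
    if query.placeholder_indices():
        raise ValueError("query must be placeholder-free")
    if not query.is_connected():
        raise ValueError("query must be connected")
    cuttable = [b for b in query.bridges() if b.order == "single"]
    class_counts = sorted(
        {
            len(g.nodes)
            for g in space.topology_graphs
            if not g.has_ring_formation()
        }
    )
    out = []
    for m in class_counts:
        if m - 1 > len(cuttable) or m > len(query.atoms):
            continue
        for cut_combo in itertools.combinations(cuttable, m - 1):
            partition = _build_partition(query, cut_combo)
            if len(partition.classes) != m:
                continue
            if any(
                next(_topology_bijections(partition, g), None) is not None
                for g in space.topology_graphs
            ):
                out.append(partition)
    return out


# ---------------------------------------------------------------------------
# step 2: matching
# ---------------------------------------------------------------------------


def match_partition(
    partition: QueryPartition, graph: TopologyGraph, slack: int = 5
) -> list[Matching]:
    """All class/node bijections passing topology and size compatibility."""
    matchings = []
    for node_order in _topology_bijections(partition, graph):
        ok = True
        for cls, node_id in zip(partition.classes, node_order):
            node = graph.node(node_id)
            if not any(
                abs(cls.heavy_atom_count - frag.heavy_atom_count) <= slack
                for frag in node.fragments
            ):
                ok = False
                break
        if ok:
            matchings.append(Matching(partition, graph, node_order))
    return matchings


# ---------------------------------------------------------------------------
# step 3: comparison
# ---------------------------------------------------------------------------


def _class_weighting(
    class_fp: Fingerprint,
    cls: PartitionClass,
    marked_atoms: frozenset[int],
    cfg: SearchConfig,
) -> FeatureWeighting | None:
    """Weighting for one partition class: M holds features fully inside the
    marked part of *this* class and present in the class fingerprint."""
    if cfg.weight == 1.0 and not cfg.weight_by_size:
        return None
    marked_in_class = cls.atoms & marked_atoms
    if not marked_in_class:
        return None
    to_capped = dict(cls.to_capped)
    capped_marked = frozenset(to_capped[a] for a in marked_in_class)
    return FeatureWeighting.from_marking(
        class_fp,
        capped_marked,
        cfg.weight,
        cfg.min_feature_size,
        cfg.weight_by_size,
    )


def score_node_fragments(
    cls: PartitionClass,
    node: TopologyNode,
    cfg: SearchConfig,
    marked_atoms: frozenset[int] = frozenset(),
    class_fp: Fingerprint | None = None,
    fragment_fps: dict[str, Fingerprint] | None = None,
) -> list[tuple[Fragment, float]]:
    """Rank a node's fragments by weighted partial similarity to the class."""
    if class_fp is None:
        class_fp = compute_fingerprint(cls.capped, cfg.descriptor)
    wgt = _class_weighting(class_fp, cls, marked_atoms, cfg)
    scored = []
    for frag in node.fragments:
        if fragment_fps is not None and frag.id in fragment_fps:
            frag_fp = fragment_fps[frag.id]
        else:
            frag_fp = compute_fingerprint(frag.graph, cfg.descriptor)
            if fragment_fps is not None:
                fragment_fps[frag.id] = frag_fp
        scored.append((frag, weighted_tanimoto(class_fp, frag_fp, wgt)))
    scored.sort(key=lambda t: (-t[1], t[0].id))
    return scored


# ---------------------------------------------------------------------------
# step 4: combination
# ---------------------------------------------------------------------------


def adjusted_atom_count(is_marked: bool, cfg: SearchConfig) -> float:
    """Atom-count contribution of one query atom to the combination shares.

    Unmarked atoms count as 1; marked atoms as the weighting factor divided
    by the correction factor, floored at 1 so that small factors (notably
    k = 1, the unweighted reduction) never shrink a marked atom below an
    unmarked one.
    """
    return max(1.0, cfg.weight / cfg.correction) if is_marked else 1.0


def adjusted_shares(
    partition: QueryPartition, marked_atoms: frozenset[int], cfg: SearchConfig
) -> tuple[float, ...]:
    """Per-class shares of the adjusted query atom count; they sum to 1."""
    per_class = [
        sum(adjusted_atom_count(a in marked_atoms, cfg) for a in cls.atoms)
        for cls in partition.classes
    ]
    total = sum(per_class)
    return tuple(c / total for c in per_class)


@dataclass
class ScoredMatching:
    matching: Matching
    shares: tuple[float, ...]
    ranked: list[list[tuple[Fragment, float]]]  # one ranked list per class
    index: int = 0  # position in the matching list, for tie-breaking


def _matching_combinations(sm: ScoredMatching) -> Iterator[Combination]:
    """Best-first (lazy) enumeration of one matching's fragment combinations."""
    m = len(sm.ranked)
    shares = sm.shares

    def score_of(ix: tuple[int, ...]) -> float:
        return sum(shares[i] * sm.ranked[i][ix[i]][1] for i in range(m))

    def to_combo(ix: tuple[int, ...]) -> Combination:
        frags = tuple(sm.ranked[i][ix[i]][0] for i in range(m))
        partials = tuple(sm.ranked[i][ix[i]][1] for i in range(m))
        return Combination(
            sm.matching.graph.id,
            sm.matching.node_order,
            frags,
            score_of(ix),
            partials,
            sm.index,
        )

    def key_of(ix: tuple[int, ...]) -> tuple:
        # ties within a matching break by fragment id tuple; equal-score
        # successors always have larger id tuples (ranked lists break ties
        # by id), so best-first popping by this key is globally exact
        return (-score_of(ix), tuple(sm.ranked[i][ix[i]][0].id for i in range(m)))

    start = (0,) * m
    heap = [(key_of(start), start)]
    seen = {start}
    while heap:
        _, ix = heapq.heappop(heap)
        yield to_combo(ix)
        for i in range(m):
            if ix[i] + 1 < len(sm.ranked[i]):
                nxt = ix[:i] + (ix[i] + 1,) + ix[i + 1 :]
                if nxt not in seen:
                    seen.add(nxt)
                    heapq.heappush(heap, (key_of(nxt), nxt))


def combine_top(
    scored_matchings: Sequence[ScoredMatching], cfg: SearchConfig
) -> list[Combination]:
    """True top-P combinations across all matchings, by lazy k-best merge.

    P is ``cfg.pool_size``; ties are broken by (score desc, graph id,
    fragment ids, matching index).
    """
    pool_size = cfg.pool_size
    gens = [_matching_combinations(sm) for sm in scored_matchings]
    heap = []
    for gi, gen in enumerate(gens):
        combo = next(gen, None)
        if combo is not None:
            heap.append((combo.sort_key(), gi, combo))
    heapq.heapify(heap)
    pool: list[Combination] = []
    while heap and len(pool) < pool_size:
        _, gi, combo = heapq.heappop(heap)
        pool.append(combo)
        nxt = next(gens[gi], None)
        if nxt is not None:
            heapq.heappush(heap, (nxt.sort_key(), gi, nxt))
    return pool


# ---------------------------------------------------------------------------
# final step: global re-ranking
# ---------------------------------------------------------------------------


def mark_atoms_by_smarts(query_smiles: str, smarts: str) -> frozenset[int]:
    """Atom indices of the query covered by any match of the SMARTS pattern."""
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise MarkingError(f"invalid SMARTS pattern: {smarts!r}")
    mol = Chem.MolFromSmiles(query_smiles)
    if mol is None:
        raise MarkingError(f"invalid query SMILES: {query_smiles!r}")
    matches = mol.GetSubstructMatches(patt)
    atoms = frozenset(itertools.chain.from_iterable(matches))
    if not atoms:
        raise MarkingError(f"SMARTS {smarts!r} matches no atom of the query")
    return atoms


class SpaceSearcher:
    """Caching search driver for one fragment space.

    Reuses fragment, class, and product fingerprints across searches, which
    makes repeated searches over the same space (e.g. the same query with
    different weighting factors) much cheaper.
    """

    def __init__(self, space: FragmentSpace):
        self.space = space
        self._fragment_fps: dict[tuple[str, str], Fingerprint] = {}
        self._class_fps: dict[tuple, Fingerprint] = {}
        self._product_fps: dict[tuple[str, str], Fingerprint] = {}
        self._partition_cache: dict[str, list[QueryPartition]] = {}

    # -- caches -----------------------------------------------------------

    def fragment_fp(self, frag: Fragment, descriptor: str) -> Fingerprint:
        key = (frag.id, descriptor)
        fp = self._fragment_fps.get(key)
        if fp is None:
            fp = compute_fingerprint(frag.graph, descriptor)
            self._fragment_fps[key] = fp
        return fp

    def _class_fp(
        self, query_smiles: str, cls: PartitionClass, descriptor: str
    ) -> Fingerprint:
        key = (query_smiles, cls.atoms, cls.cut_bonds, descriptor)
        fp = self._class_fps.get(key)
        if fp is None:
            fp = compute_fingerprint(cls.capped, descriptor)
            self._class_fps[key] = fp
        return fp

    def _product_fp(self, product: MoleculeGraph, smiles: str, descriptor: str):
        key = (smiles, descriptor)
        fp = self._product_fps.get(key)
        if fp is None:
            fp = compute_fingerprint(product, descriptor)
            self._product_fps[key] = fp
        return fp

    # -- pipeline ---------------------------------------------------------

    def partitions(self, query_smiles: str, query: MoleculeGraph):
        parts = self._partition_cache.get(query_smiles)
        if parts is None:
            parts = enumerate_partitions(query, self.space)
            self._partition_cache[query_smiles] = parts
        return parts

    def global_rerank(
        self,
        pool: Sequence[Combination],
        query: MoleculeGraph,
        query_smiles: str,
        marked_atoms: frozenset[int],
        cfg: SearchConfig,
    ) -> list[SearchHit]:
        query_fp = compute_fingerprint(query, cfg.descriptor)
        wgt = None
        if marked_atoms and (cfg.weight > 1.0 or cfg.weight_by_size):
            wgt = FeatureWeighting.from_marking(
                query_fp,
                marked_atoms,
                cfg.weight,
                cfg.min_feature_size,
                cfg.weight_by_size,
            )
        hits: dict[tuple, SearchHit] = {}
        for combo in pool:
            prov_key = (combo.graph_id, tuple(sorted((n, f.id) for n, f in combo.selection.items())))
            if prov_key in hits:
                continue
            graph = self.space.graph(combo.graph_id)
            try:
                product = assemble_product(graph, combo.selection)
            except AssemblyError as exc:
                logger.warning("dropping combination %s: %s", combo.frag_ids, exc)
                continue
            smiles = product.to_smiles()
            fp = self._product_fp(product, smiles, cfg.descriptor)
            score = weighted_tanimoto(query_fp, fp, wgt)
            hits[prov_key] = SearchHit(
                smiles, score, combo.graph_id, prov_key[1], combo.score
            )
        ordered = sorted(
            hits.values(), key=lambda h: (-h.score, h.graph_id, h.selection)
        )
        return ordered[: cfg.n_results]

    def search(
        self,
        query_smiles: str,
        smarts: str | None = None,
        marked_atoms: frozenset[int] | None = None,
        cfg: SearchConfig = SearchConfig(),
        return_details: bool = False,
    ) -> SearchResult:
        query = MoleculeGraph.from_smiles(query_smiles)
        if smarts is not None:
            marked = mark_atoms_by_smarts(query_smiles, smarts)
        elif marked_atoms is not None:
            marked = frozenset(marked_atoms)
            for i in marked:
                if not 0 <= i < len(query.atoms):
                    raise MarkingError(f"marked atom index {i} out of range")
        else:
            marked = frozenset()

        partitions = self.partitions(query_smiles, query)
        scored_matchings: list[ScoredMatching] = []
        idx = 0
        for partition in partitions:
            for graph in self.space.topology_graphs:
                for matching in match_partition(partition, graph, cfg.size_slack):
                    shares = adjusted_shares(partition, marked, cfg)
                    ranked = []
                    for cls, node_id in zip(partition.classes, matching.node_order):
                        node = graph.node(node_id)
                        class_fp = self._class_fp(query_smiles, cls, cfg.descriptor)
                        frag_fps = {
                            f.id: self.fragment_fp(f, cfg.descriptor)
                            for f in node.fragments
                        }
                        ranked.append(
                            score_node_fragments(
                                cls, node, cfg, marked, class_fp, frag_fps
                            )
                        )
                    scored_matchings.append(
                        ScoredMatching(matching, shares, ranked, idx)
                    )
                    idx += 1

        logger.info(
            "query %s: %d partitions, %d matchings",
            query_smiles,
            len(partitions),
            len(scored_matchings),
        )
        if not scored_matchings:
            logger.warning("no compatible topology for query %s", query_smiles)
            return SearchResult(query_smiles, cfg, [], marked)

        pool = combine_top(scored_matchings, cfg)
        hits = self.global_rerank(pool, query, query_smiles, marked, cfg)
        result = SearchResult(query_smiles, cfg, hits, marked)
        if return_details:
            result.details = {
                "partitions": partitions,
                "scored_matchings": scored_matchings,
                "pool": pool,
            }
        logger.info(
            "query %s: pool %d, %d hits", query_smiles, len(pool), len(hits)
        )
        return result


def search(
    space: FragmentSpace,
    query_smiles: str,
    smarts: str | None = None,
    marked_atoms: frozenset[int] | None = None,
    cfg: SearchConfig = SearchConfig(),
    return_details: bool = False,
) -> SearchResult:
    """One-shot search; see :class:`SpaceSearcher` for repeated searches."""
    return SpaceSearcher(space).search(
        query_smiles, smarts, marked_atoms, cfg, return_details
    )
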
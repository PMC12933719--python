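import random

import pytest
from rdkit import Chem

from conftest import chain2, make_space
from fragspace.benchmark import SyntheticSpaceSpec, generate_space
from fragspace.molgraph import Bond, MoleculeGraph
from fragspace.search import (
    Matching,
    MarkingError,
    ScoredMatching,
    SearchConfig,
    SpaceSearcher,
    _build_partition,
    adjusted_atom_count,
    adjusted_shares,
    combine_top,
    enumerate_partitions,
    mark_atoms_by_smarts,
    match_partition,
    score_node_fragments,
    search,
)
from oracles import brute_force_pool


def cfg(**kw):
    return SearchConfig(**kw)


class TestPartitioning:
    def test_linear_query_two_node_chain(self):
        space = make_space([chain2(["C[*:1]", "CC[*:1]"], ["[*:1]O"])])
        query = MoleculeGraph.from_smiles("CCO")
        parts = enumerate_partitions(query, space)
        assert len(parts) == 2  # one per cuttable bond
        for p in parts:
            assert len(p.classes) == 2
            covered = set().union(*(c.atoms for c in p.classes))
            assert covered == {0, 1, 2}

    def test_single_node_graph_trivial_partition(self):
        space = make_space([
            {"id": "g", "nodes": [{"id": "n1", "fragments": ["CCO", "CCN"]}],
             "edges": []}
        ])
        parts = enumerate_partitions(MoleculeGraph.from_smiles("CCOC"), space)
        assert len(parts) == 1
        assert parts[0].cut_bonds == ()
        assert len(parts[0].classes) == 1

    def test_benzene_has_no_cut(self):
        space = make_space([chain2(["C[*:1]"], ["[*:1]O"])])
        parts = enumerate_partitions(MoleculeGraph.from_smiles("c1ccccc1"), space)
        assert parts == []

    def test_query_with_placeholder_rejected(self):
        space = make_space([chain2(["C[*:1]"], ["[*:1]O"])])
        with pytest.raises(ValueError, match="placeholder"):
            enumerate_partitions(MoleculeGraph.from_smiles("CC[*:1]"), space)

    def test_capped_subgraph_wildcards(self):
        query = MoleculeGraph.from_smiles("CCO")
        p = _build_partition(query, [query.bonds[0]])
        for cls in p.classes:
            wildcards = cls.capped.placeholder_indices()
            assert len(wildcards) == len(cls.cut_bonds) == 1

    def test_partitions_unique(self, synthetic_space):
        query = MoleculeGraph.from_smiles("CC(=O)Oc1ccccc1C(=O)O")
        parts = enumerate_partitions(query, synthetic_space)
        keys = [frozenset((b.a, b.b) for b in p.cut_bonds) for p in parts]
        assert len(keys) == len(set(keys))


class TestMatching:
    def test_size_criterion_forces_unique_matching(self):
        # classes of 3 and 7 atoms; node pools of 1 and 12 heavy atoms:
        # only one bijection passes the slack-5 size filter
        space = make_space([chain2(["C[*:1]", "CC[*:1]"], ["[*:1]" + "C" * 12])])
        query = MoleculeGraph.from_smiles("C" * 10)
        cut = next(b for b in query.bonds if {b.a, b.b} == {2, 3})
        p = _build_partition(query, [cut])
        (g,) = space.topology_graphs
        matchings = match_partition(p, g, slack=5)
        assert len(matchings) == 1
        (m,) = matchings
        by_size = {len(c.atoms): n for c, n in zip(p.classes, m.node_order)}
        assert by_size == {3: "n1", 7: "n2"}

    def test_oversize_class_refused(self):
        space = make_space([chain2(["C[*:1]"], ["[*:1]CCCCC"])])  # max 5 atoms
        query = MoleculeGraph.from_smiles("C" * 13)
        cut = query.bonds[0]  # classes of 1 and 12
        p = _build_partition(query, [cut])
        (g,) = space.topology_graphs
        assert match_partition(p, g, slack=5) == []

    def test_symmetric_graph_doubles_matchings(self):
        space = make_space([chain2(["CC[*:1]"], ["[*:1]CC"])])
        query = MoleculeGraph.from_smiles("CCCC")
        cut = next(b for b in query.bonds if {b.a, b.b} == {1, 2})
        p = _build_partition(query, [cut])
        (g,) = space.topology_graphs
        assert len(match_partition(p, g, slack=5)) == 2

    def test_bond_type_must_match(self):
        space = make_space([
            {"id": "g", "nodes": [
                {"id": "n1", "fragments": ["CC=[*:1]"]},
                {"id": "n2", "fragments": ["[*:1]=C"]},
            ], "edges": [
                {"a": "n1", "b": "n2", "linker_a": "R1", "linker_b": "R1",
                 "kind": "single_bond", "order": "double"}]}
        ])
        # only single bonds are cut, so a double-bond edge can never match
        parts = enumerate_partitions(MoleculeGraph.from_smiles("CCC"), space)
        assert parts == []

    def test_ring_formation_graphs_skipped(self, ring_space):
        parts = enumerate_partitions(
            MoleculeGraph.from_smiles("CCc1ccccc1"), ring_space
        )
        assert parts == []


class TestComparison:
    def build_class(self, smiles, cut_pair):
        query = MoleculeGraph.from_smiles(smiles)
        cut = next(b for b in query.bonds if {b.a, b.b} == set(cut_pair))
        p = _build_partition(query, [cut])
        return query, p

    def test_unweighted_ranking(self):
        space = make_space([chain2(
            ["CC[*:1]", "OC(CC)(CC)[*:1]"], ["C[*:1]"])])
        query, p = self.build_class("OCCC", (2, 3))
        cls = next(c for c in p.classes if len(c.atoms) == 3)
        node = space.topology_graphs[0].nodes[0]
        ranked = score_node_fragments(cls, node, cfg(descriptor="csfp2.2"))
        scores = {f.smiles: s for f, s in ranked}
        assert scores["CC[*:1]"] == pytest.approx(2 / 3)
        assert scores["OC(CC)(CC)[*:1]"] == pytest.approx(0.5)
        assert ranked[0][0].smiles == "CC[*:1]"

    def test_weighting_swaps_ranking(self):
        # fragment 1 wins unweighted; fragment 2 holds the marked feature and
        # wins at k=10 (hand-computed weighted Tanimoto values)
        space = make_space([chain2(
            ["CC[*:1]", "OC(CC)(CC)[*:1]"], ["C[*:1]"])])
        query, p = self.build_class("OCCC", (2, 3))
        cls = next(c for c in p.classes if len(c.atoms) == 3)
        node = space.topology_graphs[0].nodes[0]
        marked = frozenset({0, 1})  # the O-C pair of the query
        ranked = score_node_fragments(
            cls, node, cfg(descriptor="csfp2.2", weight=10.0), marked
        )
        scores = {f.smiles: s for f, s in ranked}
        assert scores["OC(CC)(CC)[*:1]"] == pytest.approx(12 / 15)
        assert scores["CC[*:1]"] == pytest.approx(2 / 12)
        assert ranked[0][0].smiles == "OC(CC)(CC)[*:1]"

    def test_class_without_marked_atoms_unchanged(self):
        space = make_space([chain2(
            ["CC[*:1]", "OC(CC)(CC)[*:1]"], ["C[*:1]"])])
        query, p = self.build_class("OCCC", (2, 3))
        cls = next(c for c in p.classes if len(c.atoms) == 1)
        node = space.topology_graphs[0].nodes[1]
        plain = score_node_fragments(cls, node, cfg(descriptor="csfp2.2"))
        # marked atoms all lie outside this class: no denominator penalty
        weighted = score_node_fragments(
            cls, node, cfg(descriptor="csfp2.2", weight=10.0), frozenset({0, 1})
        )
        assert [(f.id, s) for f, s in plain] == [(f.id, s) for f, s in weighted]

    def test_k1_equals_unweighted(self):
        space = make_space([chain2(
            ["CC[*:1]", "OC(CC)(CC)[*:1]"], ["C[*:1]"])])
        query, p = self.build_class("OCCC", (2, 3))
        cls = next(c for c in p.classes if len(c.atoms) == 3)
        node = space.topology_graphs[0].nodes[0]
        a = score_node_fragments(cls, node, cfg(descriptor="csfp2.2"))
        b = score_node_fragments(
            cls, node, cfg(descriptor="csfp2.2", weight=1.0), frozenset({0, 1})
        )
        assert [(f.id, s) for f, s in a] == [(f.id, s) for f, s in b]


class TestAdjustedCounts:
    def test_fig3_worked_value(self):
        assert adjusted_atom_count(True, cfg(weight=6.0, correction=3.0)) == 2.0

    def test_unmarked_is_one(self):
        assert adjusted_atom_count(False, cfg(weight=1.0)) == 1.0
        assert adjusted_atom_count(False, cfg(weight=15.0, correction=3.0)) == 1.0

    def test_k15_c3(self):
        assert adjusted_atom_count(True, cfg(weight=15.0, correction=3.0)) == 5.0

    def test_shares_sum_to_one(self):
        query = MoleculeGraph.from_smiles("C" * 10)
        p = _build_partition(query, [query.bonds[4]])
        for marked in [frozenset(), frozenset({0, 1, 2}), frozenset(range(10))]:
            shares = adjusted_shares(p, marked, cfg(weight=6.0))
            assert sum(shares) == pytest.approx(1.0)

    def test_adjusted_score_flips_partition_preference(self):
        # 10-atom chain query, 4 marked atoms at the tail.
        # partition A isolates the marked class (6|4), partition B buries it
        # (2|8).  With hand-picked partials, B wins the original combination
        # score while A wins the adjusted one (k=6, c=3).
        query = MoleculeGraph.from_smiles("C" * 10)
        marked = frozenset({6, 7, 8, 9})
        cut_a = next(b for b in query.bonds if {b.a, b.b} == {5, 6})
        cut_b = next(b for b in query.bonds if {b.a, b.b} == {1, 2})
        pa = _build_partition(query, [cut_a])
        pb = _build_partition(query, [cut_b])
        partials_a = {6: 0.0, 4: 1.0}  # keyed by class size
        partials_b = {2: 0.8, 8: 0.409}

        def combo_score(p, partials, c):
            shares = adjusted_shares(p, marked, c)
            return sum(
                s * partials[len(cl.atoms)] for s, cl in zip(shares, p.classes)
            )

        plain = cfg(weight=1.0)
        adjusted = cfg(weight=6.0, correction=3.0)
        assert combo_score(pa, partials_a, plain) == pytest.approx(0.4)
        assert combo_score(pb, partials_b, plain) == pytest.approx(0.4872)
        assert combo_score(pa, partials_a, adjusted) == pytest.approx(8 / 14)
        assert combo_score(pb, partials_b, adjusted) == pytest.approx(
            (2 * 0.8 + 12 * 0.409) / 14
        )
        assert combo_score(pb, partials_b, plain) > combo_score(pa, partials_a, plain)
        assert combo_score(pa, partials_a, adjusted) > combo_score(pb, partials_b, adjusted)


def make_scored_matching(space, query_smiles, cut_pair, scores_by_node, shares=None):
    """ScoredMatching with stubbed partial scores for combination tests."""
    query = MoleculeGraph.from_smiles(query_smiles)
    cut = next(b for b in query.bonds if {b.a, b.b} == set(cut_pair))
    p = _build_partition(query, [cut])
    (g,) = space.topology_graphs
    m = match_partition(p, g, slack=99)[0]
    ranked = []
    for cls, node_id in zip(p.classes, m.node_order):
        node = g.node(node_id)
        node_scores = scores_by_node[node_id]
        ranked.append(
            sorted(
                [(f, node_scores[i]) for i, f in enumerate(node.fragments)],
                key=lambda t: (-t[1], t[0].id),
            )
        )
    if shares is None:
        shares = adjusted_shares(p, frozenset(), cfg())
    return ScoredMatching(m, shares, ranked, 0)


class TestCombination:
    def space_2x2(self):
        return make_space([chain2(["CC[*:1]", "CN[*:1]"], ["[*:1]CC", "[*:1]CO"])])

    def test_top_pool_hand_example(self):
        sm = make_scored_matching(
            self.space_2x2(), "CCCC", (1, 2),
            {"n1": [0.9, 0.8], "n2": [0.7, 0.1]}, shares=(0.5, 0.5),
        )
        pool = combine_top([sm], cfg(n_results=2, pool_multiplier=1))
        assert [round(c.score, 10) for c in pool] == [0.80, 0.75]

    def test_single_node_degenerate(self):
        space = make_space([
            {"id": "g", "nodes": [{"id": "n1",
                                   "fragments": ["CCO", "CCN", "CCC"]}],
             "edges": []}
        ])
        query = MoleculeGraph.from_smiles("CCO")
        p = _build_partition(query, [])
        (g,) = space.topology_graphs
        m = match_partition(p, g, slack=5)[0]
        node = g.nodes[0]
        ranked = [score_node_fragments(p.classes[0], node, cfg())]
        sm = ScoredMatching(m, (1.0,), ranked, 0)
        pool = combine_top([sm], cfg(n_results=2, pool_multiplier=1))
        assert len(pool) == 2
        assert pool[0].score >= pool[1].score

    def test_pool_matches_brute_force_random(self):
        rng = random.Random(5)
        space = self.space_2x2()
        for _ in range(20):
            sms = [
                make_scored_matching(
                    space, "CCCC", (1, 2),
                    {"n1": [rng.random(), rng.random()],
                     "n2": [rng.random(), rng.random()]},
                )
                for _ in range(3)
            ]
            for i, sm in enumerate(sms):
                sm.index = i
            c = cfg(n_results=3, pool_multiplier=2)
            lazy = combine_top(sms, c)
            brute = brute_force_pool(sms, c)
            assert [x.sort_key() for x in lazy] == [x.sort_key() for x in brute]


class TestGlobalRerankAndSearch:
    def test_identity_query_rank_one(self, synthetic_space, sources):
        res = search(synthetic_space, sources[0], cfg=cfg(n_results=5))
        assert res.hits[0].smiles == Chem.CanonSmiles(sources[0])
        assert res.hits[0].score == pytest.approx(1.0)

    def test_identity_unbeatable_with_weighting(self, synthetic_space, sources):
        q = sources[0]
        marked = frozenset(range(3))
        res = search(
            synthetic_space, q, marked_atoms=marked, cfg=cfg(n_results=5, weight=20.0)
        )
        assert res.hits[0].smiles == Chem.CanonSmiles(q)
        assert res.hits[0].score == pytest.approx(1.0)

    def test_pool_of_one(self):
        space = make_space([chain2(["CC[*:1]"], ["[*:1]O"])])
        res = search(space, "CCO", cfg=cfg(n_results=4))
        assert len(res.hits) == 1

    def test_rerank_weighting_prefers_marked_preserving_product(self):
        # hand-computed: unweighted favors NCC (2/3 vs 3/5); with the C-O
        # feature marked at k=10 the C-O-preserving product flips to the top
        space = make_space([chain2(["NC[*:1]"], ["[*:1]C(O)(C)C", "[*:1]C"])])
        c = cfg(n_results=2, descriptor="csfp2.2")
        plain = search(space, "NCCO", cfg=c)
        assert plain.hits[0].smiles == Chem.CanonSmiles("NCC")
        assert plain.hits[0].score == pytest.approx(2 / 3)
        assert plain.hits[1].score == pytest.approx(3 / 5)
        weighted = search(
            space, "NCCO", marked_atoms=frozenset({2, 3}),
            cfg=cfg(n_results=2, descriptor="csfp2.2", weight=10.0),
        )
        assert weighted.hits[0].smiles == Chem.CanonSmiles("NCC(O)(C)C")
        assert weighted.hits[0].score == pytest.approx(12 / 14)
        assert weighted.hits[1].score == pytest.approx(2 / 12)

    def test_smarts_marking(self, synthetic_space, sources):
        q = "CC(=O)Oc1ccccc1C(=O)O"
        marked = mark_atoms_by_smarts(q, "C(=O)O")
        assert len(marked) >= 3
        res = search(synthetic_space, q, smarts="C(=O)O", cfg=cfg(n_results=3, weight=5.0))
        assert res.marked_atoms == marked

    def test_smarts_no_match_is_error(self, synthetic_space):
        with pytest.raises(MarkingError):
            search(synthetic_space, "CCO", smarts="[F]", cfg=cfg(n_results=2))

    def test_no_compatible_topology_empty_result(self):
        space = make_space([chain2(["C[*:1]"], ["[*:1]O"])])
        res = search(space, "c1ccccc1", cfg=cfg(n_results=5))
        assert res.hits == []

    def test_determinism_byte_identical(self, synthetic_space, sources):
        c = cfg(n_results=10, weight=8.0)
        r1 = search(synthetic_space, sources[2], smarts="[OX2]", cfg=c)
        r2 = search(synthetic_space, sources[2], smarts="[OX2]", cfg=c)
        assert r1.to_tsv() == r2.to_tsv()

    def test_reduction_intermediates(self, sources):
        spec = SyntheticSpaceSpec(tuple(sources[:10]), (1, 2), seed=3)
        space = generate_space(spec)
        searcher = SpaceSearcher(space)
        q = sources[1]
        un = searcher.search(q, cfg=cfg(n_results=8), return_details=True)
        wk1 = searcher.search(
            q, marked_atoms=frozenset({0, 1, 2}), cfg=cfg(n_results=8, weight=1.0),
            return_details=True,
        )
        for a, b in zip(un.details["scored_matchings"], wk1.details["scored_matchings"]):
            assert a.shares == b.shares
            for ra, rb in zip(a.ranked, b.ranked):
                assert [(f.id, s) for f, s in ra] == [(f.id, s) for f, s in rb]
        assert [c.sort_key() for c in un.details["pool"]] == [
            c.sort_key() for c in wk1.details["pool"]
        ]
        assert un.hits == wk1.hits


class TestEndToEndOracle:
    def test_pool_and_final_vs_brute_force(self, sources):
        spec = SyntheticSpaceSpec(tuple(sources[:8]), (1, 2), seed=21)
        space = generate_space(spec)
        searcher = SpaceSearcher(space)
        for qi, k in [(0, 1.0), (3, 10.0)]:
            q = sources[qi]
            marked = frozenset({0, 1}) if k > 1 else None
            c = cfg(n_results=5, weight=k)
            res = searcher.search(q, marked_atoms=marked, cfg=c, return_details=True)
            brute = brute_force_pool(res.details["scored_matchings"], c)
            assert [x.sort_key() for x in res.details["pool"]] == [
                x.sort_key() for x in brute
            ]
            query = MoleculeGraph.from_smiles(q)
            brute_hits = searcher.global_rerank(
                brute, query, q, marked or frozenset(), c
            )
            assert res.hits == brute_hits
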
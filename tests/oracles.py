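"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: subgraph
enumeration by subset filtering, combination ranking by full enumeration,
and weighted similarity by feature replication.
"""

from __future__ import annotations

import itertools
import random

from fragspace.fingerprints import FeatureWeighting, Fingerprint, tanimoto
from fragspace.search import Combination, ScoredMatching, SearchConfig


def all_connected_subsets(n_atoms, bonds, min_atoms, max_atoms):
    """Every connected atom subset with size in range, by subset filtering."""
    adj = {i: set() for i in range(n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)

    def connected(subset):
        subset = set(subset)
        start = next(iter(subset))
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in adj[v] & subset:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return seen == subset

    out = []
    for size in range(min_atoms, max_atoms + 1):
        for subset in itertools.combinations(range(n_atoms), size):
            if connected(subset):
                out.append(frozenset(subset))
    return out


def brute_force_pool(
    scored_matchings: list[ScoredMatching], cfg: SearchConfig
) -> list[Combination]:
    """All fragment combinations of all matchings, fully enumerated and sorted."""
    combos: list[Combination] = []
    for sm in scored_matchings:
        index_ranges = [range(len(r)) for r in sm.ranked]
        for ix in itertools.product(*index_ranges):
            frags = tuple(sm.ranked[i][ix[i]][0] for i in range(len(ix)))
            partials = tuple(sm.ranked[i][ix[i]][1] for i in range(len(ix)))
            score = sum(sm.shares[i] * partials[i] for i in range(len(ix)))
            combos.append(
                Combination(
                    sm.matching.graph.id,
                    sm.matching.node_order,
                    frags,
                    score,
                    partials,
                    sm.index,
                )
            )
    combos.sort(key=lambda c: c.sort_key())
    return combos[: cfg.pool_size]


def replicated_tanimoto(a: Fingerprint, b: Fingerprint, wgt: FeatureWeighting) -> float:
    """Plain Tanimoto after setting marked feature counts to count * weight.

    Valid as an oracle for integer weights only.
    """

    def replicate(fp: Fingerprint) -> Fingerprint:
        feats = {
            fid: count * int(wgt.weight(fid)) for fid, count in fp.features.items()
        }
        return Fingerprint(fp.descriptor, feats, dict(fp.sizes))

    return tanimoto(replicate(a), replicate(b))


def random_fingerprint(
    rng: random.Random,
    sizes: dict[str, int],
    descriptor: str = "csfp1.4",
    max_count: int = 5,
    density: float = 0.5,
) -> Fingerprint:
    feats = {
        fid: rng.randint(1, max_count)
        for fid in sizes
        if rng.random() < density
    }
    return Fingerprint(descriptor, feats, dict(sizes))


def random_feature_sizes(rng: random.Random, n_features: int = 12) -> dict[str, int]:
    return {f"f{i:02d}": rng.randint(1, 4) for i in range(n_features)}
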
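"""Synthetic spaces, query/pattern sampling, and preservation benchmarking.

The generator fragments drug-like source molecules at randomly chosen
acyclic single bonds into 2-3 pieces and pools the pieces into chain
topology graphs by piece position.  Every source molecule is therefore
reconstructible as a product of the generated space, which gives the
benchmark exact ground truth and guarantees that some queries have exact
or near-exact products.

The benchmark runs one unweighted search plus one weighted search per
weighting factor for every query/SMARTS case, measures the preservation
score (share of result molecules matching the SMARTS), and applies two
discard rules after searching: cases where no search finds a single match,
and cases where the unweighted search already preserves the substructure in
every result.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .fingerprints import compute_fingerprint, tanimoto
from .molgraph import Atom, Bond, MoleculeGraph, LINKER, RING
from .search import SearchConfig, SearchResult, SpaceSearcher
from .space import FragmentSpace, parse_space_dict

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpaceSpec",
    "QueryCase",
    "BenchmarkReport",
    "generate_space",
    "sample_query_cases",
    "preservation_score",
    "scaffold_count",
    "pairwise_similarity_distribution",
    "run_benchmark",
]


# ---------------------------------------------------------------------------
# synthetic space generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpaceSpec:
    source_smiles: tuple[str, ...]
    cuts: tuple[int, ...] = (1, 2)  # pieces per molecule = cuts + 1
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self):
        if not self.source_smiles:
            raise ValueError("need at least one source molecule")
        if any(c not in (1, 2) for c in self.cuts):
            raise ValueError("cuts per molecule must be 1 or 2")


def _split_pieces(
    mol: MoleculeGraph, cut_bonds: list[Bond]
) -> list[tuple[set[int], list[Bond]]]:
    """Connected components after cutting, with their incident cut bonds."""
    cut_set = {frozenset((b.a, b.b)) for b in cut_bonds}
    adj: list[list[int]] = [[] for _ in mol.atoms]
    for b in mol.bonds:
        if frozenset((b.a, b.b)) not in cut_set:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
    unseen = set(range(len(mol.atoms)))
    comps = []
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
        incident = [b for b in cut_bonds if b.a in comp or b.b in comp]
        comps.append((comp, incident))
    return comps


def _piece_smiles(
    mol: MoleculeGraph, comp: set[int], linkers: list[tuple[Bond, int]]
) -> str:
    """SMILES of one piece; each (cut bond, map number) becomes a linker."""
    atoms_sorted = sorted(comp)
    sub, remap = mol.induced_subgraph(atoms_sorted)
    for bond, mapno in linkers:
        inside = bond.a if bond.a in comp else bond.b
        sub.atoms.append(Atom("*", kind=LINKER, linker_name=f"R{mapno}"))
        sub.bonds.append(Bond(remap[inside], len(sub.atoms) - 1, "single"))
    return sub.to_smiles()


def _piece_key(mol: MoleculeGraph, comp: set[int], incident: list[Bond]) -> str:
    """Deterministic ordering key: piece SMILES with generic dummy caps."""
    sub, remap = mol.induced_subgraph(sorted(comp))
    for bond in incident:
        inside = bond.a if bond.a in comp else bond.b
        sub.atoms.append(Atom("*", kind=RING))
        sub.bonds.append(Bond(remap[inside], len(sub.atoms) - 1, "single"))
    return sub.to_smiles()


def _chain_pieces(mol: MoleculeGraph, cut_bonds: list[Bond]) -> list[str]:
    """Order the pieces into a chain and emit SMILES with positional linkers.

    Piece i and i+1 are joined via linker ``R{i+1}``.  End pieces are
    ordered deterministically by their dummy-capped canonical SMILES.
    """
    comps = _split_pieces(mol, cut_bonds)
    if len(cut_bonds) == 0:
        raise ValueError("no cut bonds")
    if len(comps) != len(cut_bonds) + 1:
        raise ValueError("cut bonds must be acyclic (bridges)")
    if len(comps) == 2:
        ordered = sorted(comps, key=lambda c: _piece_key(mol, c[0], c[1]))
        bond = cut_bonds[0]
        return [
            _piece_smiles(mol, ordered[0][0], [(bond, 1)]),
            _piece_smiles(mol, ordered[1][0], [(bond, 1)]),
        ]
    # three pieces: the middle one touches both cut bonds
    middle = next(c for c in comps if len(c[1]) == 2)
    ends = sorted(
        (c for c in comps if c is not middle),
        key=lambda c: _piece_key(mol, c[0], c[1]),
    )
    first_bond = ends[0][1][0]
    second_bond = ends[1][1][0]
    return [
        _piece_smiles(mol, ends[0][0], [(first_bond, 1)]),
        _piece_smiles(mol, middle[0], [(first_bond, 1), (second_bond, 2)]),
        _piece_smiles(mol, ends[1][0], [(second_bond, 2)]),
    ]


def generate_space(spec: SyntheticSpaceSpec) -> FragmentSpace:
    """Fragment the source molecules and pool the pieces into chain graphs."""
    rng = random.Random(spec.seed)
    pools: dict[int, list[list[str]]] = {}  # piece count -> per-position pools
    for smi in spec.source_smiles:
        try:
            mol = MoleculeGraph.from_smiles(smi)
        except ValueError:
            logger.warning("skipping unparsable source molecule %r", smi)
            continue
        bridges = [
            b
            for b in mol.bridges()
            if b.order == "single"
            and not mol.atoms[b.a].is_placeholder
            and not mol.atoms[b.b].is_placeholder
        ]
        feasible = [c for c in spec.cuts if c <= len(bridges)]
        if not feasible:
            logger.warning("skipping source molecule without cuttable bond: %r", smi)
            continue
        ncuts = rng.choice(feasible)
        cut_bonds = rng.sample(bridges, ncuts)
        pieces = _chain_pieces(mol, cut_bonds)
        slots = pools.setdefault(len(pieces), [[] for _ in range(len(pieces))])
        for pos, piece in enumerate(pieces):
            if piece not in slots[pos]:
                slots[pos].append(piece)

    graphs = []
    for npieces in sorted(pools):
        slots = pools[npieces]
        graphs.append(
            {
                "id": f"chain{npieces}",
                "nodes": [
                    {"id": f"n{pos + 1}", "fragments": sorted(slot)}
                    for pos, slot in enumerate(slots)
                ],
                "edges": [
                    {
                        "a": f"n{pos + 1}",
                        "b": f"n{pos + 2}",
                        "linker_a": f"R{pos + 1}",
                        "linker_b": f"R{pos + 1}",
                        "kind": "single_bond",
                        "order": "single",
                    }
                    for pos in range(npieces - 1)
                ],
            }
        )
    if not graphs:
        raise ValueError("no source molecule could be fragmented")
    return parse_space_dict(
        {
            "format": "fragspace-json",
            "version": 1,
            "name": spec.name,
            "metadata": {"seed": spec.seed, "n_sources": len(spec.source_smiles)},
            "graphs": graphs,
        }
    )


# ---------------------------------------------------------------------------
# query / SMARTS sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QueryCase:
    case_id: str
    query_smiles: str
    smarts: str
    pattern_size: int  # heavy atoms matched by the pattern


_BOND_TOKEN = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}


def _atom_smarts(atom: Chem.Atom) -> str:
    parts = [f"#{atom.GetAtomicNum()}", "R" if atom.IsInRing() else "!R"]
    charge = atom.GetFormalCharge()
    if charge:
        sign = "+" if charge > 0 else "-"
        parts.append(sign + (str(abs(charge)) if abs(charge) > 1 else ""))
    return "[" + ";".join(parts) + "]"


def subset_smarts(mol: Chem.Mol, atom_ids: set[int]) -> str:
    """SMARTS for the induced substructure: element + ring membership per
    atom, explicit bond orders, ring closures for cycles."""
    nbrs: dict[int, list[tuple[int, Chem.Bond]]] = {a: [] for a in atom_ids}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in atom_ids and j in atom_ids:
            nbrs[i].append((j, b))
            nbrs[j].append((i, b))
    for a in nbrs:
        nbrs[a].sort(key=lambda t: t[0])
    start = min(atom_ids)

    tree_children: dict[int, list[tuple[int, Chem.Bond]]] = {a: [] for a in atom_ids}
    back_digit: dict[int, str] = {}
    visited = {start}
    stack = [start]
    tree_bonds: set[int] = set()
    # iterative DFS for the spanning tree + back edges
    def dfs(v: int):
        for u, b in nbrs[v]:
            bi = b.GetIdx()
            if bi in tree_bonds or bi in back_digit:
                continue
            if u in visited:
                back_digit[bi] = str(len(back_digit) + 1)
            else:
                visited.add(u)
                tree_bonds.add(bi)
                tree_children[v].append((u, b))
                dfs(u)

    dfs(start)

    def write(v: int) -> str:
        parts = [_atom_smarts(mol.GetAtomWithIdx(v))]
        for u, b in nbrs[v]:
            if b.GetIdx() in back_digit:
                parts.append(_BOND_TOKEN[b.GetBondType()] + back_digit[b.GetIdx()])
        children = tree_children[v]
        for i, (u, b) in enumerate(children):
            inner = _BOND_TOKEN[b.GetBondType()] + write(u)
            parts.append(f"({inner})" if i < len(children) - 1 else inner)
        return "".join(parts)

    return write(start)


def _ring_closure(mol: Chem.Mol, atoms: set[int]) -> set[int]:
    """Grow the set until every touched ring is included whole."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    atoms = set(atoms)
    changed = True
    while changed:
        changed = False
        for ring in rings:
            if atoms & ring and not ring <= atoms:
                atoms |= ring
                changed = True
    return atoms


def _random_substructure(
    mol: Chem.Mol, size: int, rng: random.Random, attempts: int = 40
) -> set[int] | None:
    """A random connected atom set of exactly ``size`` atoms, rings whole."""
    n = mol.GetNumAtoms()
    for _ in range(attempts):
        current = _ring_closure(mol, {rng.randrange(n)})
        if len(current) > size:
            continue
        while len(current) < size:
            frontier = sorted(
                {
                    u.GetIdx()
                    for a in current
                    for u in mol.GetAtomWithIdx(a).GetNeighbors()
                    if u.GetIdx() not in current
                }
            )
            rng.shuffle(frontier)
            grown = None
            for cand in frontier:
                nxt = _ring_closure(mol, current | {cand})
                if len(nxt) <= size:
                    grown = nxt
                    break
            if grown is None:
                break
            current = grown
        if len(current) == size:
            return current
    return None


def sample_query_cases(
    sources: list[str],
    n_cases: int,
    seed: int = 0,
    sizes: tuple[int, ...] = (3, 4, 5, 6, 7),
) -> list[QueryCase]:
    """Stratified query/SMARTS cases: sizes 3-7, rings whole, >= 1 non-carbon.

    The search-dependent discard rules (no match anywhere; unweighted search
    already perfect) are applied later, in :func:`run_benchmark`.
    """
    rng = random.Random(seed)
    per_size = {s: n_cases // len(sizes) for s in sizes}
    for i in range(n_cases - sum(per_size.values())):
        per_size[sizes[i % len(sizes)]] += 1

    cases = []
    shortfall = {}
    for size in sizes:
        found = 0
        tries = 0
        max_tries = per_size[size] * 60
        while found < per_size[size] and tries < max_tries:
            tries += 1
            smi = rng.choice(sources)
            mol = Chem.MolFromSmiles(smi)
            if mol is None or mol.GetNumAtoms() < size:
                continue
            subset = _random_substructure(mol, size, rng)
            if subset is None:
                continue
            if all(
                mol.GetAtomWithIdx(a).GetAtomicNum() == 6 for a in subset
            ):
                continue
            smarts = subset_smarts(mol, subset)
            patt = Chem.MolFromSmarts(smarts)
            if patt is None or not mol.HasSubstructMatch(patt):
                continue
            cases.append(
                QueryCase(f"case{len(cases):03d}_s{size}", smi, smarts, size)
            )
            found += 1
        if found < per_size[size]:
            shortfall[size] = per_size[size] - found
    if shortfall:
        logger.warning("query-case shortfall per pattern size: %s", shortfall)
    return cases


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _result_smiles(results) -> list[str]:
    if isinstance(results, SearchResult):
        return results.smiles()
    return list(results)


def preservation_score(results, smarts: str) -> float | None:
    """Fraction of result molecules with >= 1 match of the pattern.

    Empty results are reported as missing (``None``), not as 0.
    """
    smiles = _result_smiles(results)
    if not smiles:
        return None
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ValueError(f"invalid SMARTS: {smarts!r}")
    hits = sum(
        1
        for smi in smiles
        if Chem.MolFromSmiles(smi).HasSubstructMatch(patt)
    )
    return hits / len(smiles)


def scaffold_count(results) -> int:
    """Distinct atom-based Bemis-Murcko scaffolds among the result molecules.

    Acyclic molecules all reduce to the empty scaffold and count as one class.
    """
    scaffolds = set()
    for smi in _result_smiles(results):
        mol = Chem.MolFromSmiles(smi)
        scaffolds.add(Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol)))
    return len(scaffolds)


def pairwise_similarity_distribution(
    results, descriptor: str = "csfp1.4"
) -> dict:
    """All-pairs unweighted Tanimoto; histogram with bins [0, 0.05, ..., 1]."""
    smiles = _result_smiles(results)
    if len(smiles) < 2:
        raise ValueError("need at least 2 results for a pairwise distribution")
    fps = [
        compute_fingerprint(MoleculeGraph.from_smiles(smi), descriptor)
        for smi in smiles
    ]
    sims = [
        tanimoto(a, b) for a, b in itertools.combinations(fps, 2)
    ]
    edges = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    hist, _ = np.histogram(sims, bins=edges)
    return {
        "n_pairs": len(sims),
        "bin_edges": edges.tolist(),
        "histogram": hist.tolist(),
        "mean": float(np.mean(sims)),
        "median": float(np.median(sims)),
    }


# ---------------------------------------------------------------------------
# benchmark driver
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkReport:
    rows: pd.DataFrame  # columns: case_id, pattern_size, k, preservation
    discarded: list[tuple[str, str]] = field(default_factory=list)
    failed: list[tuple[str, str]] = field(default_factory=list)

    def mean_by_k(self) -> pd.Series:
        if self.rows.empty:
            return pd.Series(dtype=float)
        return self.rows.groupby("k")["preservation"].mean()

    def mean_by_k_and_size(self) -> pd.DataFrame:
        if self.rows.empty:
            return pd.DataFrame()
        return self.rows.pivot_table(
            index="pattern_size", columns="k", values="preservation", aggfunc="mean"
        )

    def summary_dict(self) -> dict:
        return {
            "n_cases": int(self.rows["case_id"].nunique()) if not self.rows.empty else 0,
            "n_discarded": len(self.discarded),
            "n_failed": len(self.failed),
            "mean_preservation_by_k": {
                str(k): float(v) for k, v in self.mean_by_k().items()
            },
        }

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def run_benchmark(
    space: FragmentSpace,
    cases: list[QueryCase],
    k_values: tuple[float, ...] = (1, 5, 10, 20),
    cfg: SearchConfig = SearchConfig(),
    searcher: SpaceSearcher | None = None,
) -> BenchmarkReport:
    """Unweighted + weighted searches per case, preservation per k.

    A row with ``k == 1`` reports the unweighted search (the weighted path
    with k = 1 is exactly equivalent).  Discard rules: cases where no search
    produced a single pattern match, and cases where the unweighted search
    already preserved the pattern in all results.
    """
    if not k_values:
        raise ValueError("k_values must not be empty")
    if searcher is None:
        searcher = SpaceSearcher(space)
    records = []
    discarded = []
    failed = []
    for case in cases:
        try:
            unweighted = searcher.search(
                case.query_smiles, cfg=replace(cfg, weight=1.0, weight_by_size=False)
            )
            scores: dict[float, float | None] = {}
            base = preservation_score(unweighted, case.smarts)
            for k in sorted(set(k_values)):
                if k == 1:
                    scores[k] = base
                    continue
                weighted = searcher.search(
                    case.query_smiles, smarts=case.smarts, cfg=replace(cfg, weight=k)
                )
                scores[k] = preservation_score(weighted, case.smarts)
        except Exception as exc:  # keep going; record the failure
            logger.warning("case %s failed: %s", case.case_id, exc)
            failed.append((case.case_id, str(exc)))
            continue
        if base is None:
            failed.append((case.case_id, "empty unweighted result"))
            continue
        if all(not s for s in scores.values()) and not base:
            discarded.append((case.case_id, "no search produced a match"))
            continue
        if base == 1.0:
            discarded.append((case.case_id, "unweighted search already perfect"))
            continue
        for k, score in scores.items():
            if score is not None:
                records.append(
                    {
                        "case_id": case.case_id,
                        "pattern_size": case.pattern_size,
                        "k": k,
                        "preservation": score,
                    }
                )
    rows = pd.DataFrame.from_records(
        records, columns=["case_id", "pattern_size", "k", "preservation"]
    )
    return BenchmarkReport(rows, discarded, failed)
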
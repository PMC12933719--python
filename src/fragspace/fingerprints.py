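"""Count fingerprints over molecular subgraphs and their (weighted) Tanimoto.

Two descriptor families are provided:

* ``csfpA.B`` — one feature per connected induced subgraph with between A
  and B atoms.  Feature ids are canonical subgraph signatures (label-sorted
  minimal encodings), collision-free by construction.
* ``ecfpD`` — circular atom environments for radii 0..D/2, identified by an
  iteratively built canonical environment signature.

Placeholder atoms participate as a wildcard element ``*`` so that border
features of fragments can match the wildcard-capped query substructures.
A feature's *size* is its number of real (non-wildcard) atoms; sizes drive
the minimum-feature-size and weight-by-size options of the weighting.
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass, field

from .molgraph import MoleculeGraph

__all__ = [
    "Fingerprint",
    "FeatureWeighting",
    "AtomMarking",
    "parse_descriptor",
    "compute_fingerprint",
    "compute_csfp",
    "compute_ecfp",
    "marked_feature_set",
    "tanimoto",
    "weighted_tanimoto",
]

_CSFP_RE = re.compile(r"^csfp([0-9]+)\.([0-9]+)$")
_ECFP_RE = re.compile(r"^ecfp([0-9]+)$")


def parse_descriptor(tag: str) -> tuple[str, tuple[int, int]]:
    """Parse ``csfpA.B`` / ``ecfpD`` tags into (family, parameters)."""
    tag = tag.lower().replace("fcsfp", "csfp")
    m = _CSFP_RE.match(tag)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid csfp size range in {tag!r}")
        return "csfp", (lo, hi)
    m = _ECFP_RE.match(tag)
    if m:
        diameter = int(m.group(1))
        if diameter % 2:
            raise ValueError(f"ecfp diameter must be even, got {diameter}")
        return "ecfp", (diameter, 0)
    raise ValueError(f"unknown descriptor {tag!r}")


@dataclass
class Fingerprint:
    """Sparse feature -> count map plus per-feature bookkeeping.

    ``sizes`` maps feature id to real-atom count; ``atom_sets`` records, for
    each feature, the atom index sets of its occurrences (used to decide
    whether a feature consists entirely of marked atoms).
    """

    descriptor: str
    features: dict[str, int] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)
    atom_sets: dict[str, list[frozenset[int]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)

    def to_json_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "features": dict(self.features),
            "sizes": dict(self.sizes),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Fingerprint":
        return cls(d["descriptor"], dict(d["features"]), dict(d.get("sizes", {})))


# ---------------------------------------------------------------------------
# atom labels and canonical subgraph signatures
# ---------------------------------------------------------------------------


def _atom_label(graph: MoleculeGraph, idx: int) -> str:
    a = graph.atoms[idx]
    if a.is_placeholder:
        return "*"
    label = a.element.lower() if a.aromatic else a.element
    if a.charge:
        label += f"{a.charge:+d}"
    return label


_ORDER_CODE = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}


def _subgraph_signature(
    labels: list[str], edges: list[tuple[int, int, str]]
) -> str:
    """Canonical signature of a tiny labeled graph.

    Minimal encoding over all atom orderings; orderings are restricted to
    label-sorted ones (the minimum necessarily lists labels in sorted order),
    so only permutations within equal-label groups are tried.
    """
    n = len(labels)
    order0 = sorted(range(n), key=lambda i: labels[i])
    groups: list[list[int]] = []
    for idx in order0:
        if groups and labels[groups[-1][0]] == labels[idx]:
            groups[-1].append(idx)
        else:
            groups.append([idx])

    best: tuple | None = None
    for perm_groups in itertools.product(
        *(itertools.permutations(g) for g in groups)
    ):
        ordering = [i for g in perm_groups for i in g]
        pos = {old: new for new, old in enumerate(ordering)}
        ekeys = sorted(
            (min(pos[a], pos[b]), max(pos[a], pos[b]), _ORDER_CODE[o])
            for a, b, o in edges
        )
        cand = (tuple(labels[i] for i in ordering), tuple(ekeys))
        if best is None or cand < best:
            best = cand
    lab, ekeys = best
    return ".".join(lab) + "|" + ";".join(f"{a},{b}{o}" for a, b, o in ekeys)


# ---------------------------------------------------------------------------
# connected-subgraph fingerprint (CSFP-like)
# ---------------------------------------------------------------------------


def _connected_subgraphs(
    adj: list[list[int]], min_atoms: int, max_atoms: int
) -> list[tuple[int, ...]]:
    """All connected induced subgraphs with min..max atoms, each once (ESU)."""
    n = len(adj)
    out: list[tuple[int, ...]] = []

    def extend(sub: list[int], ext: list[int], root: int, forbidden: set[int]):
        if min_atoms <= len(sub) <= max_atoms:
            out.append(tuple(sub))
        if len(sub) >= max_atoms:
            return
        ext = list(ext)
        while ext:
            w = ext.pop()
            new_forbidden = forbidden | set(ext)
            new_ext = list(ext)
            for u in adj[w]:
                if u > root and u not in forbidden and u != w:
                    new_ext.append(u)
                    new_forbidden.add(u)
            extend(sub + [w], new_ext, root, new_forbidden)

    for v in range(n):
        ext = [u for u in adj[v] if u > v]
        extend([v], ext, v, {v} | set(ext))
    return out


def compute_csfp(mol: MoleculeGraph, min_atoms: int, max_atoms: int) -> Fingerprint:
    """One feature per connected subgraph with size in [min_atoms, max_atoms].

    Counts are the number of distinct atom sets mapping to a signature.
    Placeholder atoms count toward subgraph size (they stand in for one real
    partner atom) but not toward the feature's recorded real-atom ``size``.
    """
    if not 1 <= min_atoms <= max_atoms:
        raise ValueError("need 1 <= min_atoms <= max_atoms")
    fp = Fingerprint(f"csfp{min_atoms}.{max_atoms}")
    labels = [_atom_label(mol, i) for i in range(len(mol.atoms))]
    adj: list[list[int]] = [[] for _ in mol.atoms]
    for b in mol.bonds:
        adj[b.a].append(b.b)
        adj[b.b].append(b.a)
    bond_order = {frozenset((b.a, b.b)): b.order for b in mol.bonds}

    for atoms in _connected_subgraphs(adj, min_atoms, max_atoms):
        atom_set = set(atoms)
        sub_labels = [labels[i] for i in atoms]
        pos = {a: i for i, a in enumerate(atoms)}
        edges = [
            (pos[a], pos[b], bond_order[frozenset((a, b))])
            for a, b in itertools.combinations(atoms, 2)
            if frozenset((a, b)) in bond_order
        ]
        sig = _subgraph_signature(sub_labels, edges)
        fp.features[sig] = fp.features.get(sig, 0) + 1
        if sig not in fp.sizes:
            fp.sizes[sig] = sum(
                1 for i in atoms if not mol.atoms[i].is_placeholder
            )
        fp.atom_sets.setdefault(sig, []).append(frozenset(atom_set))
    return fp


# ---------------------------------------------------------------------------
# circular environment fingerprint (ECFP-like)
# ---------------------------------------------------------------------------


def compute_ecfp(mol: MoleculeGraph, diameter: int) -> Fingerprint:
    """Circular environment features for radii 0..diameter/2 with counts."""
    if diameter < 0 or diameter % 2:
        raise ValueError("diameter must be even and >= 0")
    max_radius = diameter // 2
    fp = Fingerprint(f"ecfp{diameter}")
    n = len(mol.atoms)
    if n == 0:
        return fp

    adj: list[list[tuple[int, str]]] = mol.adjacency()
    # initial invariants: label + heavy degree + hydrogen count
    sigs = [
        f"({_atom_label(mol, i)}/{len(adj[i])}/{mol.atoms[i].hcount})"
        for i in range(n)
    ]
    covered = [frozenset((i,)) for i in range(n)]

    for radius in range(max_radius + 1):
        for i in range(n):
            digest = hashlib.sha1(sigs[i].encode()).hexdigest()
            fid = f"e{radius}:{digest}"
            fp.features[fid] = fp.features.get(fid, 0) + 1
            size = sum(
                1 for a in covered[i] if not mol.atoms[a].is_placeholder
            )
            if fid not in fp.sizes:
                fp.sizes[fid] = size
            fp.atom_sets.setdefault(fid, []).append(covered[i])
        if radius == max_radius:
            break
        new_sigs = [
            "("
            + sigs[i]
            + "|"
            + ",".join(
                sorted(_ORDER_CODE[o] + sigs[u] for u, o in adj[i])
            )
            + ")"
            for i in range(n)
        ]
        new_covered = [
            covered[i].union(*(covered[u] for u, _ in adj[i]))
            if adj[i]
            else covered[i]
            for i in range(n)
        ]
        sigs, covered = new_sigs, new_covered
    return fp


def compute_fingerprint(mol: MoleculeGraph, descriptor: str) -> Fingerprint:
    family, params = parse_descriptor(descriptor)
    if family == "csfp":
        return compute_csfp(mol, params[0], params[1])
    return compute_ecfp(mol, params[0])


# ---------------------------------------------------------------------------
# marking and weighting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomMarking:
    """A set of marked atom indices of one molecule."""

    mol: MoleculeGraph
    atoms: frozenset[int]

    def __post_init__(self):
        for i in self.atoms:
            if not 0 <= i < len(self.mol.atoms):
                raise ValueError(f"marked atom index {i} out of range")


def marked_features_of(fp: Fingerprint, marked_atoms: frozenset[int]) -> set[str]:
    """Features of ``fp`` with at least one occurrence entirely inside the marking."""
    if not marked_atoms:
        return set()
    return {
        fid
        for fid, occurrences in fp.atom_sets.items()
        if any(occ <= marked_atoms for occ in occurrences)
    }


def marked_feature_set(
    mol: MoleculeGraph, marking: AtomMarking, descriptor: str
) -> set[str]:
    """The set M: feature ids consisting completely of marked atoms.

    Only features actually present in ``mol``'s fingerprint are eligible.
    """
    fp = compute_fingerprint(mol, descriptor)
    return marked_features_of(fp, frozenset(marking.atoms))


@dataclass
class FeatureWeighting:
    """Per-feature weight function: w(i) = k_i for i in M, else 1.

    ``k`` is the global weighting factor; features with fewer real atoms
    than ``min_feature_size`` keep weight 1 even when marked.  With
    ``weight_by_size`` the weight of a marked feature is additionally
    multiplied by its real-atom count.
    """

    marked: frozenset[str] = frozenset()
    k: float = 1.0
    min_feature_size: int = 1
    weight_by_size: bool = False
    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("weighting factor k must be >= 1")
        if self.min_feature_size < 1:
            raise ValueError("min_feature_size must be >= 1")

    @classmethod
    def from_marking(
        cls,
        fp: Fingerprint,
        marked_atoms: frozenset[int],
        k: float,
        min_feature_size: int = 1,
        weight_by_size: bool = False,
    ) -> "FeatureWeighting":
        marked = frozenset(marked_features_of(fp, marked_atoms))
        return cls(marked, k, min_feature_size, weight_by_size, dict(fp.sizes))

    def weight(self, fid: str) -> float:
        if fid not in self.marked:
            return 1.0
        size = self.sizes.get(fid, 1)
        if size < self.min_feature_size:
            return 1.0
        return self.k * size if self.weight_by_size else self.k

    @property
    def is_trivial(self) -> bool:
        return not self.marked or (self.k == 1.0 and not self.weight_by_size)


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def _check_descriptors(a: Fingerprint, b: Fingerprint) -> None:
    if a.descriptor != b.descriptor:
        raise ValueError(
            f"descriptor mismatch: {a.descriptor!r} vs {b.descriptor!r}"
        )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Count-vector Tanimoto: sum(min)/sum(max); both-empty defined as 0."""
    _check_descriptors(a, b)
    num = den = 0
    for fid in a.features.keys() | b.features.keys():
        xa = a.features.get(fid, 0)
        xb = b.features.get(fid, 0)
        num += min(xa, xb)
        den += max(xa, xb)
    return num / den if den else 0.0


def weighted_tanimoto(
    a: Fingerprint, b: Fingerprint, wgt: FeatureWeighting | None
) -> float:
    """Weighted Tanimoto: sum(w*min)/sum(w*max); reduces to ``tanimoto``."""
    if wgt is None or wgt.is_trivial:
        return tanimoto(a, b)
    _check_descriptors(a, b)
    num = den = 0.0
    for fid in a.features.keys() | b.features.keys():
        w = wgt.weight(fid)
        xa = a.features.get(fid, 0)
        xb = b.features.get(fid, 0)
        num += w * min(xa, xb)
        den += w * max(xa, xb)
    return num / den if den else 0.0
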
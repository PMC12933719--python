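"""Labeled molecular graphs shared by fragments, queries, and products.

A :class:`MoleculeGraph` is a plain labeled graph over heavy atoms.  Besides
real atoms it may contain *placeholder* atoms of two kinds:

* **linker** placeholders carry a unique name (``R1``, ``R2``, ...) and mark
  the position where a bond to a partner fragment forms,
* **ring** placeholders are unnamed and pad rings that are split across
  fragments so the ring appears at its true size inside a single fragment.

In SMILES, linker placeholders are written as dummy atoms with an atom-map
number (``[*:1]`` is linker ``R1``) and ring placeholders as unmapped dummy
atoms (``*``).  Hydrogens are tracked only as per-atom counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from rdkit import Chem

__all__ = [
    "Atom",
    "Bond",
    "MoleculeGraph",
    "MolParseError",
    "BOND_ORDERS",
    "ATOM",
    "LINKER",
    "RING",
]

BOND_ORDERS = ("single", "double", "triple", "aromatic")

ATOM = "atom"
LINKER = "linker"
RING = "ring"

_RD_FROM_ORDER = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_ORDER_FROM_RD = {v: k for k, v in _RD_FROM_ORDER.items()}

_LINKER_NAME_RE = re.compile(r"^R[1-9][0-9]*$")


class MolParseError(ValueError):
    """Raised when a SMILES string cannot be turned into a MoleculeGraph."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom (or placeholder) of a molecule graph."""

    element: str
    charge: int = 0
    aromatic: bool = False
    kind: str = ATOM  # one of {atom, linker, ring}
    linker_name: str | None = None
    hcount: int = 0

    @property
    def is_placeholder(self) -> bool:
        return self.kind != ATOM

    def validate(self) -> None:
        if self.kind not in (ATOM, LINKER, RING):
            raise ValueError(f"unknown atom kind {self.kind!r}")
        if self.kind == LINKER:
            if not self.linker_name:
                raise ValueError("linker placeholder must carry a nonempty name")
            if not _LINKER_NAME_RE.match(self.linker_name):
                raise ValueError(
                    f"linker name {self.linker_name!r} must look like 'R<positive int>'"
                )
        elif self.linker_name is not None:
            raise ValueError(f"{self.kind} atom must not carry a linker name")


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: str = "single"

    def validate(self, n_atoms: int) -> None:
        if not (0 <= self.a < n_atoms and 0 <= self.b < n_atoms):
            raise ValueError(f"bond ({self.a},{self.b}) references invalid atom index")
        if self.a == self.b:
            raise ValueError(f"bond endpoints must be distinct, got ({self.a},{self.b})")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")

    def other(self, idx: int) -> int:
        return self.b if idx == self.a else self.a


@dataclass
class MoleculeGraph:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol) -> "MoleculeGraph":
        atoms: list[Atom] = []
        for a in mol.GetAtoms():
            if a.GetAtomicNum() == 0:
                mapno = a.GetAtomMapNum()
                if mapno > 0:
                    atoms.append(
                        Atom("*", kind=LINKER, linker_name=f"R{mapno}",
                             aromatic=a.GetIsAromatic())
                    )
                else:
                    atoms.append(Atom("*", kind=RING, aromatic=a.GetIsAromatic()))
            else:
                atoms.append(
                    Atom(
                        a.GetSymbol(),
                        charge=a.GetFormalCharge(),
                        aromatic=a.GetIsAromatic(),
                        hcount=a.GetTotalNumHs(),
                    )
                )
        bonds = [
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _ORDER_FROM_RD[b.GetBondType()])
            for b in mol.GetBonds()
        ]
        g = cls(atoms, bonds)
        g.validate()
        return g

    @classmethod
    def from_smiles(cls, smiles: str) -> "MoleculeGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MolParseError(f"invalid SMILES: {smiles!r}")
        return cls.from_rdkit(mol)

    # -- conversion -------------------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for atom in self.atoms:
            if atom.is_placeholder:
                ra = Chem.Atom(0)
                if atom.kind == LINKER:
                    ra.SetAtomMapNum(int(atom.linker_name[1:]))
            else:
                ra = Chem.Atom(atom.element)
                ra.SetFormalCharge(atom.charge)
                ra.SetNoImplicit(True)
                ra.SetNumExplicitHs(atom.hcount)
            ra.SetIsAromatic(atom.aromatic)
            rw.AddAtom(ra)
        for bond in self.bonds:
            rw.AddBond(bond.a, bond.b, _RD_FROM_ORDER[bond.order])
            if bond.order == "aromatic":
                rw.GetBondBetweenAtoms(bond.a, bond.b).SetIsAromatic(True)
        mol = rw.GetMol()
        if sanitize:
            Chem.SanitizeMol(mol)
        return mol

    def to_smiles(self) -> str:
        """Canonical SMILES (placeholders as mapped/unmapped dummies)."""
        return Chem.MolToSmiles(self.to_rdkit())

    # -- inspection -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def heavy_atom_count(self) -> int:
        """Number of real (non-placeholder) atoms."""
        return sum(1 for a in self.atoms if not a.is_placeholder)

    def placeholder_indices(self, kind: str | None = None) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.is_placeholder and (kind is None or a.kind == kind)
        ]

    def linker_names(self) -> list[str]:
        return [a.linker_name for a in self.atoms if a.kind == LINKER]

    def adjacency(self) -> list[list[tuple[int, str]]]:
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.a].append((b.b, b.order))
            adj[b.b].append((b.a, b.order))
        return adj

    def degree(self, idx: int) -> int:
        return sum(1 for b in self.bonds if idx in (b.a, b.b))

    def is_connected(self) -> bool:
        if not self.atoms:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            v = stack.pop()
            for u, _ in adj[v]:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return len(seen) == len(self.atoms)

    def validate(self) -> None:
        for atom in self.atoms:
            atom.validate()
        seen_pairs: set[frozenset[int]] = set()
        for bond in self.bonds:
            bond.validate(len(self.atoms))
            pair = frozenset((bond.a, bond.b))
            if pair in seen_pairs:
                raise ValueError(f"duplicate bond between atoms {bond.a} and {bond.b}")
            seen_pairs.add(pair)
        for idx in self.placeholder_indices():
            if self.degree(idx) < 1:
                raise ValueError(f"placeholder atom {idx} has degree 0")

    # -- editing helpers --------------------------------------------------

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(list(self.atoms), list(self.bonds))

    def without_atoms(self, remove: Iterable[int]) -> "MoleculeGraph":
        """Induced subgraph after deleting ``remove`` (indices re-packed)."""
        removed = set(remove)
        remap: dict[int, int] = {}
        atoms: list[Atom] = []
        for i, atom in enumerate(self.atoms):
            if i not in removed:
                remap[i] = len(atoms)
                atoms.append(atom)
        bonds = [
            Bond(remap[b.a], remap[b.b], b.order)
            for b in self.bonds
            if b.a not in removed and b.b not in removed
        ]
        return MoleculeGraph(atoms, bonds)

    def induced_subgraph(self, keep: Sequence[int]) -> tuple["MoleculeGraph", dict[int, int]]:
        """Induced subgraph on ``keep``; returns (graph, old->new index map)."""
        keep = list(keep)
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [self.atoms[i] for i in keep]
        bonds = [
            Bond(remap[b.a], remap[b.b], b.order)
            for b in self.bonds
            if b.a in remap and b.b in remap
        ]
        return MoleculeGraph(atoms, bonds), remap

    def bridges(self) -> list[Bond]:
        """Acyclic bonds, i.e. bonds not contained in any ring."""
        # a bond is a bridge iff removing it disconnects its endpoints
        out = []
        adj = self.adjacency()
        for bond in self.bonds:
            seen = {bond.a}
            stack = [bond.a]
            found = False
            while stack and not found:
                v = stack.pop()
                for u, _ in adj[v]:
                    if v == bond.a and u == bond.b:
                        continue
                    if (frozenset((v, u)) == frozenset((bond.a, bond.b))):
                        continue
                    if u == bond.b:
                        found = True
                        break
                    if u not in seen:
                        seen.add(u)
                        stack.append(u)
            if not found:
                out.append(bond)
        return out
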
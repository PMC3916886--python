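"""Internal molecular-graph model.

A :class:`MoleculeRecord` is one structure record from an SD file: a labelled
graph of atoms (element, formal charge, isotope mass number, implicit-H count,
2D coordinates) and bonds (order 1-3 plus a wedge/geometry annotation as
drawn).  Implicit hydrogens are completed from a standard valence table at
construction time; explicit H atoms stay in the graph until normalization
folds them.  Records whose valences cannot be completed are flagged rather
than silently repaired.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import networkx as nx


class Wedge(enum.Enum):
    """Bond stereo annotation as drawn in the molfile."""

    NONE = "none"
    UP = "up"
    DOWN = "down"
    EITHER = "either"


# neutral valences; multi-valent entries list the allowed expansions
_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,),
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "Si": (4,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
    "Se": (2, 4, 6),
    # monovalent metals occur only as counterions
    "Na": (0, 1),
    "K": (0, 1),
    "Li": (0, 1),
}

# elements whose valence shifts with formal charge like N/O (add charge)
_CHARGE_ADDS = {"N", "P", "O", "S", "Se", "F", "Cl", "Br", "I"}


def allowed_valences(element: str, charge: int) -> tuple[int, ...]:
    base = _VALENCES.get(element)
    if base is None:
        return ()
    if charge == 0:
        return base
    if element in _CHARGE_ADDS:
        return tuple(v + charge for v in base if v + charge >= 0)
    # C, B and metals: charge removes a bonding electron either way
    return tuple(max(0, v - abs(charge)) for v in base)


@dataclass
class Atom:
    element: str
    charge: int = 0
    isotope: Optional[int] = None
    h_count: int = 0  # implicit hydrogens
    x: float = 0.0
    y: float = 0.0


@dataclass
class Bond:
    a1: int  # begin atom (wedge origin, molfile convention)
    a2: int
    order: int = 1
    wedge: Wedge = Wedge.NONE


@dataclass
class MoleculeRecord:
    source_id: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    rejected: bool = False
    flags: set[str] = field(default_factory=set)

    def copy(self) -> "MoleculeRecord":
        return MoleculeRecord(
            source_id=self.source_id,
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            rejected=self.rejected,
            flags=set(self.flags),
        )

    # -- graph views -------------------------------------------------

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.atoms)))
        for i, b in enumerate(self.bonds):
            g.add_edge(b.a1, b.a2, order=b.order, index=i)
        return g

    def neighbors(self) -> list[list[tuple[int, int]]]:
        """Adjacency list: per atom, (neighbor index, bond index)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for i, b in enumerate(self.bonds):
            adj[b.a1].append((b.a2, i))
            adj[b.a2].append((b.a1, i))
        return adj

    def bond_order_sum(self, atom_index: int) -> int:
        return sum(
            b.order for b in self.bonds if atom_index in (b.a1, b.a2)
        )

    @property
    def fragment_count(self) -> int:
        if not self.atoms:
            return 0
        return nx.number_connected_components(self.graph())

    def fragments(self) -> list[list[int]]:
        """Connected components, each sorted by atom index, in stable order."""
        comps = [sorted(c) for c in nx.connected_components(self.graph())]
        return sorted(comps)

    def has_coordinates(self) -> bool:
        return any(a.x != 0.0 or a.y != 0.0 for a in self.atoms)

    # -- valence completion ------------------------------------------

    def complete_hydrogens(self) -> None:
        """Fill implicit-H counts from the valence table.

        An atom already carrying an explicit h_count is topped up only if its
        current valence is below every allowed target; atoms with no plausible
        valence mark the whole record with the 'valence' flag.
        """
        for i, atom in enumerate(self.atoms):
            occupied = self.bond_order_sum(i) + atom.h_count
            allowed = allowed_valences(atom.element, atom.charge)
            if not allowed:
                self.flags.add("valence")
                continue
            targets = [v for v in allowed if v >= occupied]
            if not targets:
                self.flags.add("valence")
                continue
            atom.h_count += min(targets) - occupied

    def validate(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.a1 < n and 0 <= b.a2 < n) or b.a1 == b.a2:
                raise ValueError(
                    f"{self.source_id}: bond references invalid atom"
                )
            if b.order not in (1, 2, 3):
                raise ValueError(f"{self.source_id}: bad bond order {b.order}")


def permuted(record: MoleculeRecord, order: Iterable[int]) -> MoleculeRecord:
    """Return the record with atoms re-indexed by the given permutation.

    ``order[new_index] = old_index``; wedge begin/end roles are preserved.
    """
    order = list(order)
    inverse = {old: new for new, old in enumerate(order)}
    rec = MoleculeRecord(
        source_id=record.source_id,
        atoms=[replace(record.atoms[old]) for old in order],
        bonds=[
            Bond(inverse[b.a1], inverse[b.a2], b.order, b.wedge)
            for b in record.bonds
        ],
        rejected=record.rejected,
        flags=set(record.flags),
    )
    return rec
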
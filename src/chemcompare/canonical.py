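"""Canonical graph labelling and identity hashing.

The identity keys are hashes of a canonical serialization of the molecular
graph.  Canonicalization uses iterative neighbourhood refinement (partition
atoms by (invariant, multiset of neighbour classes), iterate to a fixed
point) followed by individualization branching: whenever a cell of the stable
partition holds more than one atom, each member is tried as the next unique
atom and the lexicographically smallest complete serialization wins.  The
result is invariant under any permutation of the input atom order.

Wedge annotations enter the serialization (so stereo drawings are
distinguished) but not the refinement invariants; refinement sees only the
intrinsic coloured graph, which keeps the branch set automorphism-closed.
"""

from __future__ import annotations

import base64
import hashlib
from typing import Optional, Sequence

from .records import MoleculeRecord, Wedge

_WEDGE_CODE = {Wedge.NONE: "", Wedge.UP: "u", Wedge.DOWN: "d", Wedge.EITHER: "e"}


def initial_invariants(record: MoleculeRecord) -> list[tuple]:
    adj = record.neighbors()
    return [
        (a.element, a.charge, a.isotope or 0, a.h_count, len(adj[i]))
        for i, a in enumerate(record.atoms)
    ]


def refine(record: MoleculeRecord, seed_ranks: Sequence[tuple]) -> list[int]:
    """Refine a partition to a fixed point; returns dense integer ranks."""
    adj = record.neighbors()
    ranks = _densify(seed_ranks)
    while True:
        sigs = []
        for i in range(len(record.atoms)):
            nbr = sorted(
                (record.bonds[bi].order, ranks[j]) for j, bi in adj[i]
            )
            sigs.append((ranks[i], tuple(nbr)))
        new_ranks = _densify(sigs)
        if new_ranks == ranks:
            return ranks
        ranks = new_ranks


def symmetry_classes(record: MoleculeRecord) -> list[int]:
    """Stable-partition classes ('orbits' up to refinement resolution)."""
    if not record.atoms:
        return []
    return refine(record, initial_invariants(record))


def _densify(keys: Sequence) -> list[int]:
    order = {k: i for i, k in enumerate(sorted(set(keys)))}
    return [order[k] for k in keys]


def _serialize(record: MoleculeRecord, ranks: Sequence[int]) -> str:
    """Serialize under a discrete ranking (a permutation)."""
    pos = [0] * len(ranks)
    for i, r in enumerate(ranks):
        pos[i] = r
    order = sorted(range(len(ranks)), key=lambda i: pos[i])
    atom_tokens = []
    for i in order:
        a = record.atoms[i]
        tok = a.element
        if a.charge:
            tok += f"{a.charge:+d}"
        if a.isotope:
            tok += f"i{a.isotope}"
        tok += f"h{a.h_count}"
        atom_tokens.append(tok)
    bond_tokens = []
    for b in record.bonds:
        r1, r2 = pos[b.a1], pos[b.a2]
        w = _WEDGE_CODE[b.wedge]
        if w and w != "e":
            # wedge origin matters: record whether begin atom is the low rank
            w += "b" if r1 <= r2 else "t"
        lo, hi = (r1, r2) if r1 <= r2 else (r2, r1)
        bond_tokens.append(f"{lo}-{hi}:{b.order}{w}")
    bond_tokens.sort()
    return "|".join(atom_tokens) + "//" + "|".join(bond_tokens)


def canonical_serialization(record: MoleculeRecord) -> str:
    """Lexicographically smallest serialization over canonical labellings."""
    n = len(record.atoms)
    if n == 0:
        return "//"
    best: list[Optional[str]] = [None]

    def rec(seed: Sequence[tuple]) -> None:
        ranks = refine(record, seed)
        cells: dict[int, list[int]] = {}
        for i, r in enumerate(ranks):
            cells.setdefault(r, []).append(i)
        tied = sorted(r for r, members in cells.items() if len(members) > 1)
        if not tied:
            ser = _serialize(record, ranks)
            if best[0] is None or ser < best[0]:
                best[0] = ser
            return
        cell = cells[tied[0]]
        for atom in cell:
            seed2 = [(ranks[i], 1 if i == atom else 2) for i in range(n)]
            rec(seed2)

    rec(initial_invariants(record))
    assert best[0] is not None
    return best[0]


def hash_key(serialization: str) -> str:
    """27-character base-32 rendering of a 136-bit digest of the text."""
    digest = hashlib.blake2b(serialization.encode(), digest_size=17).digest()
    return base64.b32encode(digest).decode().rstrip("=")[:27]


def key_for(record: MoleculeRecord) -> str:
    return hash_key(canonical_serialization(record))
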
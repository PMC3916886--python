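"""Graded structure normalization and identity keys.

Three bespoke sensitivity levels mirror the graded-identity idea used for
compound-collection comparison:

* ``SENSITIVE`` ("ficts"): base normalization only — keys keep fragments,
  charges, isotopes, the drawn tautomeric form and stereo marks.
* ``TAUTOMER_INVARIANT`` ("ficus"): additionally folds tautomers to a
  canonical representative, per fragment.
* ``SKELETON`` ("uuuuu"): parent fragment only, neutralized, isotope- and
  stereo-stripped, tautomer-canonical — basic connectivity identity.

Base normalization applies, in fixed order: explicit-H folding, a small
documented functional-group transform table (neutral pentavalent nitro,
azide/diazo, charge-separated sulfoxide), and charged-resonance
canonicalization (the charge placement whose canonical serialization is
lexicographically smallest wins).  Every operator is idempotent and
permutation-invariant; records with uncorrectable valences are flagged
``rejected`` and excluded from identity statistics.

Standard InChIKey is a pluggable external provider (see
:mod:`chemcompare.providers`), never re-implemented here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .canonical import canonical_serialization, hash_key, symmetry_classes
from .records import Atom, Bond, MoleculeRecord, Wedge, allowed_valences

TAUTOMER_CAP = 1000

# elements allowed as 1,3-shift donor/acceptor and pivot
_SHIFT_ENDS = {"C", "N", "O", "S"}
_SHIFT_HETERO = {"N", "O", "S"}
_SHIFT_PIVOTS = {"C", "N"}


class SensitivityLevel(str, enum.Enum):
    """Identity-key sensitivity, ordered by normalization aggressiveness."""

    SENSITIVE = "ficts"
    TAUTOMER_INVARIANT = "ficus"
    SKELETON = "uuuuu"
    EXTERNAL_STANDARD = "stdkey"
    EXTERNAL_TAUTO = "tautokey"

    @property
    def aggressiveness(self) -> int:
        return {"ficts": 0, "ficus": 1, "uuuuu": 2}.get(self.value, -1)


@dataclass
class IdentifierBundle:
    source_id: str
    keys: dict[SensitivityLevel, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# base normalization
# ---------------------------------------------------------------------------


def normalize_base(record: MoleculeRecord) -> MoleculeRecord:
    rec = record.copy()
    _fold_explicit_h(rec)
    _apply_transform_table(rec)
    _recheck_valences(rec)
    if rec.rejected:
        return rec
    _canonicalize_charge_placement(rec)
    return rec


def _fold_explicit_h(rec: MoleculeRecord) -> None:
    """Fold plain explicit H atoms into their neighbour's implicit count.

    H atoms carrying an isotope label, a charge, or sitting on a wedged bond
    stay in the graph (folding them would lose information the sensitive key
    must keep).
    """
    adj = rec.neighbors()
    to_fold: list[tuple[int, int]] = []  # (H index, neighbour index)
    for i, a in enumerate(rec.atoms):
        if a.element != "H" or a.charge or a.isotope:
            continue
        if len(adj[i]) != 1:
            continue
        j, bi = adj[i][0]
        b = rec.bonds[bi]
        if b.order != 1 or b.wedge is not Wedge.NONE:
            continue
        if rec.atoms[j].element == "H":
            continue
        to_fold.append((i, j))
    if not to_fold:
        return
    doomed = {i for i, _ in to_fold}
    for _, j in to_fold:
        rec.atoms[j].h_count += 1
    remap = {}
    new_atoms = []
    for i, a in enumerate(rec.atoms):
        if i in doomed:
            continue
        remap[i] = len(new_atoms)
        new_atoms.append(a)
    rec.atoms = new_atoms
    rec.bonds = [
        Bond(remap[b.a1], remap[b.a2], b.order, b.wedge)
        for b in rec.bonds
        if b.a1 not in doomed and b.a2 not in doomed
    ]


def _apply_transform_table(rec: MoleculeRecord) -> None:
    """Fix the documented miss-drawn functional groups.

    1. neutral pentavalent nitro  R-N(=O)=O  ->  R-[N+](=O)[O-]
    2. neutral azide / diazo      X=N=N(terminal)  ->  X=[N+]=[N-]
    3. charge-separated sulfoxide [S+]-[O-]  ->  S=O
    """
    adj = rec.neighbors()

    def bonds_of(i: int) -> list[tuple[int, Bond]]:
        return [(j, rec.bonds[bi]) for j, bi in adj[i]]

    classes = symmetry_classes(rec) if rec.atoms else []
    for i, a in enumerate(rec.atoms):
        if a.element == "N" and a.charge == 0:
            dbl_o = [
                (j, b)
                for j, b in bonds_of(i)
                if b.order == 2
                and rec.atoms[j].element == "O"
                and rec.atoms[j].charge == 0
                and len(adj[j]) == 1
            ]
            dbl_n_terminal = [
                (j, b)
                for j, b in bonds_of(i)
                if b.order == 2
                and rec.atoms[j].element == "N"
                and rec.atoms[j].charge == 0
                and len(adj[j]) == 1
            ]
            n_doubles = sum(1 for _, b in bonds_of(i) if b.order == 2)
            if len(dbl_o) == 2:
                # nitro: move the negative charge to the symmetry-smallest O
                j, b = min(dbl_o, key=lambda t: (classes[t[0]], t[0]))
                b.order = 1
                rec.atoms[j].charge = -1
                rec.atoms[j].h_count = 0  # re-derived by the valence recheck
                a.charge = +1
                a.h_count = 0
            elif n_doubles == 2 and dbl_n_terminal:
                j, _ = dbl_n_terminal[0]
                rec.atoms[j].charge = -1
                rec.atoms[j].h_count = 0
                a.charge = +1
                a.h_count = 0
        elif a.element == "S" and a.charge == +1:
            for j, b in bonds_of(i):
                if (
                    b.order == 1
                    and rec.atoms[j].element == "O"
                    and rec.atoms[j].charge == -1
                    and len(adj[j]) == 1
                    and b.wedge is Wedge.NONE
                ):
                    b.order = 2
                    rec.atoms[j].charge = 0
                    rec.atoms[j].h_count = 0
                    a.charge = 0
                    break


def _recheck_valences(rec: MoleculeRecord) -> None:
    rec.flags.discard("valence")
    for i, a in enumerate(rec.atoms):
        occupied = rec.bond_order_sum(i) + a.h_count
        allowed = allowed_valences(a.element, a.charge)
        targets = [v for v in allowed if v >= occupied]
        if not targets:
            rec.rejected = True
            rec.flags.add("valence")
            return
        a.h_count += min(targets) - occupied


def _canonicalize_charge_placement(rec: MoleculeRecord) -> None:
    """Among charged-resonance forms reachable by single charge/bond swaps
    (X(q)-A=Y -> X=A-Y(q), same element and H count on X/Y), greedily move to
    the form with the lexicographically smallest canonical serialization."""
    if not any(a.charge for a in rec.atoms):
        return
    current = canonical_serialization(rec)
    while True:
        best_ser = current
        best_swap: Optional[tuple[int, int]] = None
        adj = rec.neighbors()
        for u, a in enumerate(rec.atoms):
            if a.charge == 0:
                continue
            for c, bi_uc in adj[u]:
                b_uc = rec.bonds[bi_uc]
                if b_uc.order != 1 or b_uc.wedge is not Wedge.NONE:
                    continue
                for v, bi_cv in adj[c]:
                    if v == u:
                        continue
                    b_cv = rec.bonds[bi_cv]
                    av = rec.atoms[v]
                    if (
                        b_cv.order != 2
                        or b_cv.wedge is not Wedge.NONE
                        or av.element != a.element
                        or av.charge != 0
                        or av.isotope != a.isotope
                        or av.h_count != a.h_count
                    ):
                        continue
                    _swap_charge(rec, u, v, bi_uc, bi_cv)
                    ser = canonical_serialization(rec)
                    _swap_charge(rec, v, u, bi_cv, bi_uc)
                    if ser < best_ser:
                        best_ser = ser
                        best_swap = (bi_uc, bi_cv)
                        best_atoms = (u, v)
        if best_swap is None:
            return
        u, v = best_atoms
        _swap_charge(rec, u, v, best_swap[0], best_swap[1])
        current = best_ser


def _swap_charge(rec: MoleculeRecord, u: int, v: int, bi_uc: int, bi_cv: int) -> None:
    rec.atoms[v].charge = rec.atoms[u].charge
    rec.atoms[u].charge = 0
    rec.bonds[bi_uc].order = 2
    rec.bonds[bi_cv].order = 1


# ---------------------------------------------------------------------------
# level-specific operators (each idempotent)
# ---------------------------------------------------------------------------


def select_parent(record: MoleculeRecord) -> MoleculeRecord:
    """Keep the fragment with the most heavy atoms (ties: larger MW, then
    lexicographically smallest canonical serialization)."""
    from .mw import molecular_weight  # local import avoids a cycle

    if not record.atoms:
        rec = record.copy()
        rec.rejected = True
        rec.flags.add("empty")
        return rec
    frags = record.fragments()
    if len(frags) == 1:
        return record.copy()
    subrecords = [_subrecord(record, f) for f in frags]

    def score(sub: MoleculeRecord) -> tuple:
        heavy = sum(1 for a in sub.atoms if a.element != "H")
        return (-heavy, -molecular_weight(sub), canonical_serialization(sub))

    return min(subrecords, key=score)


def _subrecord(record: MoleculeRecord, atom_indices: list[int]) -> MoleculeRecord:
    remap = {old: new for new, old in enumerate(atom_indices)}
    sub = MoleculeRecord(
        source_id=record.source_id,
        atoms=[record.atoms[i] for i in atom_indices],
        bonds=[
            Bond(remap[b.a1], remap[b.a2], b.order, b.wedge)
            for b in record.bonds
            if b.a1 in remap and b.a2 in remap
        ],
        flags=set(record.flags),
    )
    return sub.copy()


def neutralize(record: MoleculeRecord) -> MoleculeRecord:
    """Cancel formal charges by implicit-H arithmetic where valence permits;
    non-neutralizable centres (e.g. quaternary N) retain their charge."""
    rec = record.copy()
    for a in rec.atoms:
        while a.charge < 0:
            a.charge += 1
            a.h_count += 1
        while a.charge > 0 and a.h_count > 0:
            a.charge -= 1
            a.h_count -= 1
    return rec


def clear_isotopes(record: MoleculeRecord) -> MoleculeRecord:
    rec = record.copy()
    for a in rec.atoms:
        a.isotope = None
    _fold_explicit_h(rec)  # de-labelled D/T become plain H
    return rec


def strip_stereo(record: MoleculeRecord) -> MoleculeRecord:
    rec = record.copy()
    for b in rec.bonds:
        b.wedge = Wedge.NONE
    return rec


# ---------------------------------------------------------------------------
# tautomer canonicalization
# ---------------------------------------------------------------------------


def _shift_sites(rec: MoleculeRecord) -> list[tuple[int, int, int, int, int]]:
    """Enumerate 1,3 H-shift sites (donor a, pivot b, acceptor c, bonds)."""
    adj = rec.neighbors()
    wedge_origin = {
        b.a1 for b in rec.bonds if b.wedge in (Wedge.UP, Wedge.DOWN)
    }
    sites = []
    for a_idx, a in enumerate(rec.atoms):
        if a.h_count < 1 or a.charge or a.element not in _SHIFT_ENDS:
            continue
        for b_idx, bi_ab in adj[a_idx]:
            b_atom = rec.atoms[b_idx]
            bond_ab = rec.bonds[bi_ab]
            if bond_ab.order != 1 or bond_ab.wedge is not Wedge.NONE:
                continue
            if b_atom.element not in _SHIFT_PIVOTS:
                continue
            for c_idx, bi_bc in adj[b_idx]:
                if c_idx == a_idx:
                    continue
                c_atom = rec.atoms[c_idx]
                bond_bc = rec.bonds[bi_bc]
                if bond_bc.order != 2 or bond_bc.wedge is not Wedge.NONE:
                    continue
                if c_atom.charge or c_atom.element not in _SHIFT_ENDS:
                    continue
                if not ({a.element, c_atom.element} & _SHIFT_HETERO):
                    continue
                if {a_idx, b_idx, c_idx} & wedge_origin:
                    # shifting through a drawn stereocentre would erase its
                    # wedge and collapse stereoisomers at this level
                    continue
                sites.append((a_idx, b_idx, c_idx, bi_ab, bi_bc))
    return sites


def _apply_shift(rec: MoleculeRecord, site: tuple[int, int, int, int, int]) -> MoleculeRecord:
    a_idx, _, c_idx, bi_ab, bi_bc = site
    out = rec.copy()
    out.atoms[a_idx].h_count -= 1
    out.atoms[c_idx].h_count += 1
    out.bonds[bi_ab].order = 2
    out.bonds[bi_bc].order = 1
    return out


def canonical_tautomer(record: MoleculeRecord) -> MoleculeRecord:
    """Breadth-first enumeration of the 1,3-shift orbit (keto/enol,
    amide/iminol and aza analogues), capped at 1000 distinct forms; the form
    with the lexicographically smallest canonical serialization represents
    the orbit.  On cap overflow the input form is kept and flagged."""
    start_ser = canonical_serialization(record)
    forms: dict[str, MoleculeRecord] = {start_ser: record}
    frontier = [start_ser]
    while frontier:
        frontier.sort()
        next_frontier = []
        for ser in frontier:
            rec = forms[ser]
            for site in _shift_sites(rec):
                new = _apply_shift(rec, site)
                new_ser = canonical_serialization(new)
                if new_ser not in forms:
                    if len(forms) >= TAUTOMER_CAP:
                        out = record.copy()
                        out.flags.add("tautomer_cap")
                        return out
                    forms[new_ser] = new
                    next_frontier.append(new_ser)
        frontier = next_frontier
    rep = forms[min(forms)].copy()
    rep.source_id = record.source_id
    return rep


def _per_fragment_tautomer(record: MoleculeRecord) -> MoleculeRecord:
    frags = record.fragments()
    if len(frags) <= 1:
        return canonical_tautomer(record)
    parts = [canonical_tautomer(_subrecord(record, f)) for f in frags]
    out = MoleculeRecord(source_id=record.source_id, flags=set(record.flags))
    for part in parts:
        offset = len(out.atoms)
        out.atoms.extend(a for a in part.atoms)
        out.bonds.extend(
            Bond(b.a1 + offset, b.a2 + offset, b.order, b.wedge)
            for b in part.bonds
        )
        out.flags |= part.flags
    return out


# ---------------------------------------------------------------------------
# key computation
# ---------------------------------------------------------------------------

Provider = Callable[[MoleculeRecord], Optional[str]]


def compute_keys(
    record: MoleculeRecord,
    providers: Optional[dict[SensitivityLevel, Provider]] = None,
) -> Optional[IdentifierBundle]:
    """Identity keys at all levels; None for rejected records.

    External providers (e.g. a Standard-InChIKey backend) receive the *raw*
    record and their key strings are attached verbatim.
    """
    base = normalize_base(record)
    if base.rejected or not base.atoms:
        return None
    bundle = IdentifierBundle(source_id=record.source_id)
    bundle.keys[SensitivityLevel.SENSITIVE] = hash_key(
        canonical_serialization(base)
    )
    tauto = _per_fragment_tautomer(base)
    bundle.keys[SensitivityLevel.TAUTOMER_INVARIANT] = hash_key(
        canonical_serialization(tauto)
    )
    skeleton = canonical_tautomer(
        strip_stereo(clear_isotopes(neutralize(select_parent(base))))
    )
    bundle.keys[SensitivityLevel.SKELETON] = hash_key(
        canonical_serialization(skeleton)
    )
    for level, provider in (providers or {}).items():
        key = provider(record)
        if key:
            bundle.keys[level] = key
    return bundle


def compute_bundles(
    records: Sequence[MoleculeRecord],
    providers: Optional[dict[SensitivityLevel, Provider]] = None,
) -> tuple[list[IdentifierBundle], list[MoleculeRecord]]:
    """Key every record; rejected records are returned separately, tallied."""
    bundles, rejected = [], []
    for rec in records:
        bundle = compute_keys(rec, providers)
        if bundle is None:
            rejected.append(rec)
        else:
            bundles.append(bundle)
    return bundles, rejected


def export_key_table(
    bundles: Sequence[IdentifierBundle], path: str | Path
) -> None:
    cols = [
        SensitivityLevel.SENSITIVE,
        SensitivityLevel.TAUTOMER_INVARIANT,
        SensitivityLevel.SKELETON,
        SensitivityLevel.EXTERNAL_STANDARD,
    ]
    with open(path, "w") as fh:
        fh.write("source_id\tficts\tficus\tuuuuu\tstdkey\n")
        for b in bundles:
            fh.write(
                b.source_id
                + "\t"
                + "\t".join(b.keys.get(c, "") for c in cols)
                + "\n"
            )
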
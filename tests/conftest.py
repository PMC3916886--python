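"""Shared molecule builders for the test suite.

All fixtures are built programmatically; nothing is read from disk except
files the tests themselves write.
"""

from __future__ import annotations

import pytest

from chemcompare.records import Atom, Bond, MoleculeRecord, Wedge


def build(source_id, atom_spec, bond_spec):
    """atom_spec: list of (element, charge, isotope, x, y) or element string;
    bond_spec: list of (a1, a2[, order[, wedge]])."""
    atoms = []
    for a in atom_spec:
        if isinstance(a, str):
            atoms.append(Atom(a))
        else:
            el, charge, iso, x, y = (list(a) + [0, None, 0.0, 0.0])[:5]
            atoms.append(Atom(el, charge or 0, iso, 0, x or 0.0, y or 0.0))
    bonds = []
    for b in bond_spec:
        a1, a2 = b[0], b[1]
        order = b[2] if len(b) > 2 else 1
        wedge = b[3] if len(b) > 3 else Wedge.NONE
        bonds.append(Bond(a1, a2, order, wedge))
    rec = MoleculeRecord(source_id, atoms, bonds)
    rec.complete_hydrogens()
    return rec


@pytest.fixture
def benzene():
    return build(
        "benzene",
        ["C"] * 6,
        [(i, (i + 1) % 6, 2 if i % 2 == 0 else 1) for i in range(6)],
    )


@pytest.fixture
def ethanol():
    return build("ethanol", ["C", "C", "O"], [(0, 1), (1, 2)])


def alanine(wedged: bool):
    # N-CA(-CH3)(-COOH), CA is the single stereocentre
    wedge = Wedge.UP if wedged else Wedge.NONE
    return build(
        "alanine",
        [("N", 0, None, 0.0, 0.0), ("C", 0, None, 1.0, 0.5),
         ("C", 0, None, 1.0, 1.7), ("C", 0, None, 2.0, 0.0),
         ("O", 0, None, 2.0, -1.2), ("O", 0, None, 3.0, 0.6)],
        [(1, 0, 1, wedge), (1, 2), (1, 3), (3, 4, 2), (3, 5)],
    )


def butene_2(trans: bool, either: bool = False, coords: bool = True):
    # CH3-CH=CH-CH3 with explicit geometry
    pts = [(-0.5, -0.8), (0.0, 0.0), (1.0, 0.0), (1.5, 0.8 if trans else -0.8)]
    if not coords:
        pts = [(0.0, 0.0)] * 4
    wedge = Wedge.EITHER if either else Wedge.NONE
    return build(
        "butene",
        [("C", 0, None, *pts[0]), ("C", 0, None, *pts[1]),
         ("C", 0, None, *pts[2]), ("C", 0, None, *pts[3])],
        [(0, 1), (1, 2, 2, wedge), (2, 3)],
    )


def aspirin():
    # benzene ring + OC(=O)CH3 + COOH: 13 heavy atoms
    ring = [(i, (i + 1) % 6, 2 if i % 2 == 0 else 1) for i in range(6)]
    return build(
        "aspirin",
        ["C"] * 6 + ["C", "O", "O", "O", "C", "O", "C"],
        ring
        + [(0, 6), (6, 7, 2), (6, 8), (1, 9), (9, 10), (10, 11, 2), (10, 12)],
    )


def sodium_salt(record: MoleculeRecord, deprotonate_atom: int):
    rec = record.copy()
    rec.atoms[deprotonate_atom].charge = -1
    rec.atoms[deprotonate_atom].h_count -= 1
    rec.atoms.append(Atom("Na", charge=1))
    rec.source_id = record.source_id + "-Na"
    return rec


@pytest.fixture
def acetone():
    return build("acetone", ["C", "C", "C", "O"], [(0, 1), (1, 2), (1, 3, 2)])


@pytest.fixture
def propen2ol():
    return build("propen-2-ol", ["C", "C", "C", "O"], [(0, 1, 2), (1, 2), (1, 3)])


@pytest.fixture
def pyridone_pair():
    ring = ["N"] + ["C"] * 5 + ["O"]
    hydroxy = build(
        "2-hydroxypyridine", ring,
        [(0, 1, 2), (1, 2), (2, 3, 2), (3, 4), (4, 5, 2), (5, 0), (1, 6)],
    )
    pyridone = build(
        "2-pyridone", ring,
        [(0, 1), (1, 2), (2, 3, 2), (3, 4), (4, 5, 2), (5, 0), (1, 6, 2)],
    )
    return hydroxy, pyridone
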
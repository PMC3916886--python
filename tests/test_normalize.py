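"""The normalization cascade: transforms, level operators, key semantics."""

import numpy as np
import pytest

from chemcompare.canonical import canonical_serialization as ser
from chemcompare.normalize import (
    SensitivityLevel,
    canonical_tautomer,
    clear_isotopes,
    compute_bundles,
    compute_keys,
    neutralize,
    normalize_base,
    select_parent,
    strip_stereo,
)
from chemcompare.records import Atom, Bond, Wedge, permuted
from chemcompare.synthetic import LibrarySpec, SCAFFOLD_POOL, generate_library

from conftest import alanine, aspirin, build, sodium_salt

FICTS = SensitivityLevel.SENSITIVE
FICUS = SensitivityLevel.TAUTOMER_INVARIANT
UUUUU = SensitivityLevel.SKELETON


def nitrobenzene(charge_separated: bool):
    ring = [(i, (i + 1) % 6, 2 if i % 2 == 0 else 1) for i in range(6)]
    if charge_separated:
        atoms = ["C"] * 6 + [("N", 1), ("O", -1), "O"]
        bonds = ring + [(0, 6), (6, 7, 1), (6, 8, 2)]
    else:
        atoms = ["C"] * 6 + ["N", "O", "O"]
        bonds = ring + [(0, 6), (6, 7, 2), (6, 8, 2)]
    return build("nb", atoms, bonds)


OPERATORS = [
    normalize_base,
    select_parent,
    neutralize,
    clear_isotopes,
    strip_stereo,
    canonical_tautomer,
]


@pytest.mark.parametrize("op", OPERATORS, ids=lambda f: f.__name__)
def test_every_operator_is_idempotent(op):
    molecules = [
        aspirin(),
        alanine(wedged=True),
        nitrobenzene(False),
        sodium_salt(aspirin(), 8),
        SCAFFOLD_POOL[0].build(True),
    ]
    for mol in molecules:
        once = op(normalize_base(mol) if op is not normalize_base else mol)
        twice = op(once)
        assert ser(twice) == ser(once), f"{op.__name__} not idempotent on {mol.source_id}"


def test_benzene_is_a_fixed_point(benzene):
    assert ser(normalize_base(benzene)) == ser(benzene)


def test_nitro_drawings_converge():
    k_neutral = compute_keys(nitrobenzene(False))
    k_charged = compute_keys(nitrobenzene(True))
    assert k_neutral.keys[FICTS] == k_charged.keys[FICTS]


def test_azide_drawings_converge():
    # methyl azide: CH3-N=N=N neutral vs CH3-N=[N+]=[N-]
    neutral = build("az", ["C", "N", "N", "N"], [(0, 1), (1, 2, 2), (2, 3, 2)])
    charged = build(
        "az", ["C", "N", ("N", 1), ("N", -1)], [(0, 1), (1, 2, 2), (2, 3, 2)]
    )
    assert compute_keys(neutral).keys[FICTS] == compute_keys(charged).keys[FICTS]


def test_sulfoxide_drawings_converge():
    # dimethyl sulfoxide: charge-separated vs neutral S=O
    sep = build(
        "dmso", ["C", ("S", 1), "C", ("O", -1)], [(0, 1), (1, 2), (1, 3)]
    )
    neutral = build("dmso", ["C", "S", "C", "O"], [(0, 1), (1, 2), (1, 3, 2)])
    assert compute_keys(sep).keys[FICTS] == compute_keys(neutral).keys[FICTS]


def test_carboxylate_charge_placement_is_drawing_independent():
    # acetate with the charge on either oxygen normalizes to one key
    a = build("ac", ["C", "C", "O", ("O", -1)], [(0, 1), (1, 2, 2), (1, 3)])
    b = build("ac", ["C", "C", ("O", -1), "O"], [(0, 1), (1, 2, 1), (1, 3, 2)])
    assert compute_keys(a).keys[FICTS] == compute_keys(b).keys[FICTS]


def test_select_parent_keeps_largest_fragment():
    salt = sodium_salt(aspirin(), 8)
    parent = select_parent(normalize_base(salt))
    assert parent.fragment_count == 1
    assert sum(1 for a in parent.atoms if a.element != "H") == 13
    assert all(a.element != "Na" for a in parent.atoms)


def test_select_parent_tie_is_deterministic():
    # two identical fragments: one copy survives, same ser across runs
    frag = build("two", ["C", "O", "C", "O"], [(0, 1), (2, 3)])
    p1, p2 = select_parent(frag), select_parent(frag)
    assert len(p1.atoms) == 2
    assert ser(p1) == ser(p2)


def test_neutralize_carboxylate_and_quaternary_nitrogen():
    acid = build("acid", ["C", "C", "O", "O"], [(0, 1), (1, 2, 2), (1, 3)])
    anion = acid.copy()
    anion.atoms[3].charge = -1
    anion.atoms[3].h_count = 0
    fixed = neutralize(anion)
    assert sum(a.charge for a in fixed.atoms) == 0
    assert ser(fixed) == ser(acid)

    tma = build("tma", ["N", "C", "C", "C", "C"], [(0, i) for i in range(1, 5)])
    tma.atoms[0].charge = 1
    tma.atoms[0].h_count = 0
    assert neutralize(tma).atoms[0].charge == 1  # no H to remove


def test_clear_isotopes_folds_deuterium():
    d2o = build("d2o", [("O", 0, None), ("H", 0, 2), ("H", 0, 2)], [(0, 1), (0, 2)])
    cleared = clear_isotopes(normalize_base(d2o))
    water = build("water", ["O"], [])
    assert ser(cleared) == ser(water)


def test_keto_enol_merge_at_tautomer_level(acetone, propen2ol):
    ka, ke = compute_keys(acetone), compute_keys(propen2ol)
    assert ka.keys[FICTS] != ke.keys[FICTS]
    assert ka.keys[FICUS] == ke.keys[FICUS]
    assert ka.keys[UUUUU] == ke.keys[UUUUU]


def test_pyridone_iminol_merge_at_tautomer_level(pyridone_pair):
    hydroxy, pyridone = pyridone_pair
    kh, kp = compute_keys(hydroxy), compute_keys(pyridone)
    assert kh.keys[FICTS] != kp.keys[FICTS]
    assert kh.keys[FICUS] == kp.keys[FICUS]


def test_enantiomer_drawings_distinct_until_skeleton():
    up = alanine(wedged=True)
    down = up.copy()
    for b in down.bonds:
        if b.wedge is Wedge.UP:
            b.wedge = Wedge.DOWN
    ku, kd = compute_keys(up), compute_keys(down)
    assert ku.keys[FICTS] != kd.keys[FICTS]
    assert ku.keys[FICUS] != kd.keys[FICUS]
    assert ku.keys[UUUUU] == kd.keys[UUUUU]


def test_variant_family_key_counts():
    """A scaffold plus salt / isotope-label / enol-drawing / stereo-inverted
    variants: 5 sensitive keys, 4 tautomer-invariant keys, 1 skeleton key."""
    spec = LibrarySpec(
        n_scaffolds=1,
        uniform_plan=["salt", "isotope", "tautomer", "stereo_invert"],
        seed=4,
    )
    records, _, _ = generate_library(spec)
    assert len(records) == 5
    bundles, rejected = compute_bundles(records)
    assert not rejected
    assert len({b.keys[FICTS] for b in bundles}) == 5
    assert len({b.keys[FICUS] for b in bundles}) == 4
    assert len({b.keys[UUUUU] for b in bundles}) == 1


def test_exact_duplicates_share_all_keys():
    rec = SCAFFOLD_POOL[2].build(True)
    rng = np.random.default_rng(0)
    twin = permuted(rec, list(rng.permutation(len(rec.atoms))))
    assert compute_keys(rec).keys == compute_keys(twin).keys


def test_key_class_nesting_is_monotone():
    rng = np.random.default_rng(17)
    for trial in range(5):
        plan = list(
            rng.choice(
                ["salt", "charge", "isotope", "tautomer", "stereo_invert"],
                size=rng.integers(1, 4),
                replace=False,
            )
        )
        r1, _, _ = generate_library(
            LibrarySpec(n_scaffolds=int(rng.integers(1, 4)), uniform_plan=plan, seed=trial)
        )
        bundles, _ = compute_bundles(r1)
        n_ficts = len({b.keys[FICTS] for b in bundles})
        n_ficus = len({b.keys[FICUS] for b in bundles})
        n_uuuuu = len({b.keys[UUUUU] for b in bundles})
        assert n_ficts >= n_ficus >= n_uuuuu


def test_uncorrectable_valence_is_rejected_and_tallied():
    bad = build("bad", ["C"] * 6, [(0, i) for i in range(1, 6)])  # 5-valent C
    assert compute_keys(bad) is None
    bundles, rejected = compute_bundles([bad, aspirin()])
    assert len(bundles) == 1 and len(rejected) == 1


def test_external_provider_keys_are_attached():
    from chemcompare.providers import rdkit_inchikey

    rec = aspirin()
    bundle = compute_keys(
        rec, providers={SensitivityLevel.EXTERNAL_STANDARD: rdkit_inchikey}
    )
    key = bundle.keys.get(SensitivityLevel.EXTERNAL_STANDARD)
    assert key and len(key) == 27 and key.count("-") == 2
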
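"""Keyed-set algebra: uniques, overlaps, Venn partitions, diffs, categories."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemcompare.normalize import IdentifierBundle, SensitivityLevel
from chemcompare.sets import (
    KeyedSet,
    category_profile,
    coverage,
    overlap_matrix,
    release_diff,
    unique_percentage,
    unique_stats,
    venn,
)

FICTS = SensitivityLevel.SENSITIVE
UUUUU = SensitivityLevel.SKELETON


def bundles_from(pairs):
    """pairs: list of (sensitive_key, skeleton_key)."""
    out = []
    for i, (s, k) in enumerate(pairs):
        out.append(
            IdentifierBundle(f"R{i}", {FICTS: s, UUUUU: k})
        )
    return out


def keyed(label, keys):
    return KeyedSet(label, FICTS, set(keys), max(len(set(keys)), 1))


def test_unique_percentage_matches_printed_convention():
    # 2834 uniques of 3616 records prints as 78.3 (truncated, one decimal)
    assert unique_percentage(2834, 3616) == 78.3
    assert unique_percentage(599879, 600625) == 99.8


def test_identical_records_collapse_to_one_key():
    n = 8
    bundles = bundles_from([("AAA", "KKK")] * n)
    count, pct = unique_stats(bundles, FICTS, n)
    assert count == 1
    assert pct == 12.5


def test_missing_level_is_an_error():
    bundles = [IdentifierBundle("R0", {FICTS: "A"})]
    with pytest.raises(ValueError):
        unique_stats(bundles, UUUUU, 1)


def test_overlap_matrix_counts_and_diagonal():
    a = keyed("A", ["k1", "k2", "k3", "k4"])
    b = keyed("B", ["k3", "k4", "k5"])
    c = keyed("C", ["z1"])
    m = overlap_matrix([a, b, c])
    assert m.loc["A", "A"] == 4
    assert m.loc["A", "B"] == m.loc["B", "A"] == 2
    assert m.loc["A", "C"] == 0


def test_mixed_levels_are_rejected():
    a = keyed("A", ["k1"])
    b = KeyedSet("B", UUUUU, {"k1"}, 1)
    with pytest.raises(ValueError):
        overlap_matrix([a, b])
    with pytest.raises(ValueError):
        venn([a, b])


def test_coverage_reproduces_prose_percentages():
    # overlap/uniques pairs printed as 37% and 57% coverage
    assert coverage(1746, 4674) == 37
    assert coverage(1622, 2834) == 57


def test_venn_identical_sets_fill_only_the_full_mask():
    a = keyed("A", ["x", "y"])
    b = keyed("B", ["x", "y"])
    part = venn([a, b])
    assert part.count("A", "B") == 2
    assert part.count("A") == 0 and part.count("B") == 0
    assert part.union_size == 2


def test_venn_requires_2_to_4_sets():
    a = keyed("A", ["x"])
    with pytest.raises(ValueError):
        venn([a])
    with pytest.raises(ValueError):
        venn([keyed(str(i), ["x"]) for i in range(5)])


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    data=st.lists(
        st.lists(st.integers(min_value=0, max_value=60), max_size=80),
        min_size=2,
        max_size=4,
    )
)
def test_venn_matches_brute_force_membership_scan(data):
    sets = [keyed(f"S{i}", [f"k{v}" for v in vals]) for i, vals in enumerate(data)]
    part = venn(sets)
    union = set().union(*(s.keys for s in sets))
    # brute force: classify every key independently
    expected = {}
    for key in union:
        mask = frozenset(s.label for s in sets if key in s.keys)
        expected[mask] = expected.get(mask, 0) + 1
    assert {m: c for m, (c, _) in part.cells.items()} == expected
    # conservation laws
    assert part.union_size == len(union)
    for s in sets:
        assert part.set_total(s.label) == len(s.keys)


def test_overlap_equals_sum_of_shared_venn_cells():
    rng = np.random.default_rng(42)
    sets = [
        keyed(lab, [f"k{v}" for v in rng.integers(0, 120, size=70)])
        for lab in "ABC"
    ]
    part = venn(sets)
    m = overlap_matrix(sets)
    for i in "ABC":
        for j in "ABC":
            if i == j:
                continue
            cell_sum = sum(
                c for mask, (c, _) in part.cells.items() if {i, j} <= mask
            )
            assert m.loc[i, j] == cell_sum


def test_release_diff_trivial_cases():
    same = bundles_from([("a", "k"), ("b", "l")])
    d = release_diff(same, same)
    assert d.removed == {"ficts": 0, "uuuuu": 0}
    assert d.added == {"ficts": 0, "uuuuu": 0}
    assert d.skeleton_links == 0

    other = bundles_from([("c", "m")])
    d2 = release_diff(same, other)
    assert d2.maintained == {"ficts": 0, "uuuuu": 0}


def test_release_diff_conservation_identities():
    old = bundles_from([("a", "k"), ("b", "l"), ("c", "m")])
    new = bundles_from([("a", "k"), ("b2", "l"), ("d", "n")])
    d = release_diff(old, new)
    for level, uniques_old, uniques_new in (("ficts", 3, 3), ("uuuuu", 3, 3)):
        assert d.maintained[level] + d.removed[level] == uniques_old
        assert d.maintained[level] + d.added[level] == uniques_new
    # 'b' re-drawn: linked only at skeleton level
    assert d.skeleton_links == 1


def test_category_profile_and_partial_maps():
    ks = keyed("A", [f"k{i}" for i in range(10)])
    cats = {k: {"everything"} for k in ks.keys}
    assert category_profile(ks, cats) == {"everything": 100.0}
    # partial map: missing keys are in no category
    half = {f"k{i}": {"half"} for i in range(5)}
    assert category_profile(ks, half) == {"half": 50.0}
    with pytest.raises(ValueError):
        category_profile(KeyedSet("E", FICTS, set(), 1), {})


def test_category_profile_tracks_random_rate():
    rng = np.random.default_rng(7)
    keys = [f"k{i}" for i in range(1000)]
    p = 0.3
    flags = rng.random(1000) < p
    cats = {k: {"hit"} for k, f in zip(keys, flags) if f}
    profile = category_profile(keyed("A", keys), cats)
    # within ~4 binomial SDs of 100p
    assert abs(profile["hit"] - 100 * p) < 400 * np.sqrt(p * (1 - p) / 1000)
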
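"""Keyed-set statistics: unique counts, overlap matrices, Venn partitions,
release diffs with skeleton-level linking, and category profiles.

Keys, not record IDs, are the unit of set algebra: two records hashing to
one key contribute one element, which is exactly how "unique structures" are
counted.  Unique-count percentages are truncated to one decimal; coverage
percentages in prose-style reports round to the nearest integer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .normalize import IdentifierBundle, SensitivityLevel


@dataclass
class KeyedSet:
    label: str
    level: SensitivityLevel | str
    keys: set[str]
    original_count: int

    def __post_init__(self) -> None:
        if len(self.keys) > self.original_count:
            raise ValueError(
                f"{self.label}: more unique keys than original records"
            )


@dataclass
class VennPartition:
    labels: list[str]
    cells: dict[frozenset, tuple[int, set[str]]] = field(default_factory=dict)

    def count(self, *labels: str) -> int:
        """Exclusive cell count for exactly this membership combination."""
        return self.cells.get(frozenset(labels), (0, set()))[0]

    @property
    def union_size(self) -> int:
        return sum(c for c, _ in self.cells.values())

    def set_total(self, label: str) -> int:
        return sum(c for mask, (c, _) in self.cells.items() if label in mask)

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"sources": sorted(mask), "count": count, "keys": sorted(keys)}
            for mask, (count, keys) in sorted(
                self.cells.items(), key=lambda kv: sorted(kv[0])
            )
        ]
        Path(path).write_text(
            json.dumps({"labels": self.labels, "cells": payload}, indent=1)
        )


@dataclass
class ReleaseDiff:
    maintained: dict[str, int]
    removed: dict[str, int]
    added: dict[str, int]
    skeleton_links: int


def keyed_set(
    label: str,
    bundles: Sequence[IdentifierBundle],
    level: SensitivityLevel,
    original_count: int,
) -> KeyedSet:
    keys = set()
    for b in bundles:
        if level not in b.keys:
            raise ValueError(f"{b.source_id}: no key at level {level}")
        keys.add(b.keys[level])
    return KeyedSet(label, level, keys, original_count)


def unique_stats(
    bundles: Sequence[IdentifierBundle],
    level: SensitivityLevel,
    original_count: int,
) -> tuple[int, float]:
    """Distinct-key count and its percentage of the original record count.

    The percentage is truncated (not rounded) to one decimal place.
    """
    if original_count < 1:
        raise ValueError("original_count must be >= 1")
    ks = keyed_set("", bundles, level, original_count)
    n = len(ks.keys)
    return n, unique_percentage(n, original_count)


def unique_percentage(unique_count: int, original_count: int) -> float:
    """Percent of the original record count, truncated to one decimal."""
    if original_count < 1:
        raise ValueError("original_count must be >= 1")
    return math.floor(1000.0 * unique_count / original_count) / 10.0


def overlap_matrix(sets: Sequence[KeyedSet]) -> pd.DataFrame:
    """Symmetric pairwise-intersection matrix; diagonal = unique counts."""
    _require_same_level(sets)
    labels = [s.label for s in sets]
    mat = np.zeros((len(sets), len(sets)), dtype=int)
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            mat[i, j] = len(a.keys & b.keys) if i != j else len(a.keys)
    return pd.DataFrame(mat, index=labels, columns=labels)


def coverage(overlap: int, uniques: int) -> int:
    """Percent of a set covered by an overlap, nearest integer."""
    if uniques <= 0:
        raise ValueError("uniques must be positive")
    return round(100.0 * overlap / uniques)


def venn(sets: Sequence[KeyedSet]) -> VennPartition:
    """Exact exclusive-cell partition for 2-4 keyed sets."""
    if not 2 <= len(sets) <= 4:
        raise ValueError("venn requires between 2 and 4 sets")
    _require_same_level(sets)
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("set labels must be distinct")
    part = VennPartition(labels=labels)
    union = set().union(*(s.keys for s in sets))
    members: dict[frozenset, set[str]] = {}
    for key in union:
        mask = frozenset(s.label for s in sets if key in s.keys)
        members.setdefault(mask, set()).add(key)
    part.cells = {m: (len(ks), ks) for m, ks in members.items()}
    return part


def release_diff(
    old: Sequence[IdentifierBundle],
    new: Sequence[IdentifierBundle],
    sensitive_level: SensitivityLevel = SensitivityLevel.SENSITIVE,
) -> ReleaseDiff:
    """Between-release maintained/removed/added counts per level.

    ``skeleton_links`` counts skeletons present in both releases whose
    sensitive-level keys share nothing — records whose basic connectivity
    persisted while the drawing changed (stereo added, tautomer re-drawn):
    the curation-improvement signal only visible at skeleton level.
    """
    levels = {
        sensitive_level.value: sensitive_level,
        SensitivityLevel.SKELETON.value: SensitivityLevel.SKELETON,
    }
    maintained, removed, added = {}, {}, {}
    for name, level in levels.items():
        old_keys = {b.keys[level] for b in old}
        new_keys = {b.keys[level] for b in new}
        maintained[name] = len(old_keys & new_keys)
        removed[name] = len(old_keys - new_keys)
        added[name] = len(new_keys - old_keys)

    def by_skeleton(bundles: Sequence[IdentifierBundle]) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for b in bundles:
            out.setdefault(b.keys[SensitivityLevel.SKELETON], set()).add(
                b.keys[sensitive_level]
            )
        return out

    old_sk, new_sk = by_skeleton(old), by_skeleton(new)
    links = sum(
        1
        for sk in old_sk.keys() & new_sk.keys()
        if not (old_sk[sk] & new_sk[sk])
    )
    return ReleaseDiff(maintained, removed, added, links)


def category_profile(
    keyed: KeyedSet, categories: Mapping[str, set[str]]
) -> dict[str, float]:
    """Per category, the percentage of the set carrying that label.

    ``categories`` maps key -> set of category labels and may be partial;
    keys missing from it belong to no category.
    """
    if not keyed.keys:
        raise ValueError("category_profile requires a non-empty set")
    tallies: dict[str, int] = {}
    for key in keyed.keys:
        for cat in categories.get(key, ()):  # missing => no category
            tallies[cat] = tallies.get(cat, 0) + 1
    size = len(keyed.keys)
    return {cat: 100.0 * n / size for cat, n in sorted(tallies.items())}


def export_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def export_partition_tsv(part: VennPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sources\tcount\n")
        for mask, (count, _) in sorted(
            part.cells.items(), key=lambda kv: sorted(kv[0])
        ):
            fh.write(";".join(sorted(mask)) + f"\t{count}\n")


def _require_same_level(sets: Sequence[KeyedSet]) -> None:
    levels = {str(s.level) for s in sets}
    if len(levels) > 1:
        raise ValueError(f"sets keyed at mixed levels: {sorted(levels)}")
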
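"""Stereochemistry-quality statistics for record collections.

Potential tetrahedral centres are atoms with four graph-distinct substituents
(distinctness judged by canonical symmetry classes, implicit H counting as
one substituent — no CIP rules).  Stereogenic double bonds are non-ring
double bonds with two distinct substituents at each end.  "Specified" means
a wedge originates at the atom, or the cis/trans geometry is derivable from
the 2D drawing and the bond is not flagged "either".

Collections are summarized into the six-way classification used for
structure-quality comparisons: records with no atom stereocentres / all
specified / at least one unspecified, and the same triple for double bonds,
each a percentage of a caller-supplied original record count.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .canonical import symmetry_classes
from .records import MoleculeRecord, Wedge

_H_TOKEN = -1  # substituent token for an implicit hydrogen


@dataclass
class StereoProfile:
    source_id: str
    atom_centers_total: int
    atom_centers_specified: int
    bond_centers_total: int
    bond_centers_specified: int


@dataclass
class StereoSummary:
    n_records: int
    original_count: int
    no_atom_stereo: int
    full_atom_spec: int
    unspec_atom: int
    no_bond_stereo: int
    full_bond_spec: int
    unspec_bond: int

    def percentages(self) -> dict[str, float]:
        """Percent of the original record count, rounded to one decimal."""
        denom = self.original_count
        fields = (
            "no_atom_stereo",
            "full_atom_spec",
            "unspec_atom",
            "no_bond_stereo",
            "full_bond_spec",
            "unspec_bond",
        )
        return {f: round(100.0 * getattr(self, f) / denom, 1) for f in fields}


def find_atom_stereocenters(
    record: MoleculeRecord,
) -> list[tuple[int, bool]]:
    """Potential tetrahedral centres with their specified flag."""
    classes = symmetry_classes(record)
    adj = record.neighbors()
    centers = []
    for i, atom in enumerate(record.atoms):
        if len(adj[i]) + atom.h_count != 4 or atom.h_count > 1:
            continue
        if any(record.bonds[bi].order != 1 for _, bi in adj[i]):
            continue
        subs = [classes[j] for j, _ in adj[i]]
        if atom.h_count:
            subs.append(_H_TOKEN)
        if len(set(subs)) != 4:
            continue
        specified = any(
            record.bonds[bi].wedge in (Wedge.UP, Wedge.DOWN)
            and record.bonds[bi].a1 == i
            for _, bi in adj[i]
        )
        centers.append((i, specified))
    return centers


def find_bond_stereocenters(
    record: MoleculeRecord,
) -> list[tuple[int, bool]]:
    """Stereogenic double bonds (non-ring) with their specified flag."""
    classes = symmetry_classes(record)
    adj = record.neighbors()
    g = record.graph()
    bridges = set()
    for u, v in nx.bridges(g):
        bridges.add(frozenset((u, v)))
    has_coords = record.has_coordinates()
    centers = []
    for bi, b in enumerate(record.bonds):
        if b.order != 2:
            continue
        if frozenset((b.a1, b.a2)) not in bridges:
            continue  # ring double bonds excluded
        ok = True
        geometry_defined = has_coords
        for end, other in ((b.a1, b.a2), (b.a2, b.a1)):
            subs = [classes[j] for j, _ in adj[end] if j != other]
            n_h = record.atoms[end].h_count
            subs.extend([_H_TOKEN] * n_h)
            if len(subs) != 2 or subs[0] == subs[1]:
                ok = False
                break
            if geometry_defined and not _offset_from_axis(record, b, end, other, adj):
                geometry_defined = False
        if not ok:
            continue
        specified = geometry_defined and b.wedge is not Wedge.EITHER
        centers.append((bi, specified))
    return centers


def _offset_from_axis(record, bond, end, other, adj) -> bool:
    """True if some substituent of `end` lies off the double-bond axis."""
    ax = record.atoms[other].x - record.atoms[end].x
    ay = record.atoms[other].y - record.atoms[end].y
    for j, _ in adj[end]:
        if j == other:
            continue
        sx = record.atoms[j].x - record.atoms[end].x
        sy = record.atoms[j].y - record.atoms[end].y
        if abs(ax * sy - ay * sx) > 1e-6:
            return True
    return False


def stereo_profile(record: MoleculeRecord) -> StereoProfile:
    atoms = find_atom_stereocenters(record)
    bonds = find_bond_stereocenters(record)
    return StereoProfile(
        source_id=record.source_id,
        atom_centers_total=len(atoms),
        atom_centers_specified=sum(1 for _, s in atoms if s),
        bond_centers_total=len(bonds),
        bond_centers_specified=sum(1 for _, s in bonds if s),
    )


def summarize_stereo(
    records: Sequence[MoleculeRecord], original_count: int
) -> StereoSummary:
    """Classify every record into exactly one atom- and one bond-stereo class."""
    if original_count <= 0:
        raise ValueError("original_count must be positive")
    if original_count < len(records):
        raise ValueError("original_count smaller than the record list")
    counts = dict.fromkeys(
        (
            "no_atom_stereo",
            "full_atom_spec",
            "unspec_atom",
            "no_bond_stereo",
            "full_bond_spec",
            "unspec_bond",
        ),
        0,
    )
    for rec in records:
        p = stereo_profile(rec)
        if p.atom_centers_total == 0:
            counts["no_atom_stereo"] += 1
        elif p.atom_centers_specified == p.atom_centers_total:
            counts["full_atom_spec"] += 1
        else:
            counts["unspec_atom"] += 1
        if p.bond_centers_total == 0:
            counts["no_bond_stereo"] += 1
        elif p.bond_centers_specified == p.bond_centers_total:
            counts["full_bond_spec"] += 1
        else:
            counts["unspec_bond"] += 1
    return StereoSummary(
        n_records=len(records), original_count=original_count, **counts
    )


def export_stereo_table(
    summaries: dict[str, StereoSummary], path: str | Path
) -> None:
    """TSV mirroring the six-column stereo-quality layout."""
    cols = (
        "no_atom_stereo",
        "full_atom_spec",
        "unspec_atom",
        "no_bond_stereo",
        "full_bond_spec",
        "unspec_bond",
    )
    with open(path, "w") as fh:
        fh.write("collection\t" + "\t".join(cols) + "\n")
        for label, s in summaries.items():
            pct = s.percentages()
            cells = [f"{getattr(s, c)} ({pct[c]:.1f})" for c in cols]
            fh.write(label + "\t" + "\t".join(cells) + "\n")
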
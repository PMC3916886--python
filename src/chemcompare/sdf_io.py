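"""Reading and writing SD files (MDL V2000).

Records are delimited by ``$$$$``.  Every record block is accounted for:
blocks that fail to parse (malformed counts line, bond referencing a missing
atom, V3000 connection tables, un-kekulizable aromatic systems) are counted
and logged in a :class:`ParseReport` with their ordinal, never silently
dropped.  Aromatic (order 4) bonds are kekulized on read so the internal
model only carries orders 1-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .records import Atom, Bond, MoleculeRecord, Wedge

_CHARGE_FIELD = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_CHARGE_FIELD_INV = {v: k for k, v in _CHARGE_FIELD.items()}
_WEDGE_IN = {0: Wedge.NONE, 1: Wedge.UP, 6: Wedge.DOWN, 4: Wedge.EITHER}
_WEDGE_OUT = {Wedge.NONE: 0, Wedge.UP: 1, Wedge.DOWN: 6, Wedge.EITHER: 4}


@dataclass
class ParseReport:
    records_read: int = 0
    records_failed: int = 0
    failure_reasons: list[tuple[int, str]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ordinal\treason\n")
            for ordinal, reason in self.failure_reasons:
                fh.write(f"{ordinal}\t{reason}\n")


class RecordParseError(ValueError):
    pass


def read_sdf(
    path: str | Path, id_field: str = "title"
) -> tuple[list[MoleculeRecord], ParseReport]:
    """Parse an SD file into MoleculeRecords plus a failure report.

    ``id_field`` names the SD data field holding the source record ID;
    ``"title"`` (or a missing/empty field) falls back to the molfile title
    line.  Duplicate source IDs raise a warning but both records are kept —
    deduplication is the identity layer's job.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    blocks = _split_blocks(text)
    records: list[MoleculeRecord] = []
    report = ParseReport()
    seen_ids: set[str] = set()
    for ordinal, block in enumerate(blocks, start=1):
        try:
            rec = _parse_block(block, id_field)
        except RecordParseError as exc:
            report.records_failed += 1
            report.failure_reasons.append((ordinal, str(exc)))
            continue
        if rec.source_id in seen_ids:
            warnings.warn(
                f"duplicate source_id {rec.source_id!r} (record {ordinal})",
                stacklevel=2,
            )
        seen_ids.add(rec.source_id)
        records.append(rec)
        report.records_read += 1
    return records, report


def _split_blocks(text: str) -> list[list[str]]:
    lines = text.split("\n")
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in lines:
        if line.strip() == "$$$$":
            blocks.append(current)
            current = []
        else:
            current.append(line)
    # trailing content without terminator is ignored if blank
    if any(line.strip() for line in current):
        blocks.append(current)
    return blocks


def _parse_block(lines: list[str], id_field: str) -> MoleculeRecord:
    if len(lines) < 4:
        raise RecordParseError("truncated record block")
    title = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise RecordParseError("unsupported version")
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise RecordParseError("malformed counts line") from None
    if n_atoms < 0 or n_bonds < 0:
        raise RecordParseError("malformed counts line")

    atom_lines = lines[4 : 4 + n_atoms]
    bond_lines = lines[4 + n_atoms : 4 + n_atoms + n_bonds]
    if len(atom_lines) < n_atoms or len(bond_lines) < n_bonds:
        raise RecordParseError("truncated atom/bond block")

    atoms: list[Atom] = []
    for ln in atom_lines:
        try:
            x = float(ln[0:10])
            y = float(ln[10:20])
            element = ln[31:34].strip()
            charge_code = int(ln[36:39]) if ln[36:39].strip() else 0
        except (ValueError, IndexError):
            raise RecordParseError("malformed atom line") from None
        if not element:
            raise RecordParseError("malformed atom line")
        atoms.append(
            Atom(element, _CHARGE_FIELD.get(charge_code, 0), None, 0, x, y)
        )

    bonds: list[Bond] = []
    aromatic: list[int] = []
    for ln in bond_lines:
        try:
            a1 = int(ln[0:3]) - 1
            a2 = int(ln[3:6]) - 1
            order = int(ln[6:9])
            stereo = int(ln[9:12]) if len(ln) >= 12 and ln[9:12].strip() else 0
        except (ValueError, IndexError):
            raise RecordParseError("malformed bond line") from None
        if not (0 <= a1 < n_atoms and 0 <= a2 < n_atoms) or a1 == a2:
            raise RecordParseError("bond references nonexistent atom")
        wedge = _WEDGE_IN.get(stereo, Wedge.NONE)
        if order == 2 and stereo == 3:
            wedge = Wedge.EITHER
        if order == 4:
            aromatic.append(len(bonds))
            order = 1
        elif order not in (1, 2, 3):
            raise RecordParseError(f"unsupported bond order {order}")
        bonds.append(Bond(a1, a2, order, wedge))

    # property block: M  CHG / M  ISO supersede atom-line fields
    chg_seen = False
    data: dict[str, str] = {}
    i = 4 + n_atoms + n_bonds
    while i < len(lines):
        line = lines[i]
        if line.startswith("M  CHG"):
            if not chg_seen:
                for a in atoms:
                    a.charge = 0
                chg_seen = True
            for idx, val in _parse_property_pairs(line):
                atoms[idx].charge = val
        elif line.startswith("M  ISO"):
            for idx, val in _parse_property_pairs(line):
                atoms[idx].isotope = val
        elif line.startswith("M  END"):
            i += 1
            break
        i += 1

    # SD data fields
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            tag = line[line.find("<") + 1 : line.rfind(">")]
            value_lines = []
            i += 1
            while i < len(lines) and lines[i].strip():
                value_lines.append(lines[i])
                i += 1
            data[tag] = "\n".join(value_lines).strip()
        i += 1

    source_id = title
    if id_field != "title" and data.get(id_field, "").strip():
        source_id = data[id_field].strip()

    rec = MoleculeRecord(source_id=source_id, atoms=atoms, bonds=bonds)
    rec.validate()
    if aromatic:
        _kekulize(rec, aromatic)
    rec.complete_hydrogens()
    return rec


def _parse_property_pairs(line: str) -> list[tuple[int, int]]:
    try:
        n = int(line[6:9])
        pairs = []
        for k in range(n):
            base = 9 + 8 * k
            idx = int(line[base : base + 4]) - 1
            val = int(line[base + 4 : base + 8])
            pairs.append((idx, val))
        return pairs
    except (ValueError, IndexError):
        raise RecordParseError("malformed property line") from None


def _kekulize(rec: MoleculeRecord, aromatic_bond_idx: list[int]) -> None:
    """Assign single/double orders to aromatic bonds by backtracking.

    Every atom touched by aromatic bonds must get exactly one aromatic double
    bond, except N/O/S atoms, which may take zero (pyrrole-type).  Failure is
    a parse error.
    """
    arom_atoms = set()
    for bi in aromatic_bond_idx:
        arom_atoms.add(rec.bonds[bi].a1)
        arom_atoms.add(rec.bonds[bi].a2)
    incident: dict[int, list[int]] = {a: [] for a in arom_atoms}
    for bi in aromatic_bond_idx:
        incident[rec.bonds[bi].a1].append(bi)
        incident[rec.bonds[bi].a2].append(bi)
    assigned: dict[int, int] = {}  # bond index -> order

    def atom_ok(a: int, final: bool) -> bool:
        orders = [assigned.get(bi) for bi in incident[a]]
        doubles = sum(1 for o in orders if o == 2)
        if doubles > 1:
            return False
        if final or None not in orders:
            if doubles == 0 and rec.atoms[a].element not in ("N", "O", "S"):
                return False
        return True

    order_of_bonds = sorted(aromatic_bond_idx)

    def backtrack(k: int) -> bool:
        if k == len(order_of_bonds):
            return all(atom_ok(a, True) for a in arom_atoms)
        bi = order_of_bonds[k]
        b = rec.bonds[bi]
        for order in (2, 1):
            assigned[bi] = order
            if atom_ok(b.a1, False) and atom_ok(b.a2, False):
                if backtrack(k + 1):
                    return True
            del assigned[bi]
        return False

    if not backtrack(0):
        raise RecordParseError("cannot kekulize aromatic system")
    for bi, order in assigned.items():
        rec.bonds[bi].order = order


def write_sdf(
    records: list[MoleculeRecord],
    path: str | Path,
    id_field: Optional[str] = None,
) -> None:
    """Write records as an SD file; round-trips graphs and source IDs.

    The source ID goes on the molfile title line and, when ``id_field`` is
    given, additionally into that SD data field.
    """
    with open(path, "w") as fh:
        for rec in records:
            fh.write(record_to_block(rec, id_field))


def record_to_block(rec: MoleculeRecord, id_field: Optional[str] = None) -> str:
    lines = [rec.source_id, "  chemcompare", ""]
    lines.append(
        f"{len(rec.atoms):3d}{len(rec.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for a in rec.atoms:
        lines.append(
            f"{a.x:10.4f}{a.y:10.4f}{0.0:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for b in rec.bonds:
        stereo = _WEDGE_OUT[b.wedge]
        if b.order == 2 and b.wedge is Wedge.EITHER:
            stereo = 3
        lines.append(f"{b.a1 + 1:3d}{b.a2 + 1:3d}{b.order:3d}{stereo:3d}")
    charged = [(i, a.charge) for i, a in enumerate(rec.atoms) if a.charge]
    for chunk_start in range(0, len(charged), 8):
        chunk = charged[chunk_start : chunk_start + 8]
        lines.append(
            "M  CHG" + f"{len(chunk):3d}"
            + "".join(f"{i + 1:4d}{c:4d}" for i, c in chunk)
        )
    isotopic = [(i, a.isotope) for i, a in enumerate(rec.atoms) if a.isotope]
    for chunk_start in range(0, len(isotopic), 8):
        chunk = isotopic[chunk_start : chunk_start + 8]
        lines.append(
            "M  ISO" + f"{len(chunk):3d}"
            + "".join(f"{i + 1:4d}{m:4d}" for i, m in chunk)
        )
    lines.append("M  END")
    if id_field and id_field != "title":
        lines.append(f"> <{id_field}>")
        lines.append(rec.source_id)
        lines.append("")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"
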
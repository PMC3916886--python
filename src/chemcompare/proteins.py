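"""UniProt-ID set comparison.

Accession lists are plain text, one ID per line; annotations (species,
review status, GO top-level molecular-function categories) come from a
required TSV table — never fetched live.  A high TrEMBL fraction among
target-species mappings signals curation lapses, since expert review is
essentially complete for plausible drug targets, so the target-species
unreviewed count is reported explicitly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .sets import KeyedSet, VennPartition, venn

logger = logging.getLogger(__name__)

# UniProt accession grammar (6- and 10-character forms)
ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


@dataclass
class ProteinEntry:
    accession: str
    species: str = "unknown"
    reviewed: bool = False
    go_categories: set[str] = field(default_factory=set)


@dataclass
class SpeciesSplit:
    total: int
    target_species: str
    target_count: int
    species_counts: dict[str, int]
    largest_non_target: Optional[tuple[str, int]]
    sp_count: int
    tr_count: int
    target_unreviewed: int

    @property
    def n_species(self) -> int:
        return len(self.species_counts)

    @property
    def sp_tr_ratio(self) -> str:
        return f"{self.sp_count}:{self.tr_count}"


def load_ids(path: str | Path) -> set[str]:
    """De-duplicated accession set; malformed lines are logged and skipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    accessions: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        token = line.strip()
        if not token:
            continue
        if not ACCESSION_RE.match(token):
            logger.warning("%s:%d: not a UniProt accession: %r", path, lineno, token)
            continue
        accessions.add(token)
    return accessions


def load_annotations(path: str | Path) -> dict[str, ProteinEntry]:
    """Annotation TSV: accession, species, reviewed in {SP, TR},
    semicolon-joined GO top-level labels (may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = {}
    for row in df.itertuples(index=False):
        go = {g for g in str(row.go_categories).split(";") if g}
        entries[row.accession] = ProteinEntry(
            accession=row.accession,
            species=row.species or "unknown",
            reviewed=row.reviewed == "SP",
            go_categories=go,
        )
    return entries


def annotate(
    accessions: Iterable[str], annotations: Mapping[str, ProteinEntry]
) -> list[ProteinEntry]:
    """Join annotations onto an accession set.

    Missing accessions become species "unknown" and count as unreviewed;
    each is logged.
    """
    out = []
    for acc in sorted(accessions):
        entry = annotations.get(acc)
        if entry is None:
            logger.warning("no annotation for %s", acc)
            entry = ProteinEntry(accession=acc)
        out.append(entry)
    return out


def species_split(
    entries: Sequence[ProteinEntry], target_species: str = "Human"
) -> SpeciesSplit:
    species_counts: dict[str, int] = {}
    sp = tr = target_tr = 0
    for e in entries:
        species_counts[e.species] = species_counts.get(e.species, 0) + 1
        if e.reviewed:
            sp += 1
        else:
            tr += 1
            if e.species == target_species:
                target_tr += 1
    non_target = [
        (count, name)
        for name, count in species_counts.items()
        if name != target_species
    ]
    largest = None
    if non_target:
        count, name = max(non_target, key=lambda t: (t[0], t[1]))
        largest = (name, count)
    return SpeciesSplit(
        total=len(entries),
        target_species=target_species,
        target_count=species_counts.get(target_species, 0),
        species_counts=species_counts,
        largest_non_target=largest,
        sp_count=sp,
        tr_count=tr,
        target_unreviewed=target_tr,
    )


def consensus(named_sets: Mapping[str, set[str]]) -> VennPartition:
    """n-way (2-4) Venn partition of accession sets."""
    keyed = [
        KeyedSet(label, "accession", set(accs), max(len(accs), 1))
        for label, accs in named_sets.items()
    ]
    return venn(keyed)


def go_distribution(
    entries: Sequence[ProteinEntry],
) -> tuple[dict[str, tuple[int, float]], int]:
    """Top-level GO molecular-function distribution.

    Each protein contributes once per assigned category (GO terms fork, so
    multi-category proteins are counted in every category they carry);
    fractions are over total assignments and sum to 1.  Returns
    (distribution, number of unannotated proteins).
    """
    tallies: dict[str, int] = {}
    unannotated = 0
    for e in entries:
        if not e.go_categories:
            unannotated += 1
            continue
        for cat in e.go_categories:
            tallies[cat] = tallies.get(cat, 0) + 1
    total = sum(tallies.values())
    if total == 0:
        logger.warning("no GO assignments in the input set")
        return {}, unannotated
    return (
        {cat: (n, n / total) for cat, n in sorted(tallies.items())},
        unannotated,
    )


def export_species_table(
    splits: Mapping[str, SpeciesSplit], path: str | Path
) -> None:
    """TSV shaped like the species/SP:TR comparison table."""
    with open(path, "w") as fh:
        fh.write(
            "source\tall\ttarget\tspecies_total\tlargest_non_target"
            "\tsp_tr\ttarget_tr_only\n"
        )
        for label, s in splits.items():
            largest = (
                f"{s.largest_non_target[0]} ({s.largest_non_target[1]})"
                if s.largest_non_target
                else ""
            )
            fh.write(
                f"{label}\t{s.total}\t{s.target_count}\t{s.n_species}"
                f"\t{largest}\t{s.sp_tr_ratio}\t{s.target_unreviewed}\n"
            )


def export_go_table(
    dists: Mapping[str, tuple[dict[str, tuple[int, float]], int]],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("source\tcategory\tcount\tfraction\n")
        for label, (dist, unannotated) in dists.items():
            for cat, (n, frac) in dist.items():
                fh.write(f"{label}\t{cat}\t{n}\t{frac:.4f}\n")
            fh.write(f"{label}\t(unannotated)\t{unannotated}\t\n")
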
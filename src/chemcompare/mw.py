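"""Molecular weight computation and distribution statistics.

MW is the sum of abundance-averaged standard atomic weights (RDKit periodic
table) over all atoms including implicit hydrogens; isotope-labelled atoms
contribute their nuclide mass instead.  Profiles are computed on the
tautomer-invariant-level normalized parent fragment by default (salt-free),
with a flag to keep counterions.

Quartiles use inclusive linear interpolation; the standard deviation is the
population SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .records import MoleculeRecord

_PT = Chem.GetPeriodicTable()


@dataclass
class MWStats:
    n: int
    mean: float
    std_dev: float
    q1: float
    median: float
    q3: float


def molecular_weight(record: MoleculeRecord) -> float:
    """Sum of standard atomic weights (Da), implicit H included."""
    total = 0.0
    h_mass = _PT.GetAtomicWeight("H")
    for a in record.atoms:
        if a.isotope:
            mass = _PT.GetMassForIsotope(a.element, a.isotope)
            if mass == 0.0:
                raise ValueError(
                    f"{record.source_id}: unknown nuclide {a.element}-{a.isotope}"
                )
        else:
            mass = _PT.GetAtomicWeight(a.element)
            if mass == 0.0:
                raise ValueError(f"{record.source_id}: unknown element {a.element}")
        total += mass + a.h_count * h_mass
    return total


def profile_weights(
    records: Sequence[MoleculeRecord], include_counterions: bool = False
) -> list[float]:
    """MW per record after base normalization (parent fragment by default).

    Rejected records are skipped.
    """
    from .normalize import normalize_base, select_parent

    weights = []
    for rec in records:
        base = normalize_base(rec)
        if base.rejected or not base.atoms:
            continue
        if not include_counterions:
            base = select_parent(base)
        weights.append(molecular_weight(base))
    return weights


def mw_stats(values: Sequence[float] | Sequence[MoleculeRecord]) -> MWStats:
    vals = _as_weights(values)
    if len(vals) == 0:
        raise ValueError("mw_stats requires at least one record")
    arr = np.asarray(vals, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return MWStats(
        n=len(arr),
        mean=float(arr.mean()),
        std_dev=float(arr.std(ddof=0)),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
    )


def mw_histogram(
    values: Sequence[float] | Sequence[MoleculeRecord],
    bin_width: float = 50.0,
    subset: Optional[Sequence[float] | Sequence[MoleculeRecord]] = None,
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Histogram over fixed-width bins starting at 0.

    Returns (bin_edges, counts, subset_counts); ``subset`` produces the
    exclusive-content overlay on the same bins.
    """
    vals = np.asarray(_as_weights(values), dtype=float)
    if vals.size == 0:
        raise ValueError("mw_histogram requires at least one record")
    top = float(np.ceil(vals.max() / bin_width) + 1) * bin_width
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    sub_counts = None
    if subset is not None:
        sub = np.asarray(_as_weights(subset), dtype=float)
        sub_counts, _ = np.histogram(sub, bins=edges)
    return edges, counts, sub_counts


def histogram_modes(counts: np.ndarray, edges: np.ndarray) -> list[float]:
    """Bin centres of strict local maxima of a binned distribution."""
    centres = (edges[:-1] + edges[1:]) / 2
    modes = []
    padded = np.concatenate([[0], counts, [0]])
    for i in range(len(counts)):
        if padded[i + 1] > padded[i] and padded[i + 1] >= padded[i + 2]:
            if counts[i] > 0:
                modes.append(float(centres[i]))
    return modes


def export_mw_table(
    stats: dict[str, MWStats], path: str | Path
) -> None:
    """TSV with one row per collection: mean, SD, Q1, median, Q3."""
    with open(path, "w") as fh:
        fh.write("collection\tn\tmean\tstd_dev\tq1\tmedian\tq3\n")
        for label, s in stats.items():
            fh.write(
                f"{label}\t{s.n}\t{s.mean:.1f}\t{s.std_dev:.1f}"
                f"\t{s.q1:.1f}\t{s.median:.1f}\t{s.q3:.1f}\n"
            )


def _as_weights(values) -> list[float]:
    out = []
    for v in values:
        if isinstance(v, MoleculeRecord):
            out.append(molecular_weight(v))
        else:
            out.append(float(v))
    return out
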
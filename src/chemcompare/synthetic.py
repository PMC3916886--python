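"""Synthetic database releases and protein inputs with known ground truth.

The generator emulates what a curated compound collection looks like to the
comparison pipeline: controlled redundancy inside one release (exact
duplicates, salt forms, charge states, isotope labels, tautomer drawings,
stereo variants) and controlled curation events between two releases
(records kept, removed, re-drawn with stereo or as another tautomer, plus
newly added structures).  Every emitted record's identity class at every
sensitivity level is known by construction, so unique counts, release-diff
triples, skeleton links, stereo classes, Venn cells and MW statistics can be
asserted exactly.

The scaffold pool is hand-curated: a family of 4-substituted amino ketones
``X-CH(CH3)-(CH2)1+L-C(=O)-CH2-NH2`` (one tetrahedral stereocentre, drawn
with a wedge; keto/enol-capable; protonatable amine) and an achiral family
``CH3-(CH2)k-C(=O)-CH2-NH2``.  Random choice only selects and decorates from
this pool, so stereo/tautomer capability is provable, never accidental.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .records import Atom, Bond, MoleculeRecord, Wedge
from .normalize import _shift_sites, _apply_shift  # closed transform set
from .sdf_io import write_sdf
from .sets import KeyedSet

VARIANT_TYPES = (
    "exact_duplicate",
    "salt",
    "charge",
    "isotope",
    "tautomer",
    "stereo_invert",
    "stereo_strip",
)

_CHIRAL_X = ("F", "Cl", "Br", "I", "O", "N", "S")


class SpecError(ValueError):
    """A library plan that cannot be realised (never silent)."""


# ---------------------------------------------------------------------------
# scaffold pool
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scaffold:
    pool_id: int
    name: str
    chiral: bool

    def build(self, with_wedge: bool) -> MoleculeRecord:
        if self.chiral:
            x, extra = _CHIRAL_PARAMS[self.pool_id]
            rec = _build_chiral(x, extra, with_wedge)
        else:
            if with_wedge:
                raise SpecError(f"{self.name}: no prochiral site to draw")
            k = _ACHIRAL_PARAMS[self.pool_id]
            rec = _build_achiral(k)
        rec.source_id = self.name
        return rec


def _zigzag(n: int) -> list[tuple[float, float]]:
    return [(0.9 * i, 0.45 * (i % 2)) for i in range(n)]


def _build_chiral(x_element: str, extra_ch2: int, with_wedge: bool) -> MoleculeRecord:
    """X-CH(CH3)-(CH2)1+extra-C(=O)-CH2-NH2 with the wedge on C-X."""
    chain_len = 5 + extra_ch2  # C1..C4 backbone plus inserted CH2 and C5
    coords = _zigzag(chain_len + 3)
    atoms = []
    bonds = []
    # backbone: C1(methyl) C2(stereo) C3.. C(=O) C5 N
    n_backbone = 4 + extra_ch2  # C1 C2 C3 [C3b]* Ccarbonyl
    for i in range(n_backbone):
        atoms.append(Atom("C", x=coords[i][0], y=coords[i][1]))
        if i:
            bonds.append(Bond(i - 1, i))
    carbonyl = n_backbone - 1
    o_idx = len(atoms)
    atoms.append(Atom("O", x=coords[carbonyl][0], y=coords[carbonyl][1] + 1.0))
    bonds.append(Bond(carbonyl, o_idx, 2))
    c5 = len(atoms)
    atoms.append(Atom("C", x=coords[n_backbone][0], y=coords[n_backbone][1]))
    bonds.append(Bond(carbonyl, c5))
    n_idx = len(atoms)
    atoms.append(Atom("N", x=coords[n_backbone + 1][0], y=coords[n_backbone + 1][1]))
    bonds.append(Bond(c5, n_idx))
    x_idx = len(atoms)
    atoms.append(Atom(x_element, x=coords[1][0], y=coords[1][1] - 1.0))
    bonds.append(
        Bond(1, x_idx, 1, Wedge.UP if with_wedge else Wedge.NONE)
    )
    rec = MoleculeRecord(source_id="", atoms=atoms, bonds=bonds)
    rec.complete_hydrogens()
    return rec


def _build_achiral(k: int) -> MoleculeRecord:
    """CH3-(CH2)k-C(=O)-CH2-NH2."""
    n_chain = k + 2  # methyl + k CH2 + carbonyl C
    coords = _zigzag(n_chain + 3)
    atoms = [Atom("C", x=coords[i][0], y=coords[i][1]) for i in range(n_chain)]
    bonds = [Bond(i - 1, i) for i in range(1, n_chain)]
    carbonyl = n_chain - 1
    o_idx = len(atoms)
    atoms.append(Atom("O", x=coords[carbonyl][0], y=coords[carbonyl][1] + 1.0))
    bonds.append(Bond(carbonyl, o_idx, 2))
    c5 = len(atoms)
    atoms.append(Atom("C", x=coords[n_chain][0], y=coords[n_chain][1]))
    bonds.append(Bond(carbonyl, c5))
    n_idx = len(atoms)
    atoms.append(Atom("N", x=coords[n_chain + 1][0], y=coords[n_chain + 1][1]))
    bonds.append(Bond(c5, n_idx))
    rec = MoleculeRecord(source_id="", atoms=atoms, bonds=bonds)
    rec.complete_hydrogens()
    return rec


_CHIRAL_PARAMS: dict[int, tuple[str, int]] = {}
_ACHIRAL_PARAMS: dict[int, int] = {}
SCAFFOLD_POOL: list[Scaffold] = []
for _x in _CHIRAL_X:
    for _extra in (0, 1):
        pid = len(SCAFFOLD_POOL)
        _CHIRAL_PARAMS[pid] = (_x, _extra)
        SCAFFOLD_POOL.append(Scaffold(pid, f"SCF{pid:02d}", True))
for _k in (1, 2, 3, 4, 5, 6):
    pid = len(SCAFFOLD_POOL)
    _ACHIRAL_PARAMS[pid] = _k
    SCAFFOLD_POOL.append(Scaffold(pid, f"SCF{pid:02d}", False))


# ---------------------------------------------------------------------------
# library specification and ground truth
# ---------------------------------------------------------------------------


@dataclass
class CurationPlan:
    """Per-record events applied when deriving release 2 from release 1."""

    remove: list[tuple[int, str]] = field(default_factory=list)  # (slot, tag)
    add_stereo: list[int] = field(default_factory=list)  # slots, flat libraries
    redraw_tautomer: list[int] = field(default_factory=list)  # slots (base record)
    new_records: int = 0


@dataclass
class LibrarySpec:
    n_scaffolds: int
    variant_plans: Optional[list[list[str]]] = None  # per slot; None = no variants
    uniform_plan: Sequence[str] = ()
    curation: CurationPlan = field(default_factory=CurationPlan)
    draw_stereo: bool = True
    scaffold_ids: Optional[list[int]] = None  # explicit pool picks
    seed: int = 0

    def plans(self) -> list[list[str]]:
        if self.variant_plans is not None:
            if len(self.variant_plans) != self.n_scaffolds:
                raise SpecError("variant_plans length != n_scaffolds")
            return [list(p) for p in self.variant_plans]
        return [list(self.uniform_plan) for _ in range(self.n_scaffolds)]


@dataclass
class GroundTruth:
    uniques_r1: dict[str, int]
    uniques_r2: dict[str, int]
    n_records_r1: int
    n_records_r2: int
    diff: dict[str, dict[str, int]]  # level -> maintained/removed/added
    skeleton_links: int
    stereo_r1: dict[str, int]
    stereo_r2: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def generate_library(
    spec: LibrarySpec,
) -> tuple[list[MoleculeRecord], list[MoleculeRecord], GroundTruth]:
    """Two releases plus exact expectations for every pipeline stage."""
    rng = np.random.default_rng(spec.seed)
    plans = spec.plans()
    for plan in plans:
        for v in plan:
            if v not in VARIANT_TYPES:
                raise SpecError(f"unknown variant type {v!r}")

    slots = _assign_scaffolds(spec, plans, rng)
    n_new = spec.curation.new_records
    used = {s.pool_id for s in slots}
    unused = [s for s in SCAFFOLD_POOL if s.pool_id not in used]
    if n_new > len(unused):
        raise SpecError("curation plan demands more new scaffolds than the pool holds")
    new_scaffolds = unused[:n_new]

    _validate_curation(spec, plans)

    # ---- release 1 ----------------------------------------------------
    release1: list[MoleculeRecord] = []
    signatures1: list[tuple[int, str]] = []  # (slot, form tag)
    for slot, (scaffold, plan) in enumerate(zip(slots, plans)):
        base = scaffold.build(spec.draw_stereo and scaffold.chiral)
        base.source_id = f"SYN{slot:03d}"
        release1.append(base)
        signatures1.append((slot, "base"))
        for tag in sorted(set(plan)):
            var = _make_variant(base, tag, scaffold, spec, rng)
            var.source_id = f"SYN{slot:03d}-{tag}"
            release1.append(var)
            signatures1.append((slot, "base" if tag == "exact_duplicate" else tag))

    # ---- release 2 ----------------------------------------------------
    removed = set(spec.curation.remove)
    stereo_slots = set(spec.curation.add_stereo)
    tauto_slots = set(spec.curation.redraw_tautomer)
    release2: list[MoleculeRecord] = []
    signatures2: list[tuple[int, str]] = []
    for rec, (slot, tag) in zip(release1, signatures1):
        raw_tag = rec.source_id.split("-", 1)[1] if "-" in rec.source_id else "base"
        if (slot, raw_tag) in removed:
            continue
        if raw_tag == "base" and slot in stereo_slots:
            new = slots[slot].build(True)
            new.source_id = rec.source_id
            release2.append(new)
            signatures2.append((slot, "stereoed"))
        elif raw_tag == "base" and slot in tauto_slots:
            new = _tautomer_drawing(rec)
            release2.append(new)
            signatures2.append((slot, "tautomer"))
        else:
            release2.append(rec.copy())
            signatures2.append((slot, tag))
    for extra, scaffold in enumerate(new_scaffolds):
        slot = len(slots) + extra
        rec = scaffold.build(spec.draw_stereo and scaffold.chiral)
        rec.source_id = f"SYN{slot:03d}"
        release2.append(rec)
        signatures2.append((slot, "base"))

    gt = _ground_truth(
        spec, slots, new_scaffolds, signatures1, signatures2
    )
    return release1, release2, gt


def generate_library_files(
    spec: LibrarySpec, outdir: str | Path
) -> tuple[Path, Path, GroundTruth]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r1, r2, gt = generate_library(spec)
    p1, p2 = outdir / "release1.sdf", outdir / "release2.sdf"
    write_sdf(r1, p1)
    write_sdf(r2, p2)
    gt.to_json(outdir / "ground_truth.json")
    return p1, p2, gt


def _assign_scaffolds(
    spec: LibrarySpec, plans: list[list[str]], rng: np.random.Generator
) -> list[Scaffold]:
    if spec.scaffold_ids is not None:
        if len(spec.scaffold_ids) != spec.n_scaffolds:
            raise SpecError("scaffold_ids length != n_scaffolds")
        slots = [SCAFFOLD_POOL[i] for i in spec.scaffold_ids]
        for scaffold, plan in zip(slots, plans):
            if _needs_stereo(plan, spec) and not scaffold.chiral:
                raise SpecError(
                    f"{scaffold.name}: plan demands a stereo variant but the "
                    "scaffold has no prochiral site"
                )
        return slots
    chiral = [s for s in SCAFFOLD_POOL if s.chiral]
    achiral = [s for s in SCAFFOLD_POOL if not s.chiral]
    rng.shuffle(chiral)
    rng.shuffle(achiral)
    slots: list[Optional[Scaffold]] = [None] * spec.n_scaffolds
    for i, plan in enumerate(plans):
        if _needs_stereo(plan, spec):
            if not chiral:
                raise SpecError(
                    "plan demands a stereo variant but no stereo-capable "
                    "scaffold is left in the pool"
                )
            slots[i] = chiral.pop()
    rest = chiral + achiral
    for i in range(spec.n_scaffolds):
        if slots[i] is None:
            if not rest:
                raise SpecError("scaffold pool exhausted")
            slots[i] = rest.pop()
    return slots  # type: ignore[return-value]


def _needs_stereo(plan: Sequence[str], spec: LibrarySpec) -> bool:
    return bool({"stereo_invert", "stereo_strip"} & set(plan))


def _validate_curation(spec: LibrarySpec, plans: list[list[str]]) -> None:
    cur = spec.curation
    for slot in cur.add_stereo:
        if spec.draw_stereo:
            raise SpecError(
                "add_stereo curation requires a flat-drawn library "
                "(draw_stereo=False)"
            )
        if slot >= spec.n_scaffolds:
            raise SpecError(f"add_stereo slot {slot} out of range")
        if "exact_duplicate" in plans[slot]:
            raise SpecError(
                "add_stereo on a scaffold with exact duplicates would leave "
                "the old drawing alive; forbidden"
            )
    for slot in cur.redraw_tautomer:
        if slot >= spec.n_scaffolds:
            raise SpecError(f"redraw_tautomer slot {slot} out of range")
        if {"tautomer", "exact_duplicate"} & set(plans[slot]):
            raise SpecError(
                "redraw_tautomer collides with a tautomer/duplicate variant "
                "of the same scaffold"
            )
    if set(cur.add_stereo) & set(cur.redraw_tautomer):
        raise SpecError("conflicting curation events on one record")
    for slot, tag in cur.remove:
        if slot >= spec.n_scaffolds:
            raise SpecError(f"remove slot {slot} out of range")
        if tag != "base" and tag not in plans[slot]:
            raise SpecError(f"remove targets missing record ({slot}, {tag})")
        if tag == "base" and (slot in cur.add_stereo or slot in cur.redraw_tautomer):
            raise SpecError("cannot both remove and re-draw a record")


def _make_variant(
    base: MoleculeRecord,
    tag: str,
    scaffold: Scaffold,
    spec: LibrarySpec,
    rng: np.random.Generator,
) -> MoleculeRecord:
    from .records import permuted

    if tag == "exact_duplicate":
        order = list(rng.permutation(len(base.atoms)))
        return permuted(base, order)
    if tag == "salt":
        rec = base.copy()
        rec.atoms.append(Atom("O", h_count=2, x=-2.0, y=-2.0))
        return rec
    if tag == "charge":
        rec = base.copy()
        n_idx = _amine_nitrogen(rec)
        rec.atoms[n_idx].charge = 1
        rec.atoms[n_idx].h_count += 1
        return rec
    if tag == "isotope":
        rec = base.copy()
        rec.atoms[0].isotope = 13  # the methyl carbon
        return rec
    if tag == "tautomer":
        return _tautomer_drawing(base)
    if tag in ("stereo_invert", "stereo_strip"):
        if not scaffold.chiral or not spec.draw_stereo:
            raise SpecError(
                f"{scaffold.name}: {tag} demands a drawn stereocentre"
            )
        rec = base.copy()
        for b in rec.bonds:
            if b.wedge is Wedge.UP:
                b.wedge = Wedge.DOWN if tag == "stereo_invert" else Wedge.NONE
        return rec
    raise SpecError(f"unknown variant type {tag!r}")


def _amine_nitrogen(rec: MoleculeRecord) -> int:
    adj = rec.neighbors()
    for i, a in enumerate(rec.atoms):
        if a.element == "N" and len(adj[i]) == 1 and a.h_count == 2:
            return i
    raise SpecError("no terminal amine to protonate")


def _tautomer_drawing(rec: MoleculeRecord) -> MoleculeRecord:
    """One deterministic 1,3-shift step: a different drawing, same orbit."""
    sites = _shift_sites(rec)
    if not sites:
        raise SpecError(f"{rec.source_id}: no tautomer-capable site")
    site = min(sites)
    out = _apply_shift(rec, site)
    out.source_id = rec.source_id
    return out


def _ground_truth(
    spec: LibrarySpec,
    slots: list[Scaffold],
    new_scaffolds: list[Scaffold],
    sig1: list[tuple[int, str]],
    sig2: list[tuple[int, str]],
) -> GroundTruth:
    def fold_ficus(tag: str) -> str:
        return "base" if tag == "tautomer" else tag

    sens1, sens2 = set(sig1), set(sig2)
    ficus1 = {(s, fold_ficus(t)) for s, t in sig1}
    ficus2 = {(s, fold_ficus(t)) for s, t in sig2}
    # at ficus level a "stereoed" re-drawing is still distinct from flat base
    skel1 = {s for s, _ in sig1}
    skel2 = {s for s, _ in sig2}

    diff = {}
    for name, old, new in (
        ("ficts", sens1, sens2),
        ("uuuuu", skel1, skel2),
    ):
        diff[name] = {
            "maintained": len(old & new),
            "removed": len(old - new),
            "added": len(new - old),
        }
    links = 0
    for sk in skel1 & skel2:
        old_forms = {t for s, t in sens1 if s == sk}
        new_forms = {t for s, t in sens2 if s == sk}
        if not (old_forms & new_forms):
            links += 1

    all_scaffolds = {s.pool_id: s for s in slots}
    for extra, sc in enumerate(new_scaffolds):
        all_scaffolds[sc.pool_id] = sc
    slot_map = {i: sc for i, sc in enumerate(slots)}
    for extra, sc in enumerate(new_scaffolds):
        slot_map[len(slots) + extra] = sc

    def stereo_counts(sig: list[tuple[int, str]]) -> dict[str, int]:
        # enol drawings carry one stereogenic C=C whose geometry the 2D
        # layout defines, so tautomer records land in "full bond spec"
        n_enol = sum(1 for _, tag in sig if tag == "tautomer")
        counts = {
            "no_atom_stereo": 0,
            "full_atom_spec": 0,
            "unspec_atom": 0,
            "no_bond_stereo": len(sig) - n_enol,
            "full_bond_spec": n_enol,
            "unspec_bond": 0,
        }
        for slot, tag in sig:
            scaffold = slot_map[slot]
            if not scaffold.chiral:
                counts["no_atom_stereo"] += 1
            elif tag == "stereoed" or (
                spec.draw_stereo and tag != "stereo_strip"
            ):
                counts["full_atom_spec"] += 1
            else:
                counts["unspec_atom"] += 1
        return counts

    return GroundTruth(
        uniques_r1={
            "ficts": len(sens1),
            "ficus": len(ficus1),
            "uuuuu": len(skel1),
        },
        uniques_r2={
            "ficts": len(sens2),
            "ficus": len(ficus2),
            "uuuuu": len(skel2),
        },
        n_records_r1=len(sig1),
        n_records_r2=len(sig2),
        diff=diff,
        skeleton_links=links,
        stereo_r1=stereo_counts(sig1),
        stereo_r2=stereo_counts(sig2),
    )


# ---------------------------------------------------------------------------
# planted key sets (abstract Venn fixtures)
# ---------------------------------------------------------------------------


def plant_keyed_sets(
    labels: Sequence[str],
    cells: dict[tuple[str, ...], int],
    seed: int = 0,
) -> tuple[list[KeyedSet], dict[frozenset, int]]:
    """Random key sets realising exact exclusive Venn cell counts."""
    label_set = set(labels)
    for mask, count in cells.items():
        if not set(mask) <= label_set:
            raise SpecError(f"cell {mask} references unknown labels")
        if count < 0:
            raise SpecError("cell counts must be non-negative")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {lab: set() for lab in labels}
    truth: dict[frozenset, int] = {}
    serial = 0
    for mask, count in sorted(cells.items()):
        truth[frozenset(mask)] = count
        for _ in range(count):
            key = f"K{serial:06d}{rng.integers(0, 1 << 30):08x}"
            serial += 1
            for lab in mask:
                sets[lab].add(key)
    keyed = [
        KeyedSet(lab, "planted", sets[lab], max(1, len(sets[lab])))
        for lab in labels
    ]
    return keyed, truth


# ---------------------------------------------------------------------------
# molecular-weight regimes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogNormalComponent:
    weight: float
    median: float  # Da
    sigma: float  # log-space SD

    @property
    def mu(self) -> float:
        return math.log(self.median)

    def theory(self) -> dict[str, float]:
        mean = math.exp(self.mu + self.sigma**2 / 2)
        sd = mean * math.sqrt(math.exp(self.sigma**2) - 1)
        z = 0.6744897501960817  # Phi^-1(0.75)
        return {
            "mean": mean,
            "sd": sd,
            "q1": math.exp(self.mu - z * self.sigma),
            "median": self.median,
            "q3": math.exp(self.mu + z * self.sigma),
        }


# broad lead-like default; bimodal/tri-modal presets mimic a metabolite
# collection acquiring large-lipid clusters
LEAD_LIKE = (LogNormalComponent(1.0, 380.0, 0.45),)
BIMODAL = (
    LogNormalComponent(0.6, 350.0, 0.30),
    LogNormalComponent(0.4, 1000.0, 0.12),
)
TRIMODAL = (
    LogNormalComponent(0.5, 350.0, 0.30),
    LogNormalComponent(0.3, 1000.0, 0.10),
    LogNormalComponent(0.2, 1500.0, 0.08),
)

_CH2 = 14.02658
_H2 = 2.01588


def generate_mw_records(
    components: Sequence[LogNormalComponent],
    n: int,
    seed: int = 0,
) -> tuple[list[MoleculeRecord], np.ndarray]:
    """Hydrocarbon-chain records whose MW follows a log-normal mixture.

    Chain lengths are the nearest integer realisation of each draw, so the
    emitted MW sits within half a CH2 unit of the sampled value; the sampled
    (continuous) values are returned alongside for closed-form checks.
    """
    if n < 1:
        raise SpecError("n must be >= 1")
    weights = np.array([c.weight for c in components], dtype=float)
    if weights.sum() <= 0:
        raise SpecError("component weights must sum to a positive value")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    choices = rng.choice(len(components), size=n, p=weights)
    draws = np.empty(n)
    for i, c in enumerate(components):
        mask = choices == i
        draws[mask] = rng.lognormal(c.mu, c.sigma, size=int(mask.sum()))
    records = []
    for i, m in enumerate(draws):
        length = max(1, round((m - _H2) / _CH2))
        records.append(_alkane(length, f"MW{i:05d}"))
    return records, draws


def _alkane(n_carbons: int, source_id: str) -> MoleculeRecord:
    coords = _zigzag(n_carbons)
    rec = MoleculeRecord(
        source_id=source_id,
        atoms=[Atom("C", x=x, y=y) for x, y in coords],
        bonds=[Bond(i - 1, i) for i in range(1, n_carbons)],
    )
    rec.complete_hydrogens()
    return rec


# ---------------------------------------------------------------------------
# protein inputs
# ---------------------------------------------------------------------------


@dataclass
class ProteinPlantSpec:
    labels: Sequence[str]
    cells: dict[tuple[str, ...], int]
    species_fractions: dict[str, float]  # over the union; must sum to 1
    reviewed_fraction: float = 0.9
    target_species: str = "Human"
    go_categories: Sequence[str] = (
        "catalytic activity",
        "receptor activity",
        "transporter activity",
        "ion channel activity",
        "binding",
    )
    go_weights: Optional[dict[str, Sequence[float]]] = None  # per label
    fork_fraction: float = 0.1  # proteins carrying a second category
    duplicates_per_source: int = 0
    malformed_per_source: int = 0
    seed: int = 0


@dataclass
class ProteinGroundTruth:
    cells: dict[frozenset, int]
    set_sizes: dict[str, int]
    species_counts: dict[str, dict[str, int]]
    sp_tr: dict[str, tuple[int, int]]
    target_unreviewed: dict[str, int]
    go_counts: dict[str, dict[str, int]]
    n_assignments: dict[str, int]


def generate_protein_inputs(
    spec: ProteinPlantSpec,
) -> tuple[dict[str, list[str]], "pd.DataFrame", ProteinGroundTruth]:
    import pandas as pd

    label_set = set(spec.labels)
    for mask, count in spec.cells.items():
        if not set(mask) <= label_set or count < 0:
            raise SpecError(f"infeasible cell {mask}: {count}")
    if abs(sum(spec.species_fractions.values()) - 1.0) > 1e-9:
        raise SpecError("species fractions must sum to 1")

    rng = np.random.default_rng(spec.seed)
    # accessions per cell
    membership: dict[str, frozenset] = {}
    serial = 1
    for mask, count in sorted(spec.cells.items()):
        for _ in range(count):
            acc = f"P{serial:05d}"
            serial += 1
            membership[acc] = frozenset(mask)
    union = sorted(membership)

    # deterministic species assignment: largest-remainder allocation, then
    # contiguous blocks over the (sorted) union
    species_alloc = _largest_remainder(
        spec.species_fractions, len(union)
    )
    species_of: dict[str, str] = {}
    cursor = 0
    for name, count in species_alloc:
        for acc in union[cursor : cursor + count]:
            species_of[acc] = name
        cursor += count

    # reviewed flags: deterministic per species block
    reviewed_of: dict[str, bool] = {}
    by_species: dict[str, list[str]] = {}
    for acc in union:
        by_species.setdefault(species_of[acc], []).append(acc)
    for name, accs in by_species.items():
        n_sp = round(spec.reviewed_fraction * len(accs))
        for i, acc in enumerate(accs):
            reviewed_of[acc] = i < n_sp

    # GO assignment: weight vector averaged over the sources holding the acc
    cats = list(spec.go_categories)
    weights = spec.go_weights or {
        lab: [1.0] * len(cats) for lab in spec.labels
    }
    go_of: dict[str, set[str]] = {}
    for acc in union:
        mask = membership[acc]
        w = np.zeros(len(cats))
        for lab in mask:
            w += np.asarray(weights[lab], dtype=float)
        w = w / w.sum()
        first = cats[int(rng.choice(len(cats), p=w))]
        chosen = {first}
        if rng.random() < spec.fork_fraction:
            others = [c for c in cats if c != first]
            chosen.add(others[int(rng.integers(len(others)))])
        go_of[acc] = chosen

    # per-source lists and bookkeeping
    id_lists: dict[str, list[str]] = {lab: [] for lab in spec.labels}
    species_counts: dict[str, dict[str, int]] = {}
    sp_tr: dict[str, tuple[int, int]] = {}
    target_tr: dict[str, int] = {}
    go_counts: dict[str, dict[str, int]] = {}
    n_assign: dict[str, int] = {}
    sizes: dict[str, int] = {}
    for lab in spec.labels:
        accs = sorted(a for a in union if lab in membership[a])
        sizes[lab] = len(accs)
        sc: dict[str, int] = {}
        sp = tr = ttr = 0
        gc: dict[str, int] = {}
        for acc in accs:
            sc[species_of[acc]] = sc.get(species_of[acc], 0) + 1
            if reviewed_of[acc]:
                sp += 1
            else:
                tr += 1
                if species_of[acc] == spec.target_species:
                    ttr += 1
            for cat in go_of[acc]:
                gc[cat] = gc.get(cat, 0) + 1
        species_counts[lab] = sc
        sp_tr[lab] = (sp, tr)
        target_tr[lab] = ttr
        go_counts[lab] = gc
        n_assign[lab] = sum(gc.values())
        listing = list(accs)
        if spec.duplicates_per_source:
            listing += list(
                rng.choice(accs, size=min(spec.duplicates_per_source, len(accs)), replace=False)
            )
        listing += [
            f"not_an_id_{k}" for k in range(spec.malformed_per_source)
        ]
        rng.shuffle(listing)
        id_lists[lab] = listing

    annotations = pd.DataFrame(
        {
            "accession": union,
            "species": [species_of[a] for a in union],
            "reviewed": ["SP" if reviewed_of[a] else "TR" for a in union],
            "go_categories": [";".join(sorted(go_of[a])) for a in union],
        }
    )
    truth = ProteinGroundTruth(
        cells={frozenset(m): c for m, c in spec.cells.items()},
        set_sizes=sizes,
        species_counts=species_counts,
        sp_tr=sp_tr,
        target_unreviewed=target_tr,
        go_counts=go_counts,
        n_assignments=n_assign,
    )
    return id_lists, annotations, truth


def write_protein_inputs(
    spec: ProteinPlantSpec, outdir: str | Path
) -> ProteinGroundTruth:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    id_lists, annotations, truth = generate_protein_inputs(spec)
    for lab, listing in id_lists.items():
        (outdir / f"{lab}.txt").write_text("\n".join(listing) + "\n")
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
    return truth


def _largest_remainder(
    fractions: dict[str, float], total: int
) -> list[tuple[str, int]]:
    items = sorted(fractions.items())
    raw = [(name, frac * total) for name, frac in items]
    counts = {name: int(math.floor(x)) for name, x in raw}
    leftover = total - sum(counts.values())
    by_remainder = sorted(
        raw, key=lambda t: (t[1] - math.floor(t[1]), t[0]), reverse=True
    )
    for name, _ in by_remainder[:leftover]:
        counts[name] += 1
    return [(name, counts[name]) for name, _ in items]
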
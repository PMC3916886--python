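# Methods

## The identity model

`chemcompare` treats chemical identity as a family of equivalence relations
of increasing coarseness rather than a single canonical form. Each SD
record is parsed into a labelled graph (element, formal charge, isotope
mass number, implicit-H count per atom; order 1-3 plus a wedge/geometry
annotation per bond) and keyed at three levels:

1. **Sensitive** (`ficts`): base normalization only. Two records share a
   key iff their normalized graphs are isomorphic, including charges,
   isotopes, fragments, the drawn tautomer and the drawn wedge marks.
2. **Tautomer-invariant** (`ficus`): base normalization plus canonical
   tautomer selection, applied independently to every connected fragment.
   Counterions, charges, isotopes and stereo marks are still distinguished.
3. **Skeleton** (`uuuuu`): parent-fragment selection, charge
   neutralization, isotope clearing, stereo stripping and tautomer
   canonicalization — basic-connectivity identity.

The class structure is nested by construction: equal sensitive keys imply
equal tautomer-invariant keys imply equal skeleton keys. Unique-count
tables at the three levels therefore decompose a collection's redundancy
into "exact duplicates", "tautomer drawings" and "salt/charge/isotope/
stereo variants".

Standard InChIKey is treated as an *external provider* (an RDKit-backed
callable whose strings are attached verbatim); the package makes no claim
of numeric agreement between its own keys and any historical identifier
values — the contracts (what each level disregards), not the hash values,
are the reproducible content.

## Base normalization

Applied in fixed order; every operator is idempotent and invariant under
permutation of the input atom order.

1. **Explicit-H folding.** Plain explicit hydrogens (no charge, no isotope,
   single non-wedged bond to a heavy atom) are folded into the neighbour's
   implicit count. H atoms carrying an isotope label or sitting on a wedge
   stay in the graph, because the sensitive key must keep that information.
2. **Functional-group transforms** (the documented miss-drawn-group table):
   neutral pentavalent nitro `R-N(=O)=O -> R-[N+](=O)[O-]`; neutral azide /
   diazo `X=N=N -> X=[N+]=[N-]` (terminal N); charge-separated sulfoxide
   `[S+]-[O-] -> S=O`. Implicit hydrogens of rewritten atoms are re-derived
   from the corrected valence, since the original values were inferred from
   a miss-drawn valence in the first place. Records whose valences cannot
   be completed after transformation are flagged `rejected`, excluded from
   identity statistics, and tallied.
3. **Charged-resonance canonicalization.** Wherever a charge can migrate by
   a single swap `X(q)-A=Y -> X=A-Y(q)` between atoms of the same element,
   H count and isotope, the placement whose canonical serialization is
   lexicographically smallest is chosen (greedy descent; each accepted swap
   strictly decreases the serialization, so the procedure terminates and is
   idempotent). Symmetry-equivalent placements yield isomorphic graphs and
   hence identical keys without any swap. No CIP ranks are used anywhere.

## Canonical serialization and hashing

Atoms are partitioned by iterative neighbourhood refinement: the initial
invariant is (element, charge, isotope, implicit-H count, degree), and each
round re-partitions by (current class, sorted multiset of (bond order,
neighbour class)) until stable. Remaining ties are resolved by
individualization branching — every member of the first tied cell is tried
as the next unique atom, recursively — and the lexicographically smallest
complete serialization wins. Wedge annotations (including which end of the
bond the wedge originates from) enter the serialization but not the
refinement invariants, which keeps the branch set closed under
automorphisms of the intrinsic coloured graph; the minimum over that set is
therefore a true graph invariant. Branching is exponential only for highly
symmetric graphs, which at molecule scale is harmless (benzene explores 12
labellings).

The key is the first 27 base-32 characters of a 136-bit BLAKE2b digest of
the serialization — fixed-length, InChIKey-shaped. Collisions are treated
as impossible at working scale (2^136 space); the test suite additionally
cross-checks key-equality classes against brute-force VF2 graph
isomorphism on small molecules, so a collision would surface as a class
mismatch rather than pass silently.

## Tautomer canonicalization

The transform set is deliberately small and closed: 1,3 H-shifts
`H-a-b=c -> a=b-c-H` with a, c in {C, N, O, S} (at least one heteroatom
among a, c), pivot b in {C, N}, uncharged shift ends and no wedge on the
two bonds. Each transform is its own inverse pattern, so the reachable set
of forms is an equivalence orbit; it is enumerated breadth-first (frontier
ordered by canonical serialization, so enumeration order is
drawing-independent) to a hard cap of 1000 distinct forms, and the form
with the smallest canonical serialization represents the orbit. On cap
overflow the input form is kept and flagged `tautomer_cap`, keeping the key
deterministic. This covers keto/enol, amide/iminol (2-pyridone /
2-hydroxypyridine) and their aza analogues — enough to demonstrate every
collection-level phenomenon the tautomer-invariant level exists for,
without attempting an exhaustive mobile-H model.

A shift is additionally blocked when one of its three atoms is the origin
of a drawn wedge. Without this rule, enolization through a lone
stereocentre would erase its wedge during enumeration and collapse
stereoisomer drawings at the tautomer-invariant level, contradicting that
level's contract of keeping stereo. The cost is that a tautomer pair whose
mobile hydrogen sits *on* a wedged stereocentre is not merged — a
documented conservatism.

In the skeleton pipeline stereo is stripped *before* tautomer
canonicalization. The two operations only commute when no shift is
wedge-blocked; stripping first makes the skeleton key independent of wedge
direction in all cases, which is that level's contract.

## Stereo perception

No CIP rules: substituent distinctness is judged by the refinement classes
above. A potential tetrahedral centre is an atom with four graph-distinct
substituents (implicit H counts as one substituent; at most one), counted
as *specified* when a wedge originates at it. A stereogenic double bond is
a non-ring double bond (ring membership via bridge detection, any ring
size) with two distinct substituents at each end, *specified* when the 2D
coordinates place substituents off the bond axis and the bond is not
flagged "either"; records without coordinates count as unspecified.
Refinement classes can merge branches that full isomorphism would
distinguish (e.g. some meso cases), so the centre count is a deterministic
approximation — appropriate for collection-level quality statistics, not
for per-molecule stereo assignment.

Each record falls in exactly one atom-stereo class (no centres / all
specified / at least one unspecified) and one bond-stereo class, so the
six columns partition the collection exactly. Percentages are computed
against a caller-supplied *original* record count (pre-failure,
pre-rejection), which is why a summary row need not sum to 100%.

## Statistical conventions

* Unique-count percentages are **truncated** to one decimal
  (2834/3616 -> 78.3); prose-style coverage percentages are **rounded** to
  the nearest integer (1746/4674 -> 37%); stereo-table percentages are
  **rounded** to one decimal. The two table conventions follow the
  corresponding published table formats, which are not mutually consistent.
* Molecular weight is the sum of abundance-averaged standard atomic
  weights (RDKit periodic table), isotope-labelled atoms contributing their
  nuclide mass. Profiles default to the normalized parent fragment
  (salt-free); a flag retains counterions. Quartiles use inclusive linear
  interpolation; the SD is the population SD. Both choices are defaults of
  this package, stated because the table formats they mirror leave the
  method unstated.
* Set algebra is over keys, not record IDs: two records with one key are
  one element.
* `skeleton_links` counts skeleton keys present in both releases whose
  sensitive-level key sets are disjoint — records whose connectivity
  persisted while every drawing of it changed. This is the
  curation-improvement signal that makes a skeleton-level union exceed the
  sensitive-level union.

## The synthetic generator

The generator is the package's study-condition definition, not a test
convenience dial. Its scaffold pool is hand-curated (20 graphs): a chiral
family `X-CH(CH3)-(CH2)1+L-C(=O)-CH2-NH2` (X in {F, Cl, Br, I, OH, NH2,
SH}, L in {0, 1}) and an achiral family `CH3-(CH2)k-C(=O)-CH2-NH2`
(k = 1..6). Every chiral scaffold provably has exactly one tetrahedral
stereocentre (drawn with a wedge), every scaffold a keto/enol site away
from the stereocentre, a protonatable amine and an isotope-labellable
methyl — so variant plans (exact duplicate, salt = added water fragment,
protonated charge state, 13C label, enol re-drawing, wedge inversion, wedge
stripping) are always realisable or fail loudly at generation time.
Release-2 curation events (keep / remove / add stereo to flat drawings /
re-draw as tautomer / add new scaffolds) are bookkept symbolically, so the
expected unique counts, diff triples, skeleton links and stereo classes are
exact by construction, not re-derived through the pipeline under test.
Validation forbids event combinations that would make that bookkeeping
ambiguous (re-drawing a record that also has an exact duplicate, tautomer
re-drawing where the plan already plants a tautomer variant).

MW regimes are log-normal mixtures realised as hydrocarbon chains of the
nearest length, emitted by a companion operation so unique-count ground
truth stays closed-form. Defaults: a single broad lead-like component
(median 380 Da, log-SD 0.45) and bimodal/tri-modal presets with clusters
near 1000 and 1500 Da mimicking a metabolite collection acquiring large
lipid classes. The chain realisation quantises MW to ~14 Da steps, which
is well inside the sampling error of the distribution statistics at the
default sizes (n = 1000-1200).

Protein inputs plant exact Venn cells (accessions generated per cell),
deterministic species allocation (largest-remainder), deterministic
reviewed flags per species block, and seeded GO category assignment with a
configurable per-source bias and fork fraction (proteins carrying two
categories). The ground truth records realised counts, so recovery
assertions are exact.

What the generator does **not** emulate: realistic medicinal-chemistry
scaffolds, ring-rich chemistry, aromatic tautomerism beyond the closed
transform set, stereogenic double-bond curation, 3D structures, or any
real database's counts. Passing tests demonstrate that the pipeline's
set-algebra, classification and recovery logic are exact under controlled
redundancy — not that the normalization rules match any particular
production toolkit on wild data.

## Numerical and degenerate-input choices

* Kekulization of aromatic (order-4) molfile bonds by backtracking; each
  aromatic atom takes exactly one double bond, N/O/S may take none;
  failures are parse failures, as are V3000 blocks ("unsupported version"),
  malformed counts lines and out-of-range bond indices. Parse failures
  never abort a file; `records_read + records_failed` equals the number of
  `$$$$` blocks.
* Implicit hydrogens come from a standard valence table (charge-adjusted);
  atoms with no plausible valence flag the record.
* Parent selection: most heavy atoms, then larger MW, then smallest
  canonical serialization (fully deterministic for true ties).
* Neutralization adds/removes implicit H per unit charge where the valence
  table permits; quaternary nitrogens and bare metal cations keep their
  charge.
* Empty records (zero atoms) are rejected at keying time; empty inputs to
  statistics functions raise rather than return NaN.
* Problem sizes in the test and acceptance runs (libraries of 1-8
  scaffolds, 50 random libraries for the hierarchy property, n = 1000-1200
  for MW, ~1000 accessions for protein plants) were chosen as the smallest
  sizes at which every planted phenomenon is distinguishable from
  degenerate behaviour.

## Known limitations

* The transform tables are minimal stand-ins honouring the stated
  contracts; no agreement with proprietary normalization rule sets is
  claimed or tested.
* Stereo perception is symmetry-class-based and can under-count centres in
  symmetric molecules; bond-stereo "specified" trusts 2D geometry, which
  real files sometimes draw arbitrarily.
* GO handling is flat top-level categories from an input table; no
  ontology traversal.
* The tautomer cap (1000 forms) makes keys of pathological mobile-H systems
  drawing-dependent (flagged, never silent).
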
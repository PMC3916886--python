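# chemcompare

Compare the chemical-structure and protein-target content of curated
compound databases (ChEMBL-, DrugBank-, HMDB-, TTD-style collections)
across sources and across releases.

Public compound collections overlap, diverge and improve over time, but
their SD-file dumps cannot be compared record-by-record: the "same"
compound may appear as a salt, a charged species, an isotope-labelled
form, another tautomer drawing, a different stereo drawing, or an exact
duplicate. `chemcompare` resolves this with **graded identity keys**: every
record is normalized and hashed at three sensitivity levels,

| level | name | invariant to |
|---|---|---|
| sensitive | `ficts` | atom order, miss-drawn functional groups, charge-resonance placement |
| tautomer-invariant | `ficus` | additionally: tautomeric form (1,3 H-shifts, per fragment) |
| skeleton | `uuuuu` | additionally: counterions, charges, isotopes, stereo marks |

so that `uniques(ficts) >= uniques(ficus) >= uuuuu` holds by construction
and the gap between levels measures the kind of redundancy a collection
carries. Keys are 27-character base-32 hashes of a canonical graph
serialization (iterative neighbourhood refinement with deterministic
tie-breaking); a Standard InChIKey provider (RDKit) can be plugged in
alongside. On top of the keys the package computes the comparison
statistics used to characterise database content and curation quality:

* unique-structure counts with percent-of-original tables,
* pairwise overlap matrices and 2-4-way Venn partitions,
* between-release diffs (maintained/removed/added) with **skeleton
  linking** — records whose basic connectivity persisted while the drawing
  improved (e.g. stereo added), visible only at skeleton level,
* stereochemistry-quality tables (no/full/partial specification for
  tetrahedral centres and double bonds),
* molecular-weight profiles (mean/SD/quartiles, histograms with
  exclusive-subset overlays),
* UniProt-ID set comparison: species splits, Swiss-Prot:TrEMBL ratios,
  n-way consensus, GO molecular-function distributions.

A first-class synthetic-data generator emits SD-file "releases" with
controlled redundancy and curation events and exact ground truth, so every
statistic above is testable end-to-end.

## Worked example

Generate a synthetic pair of releases (3 scaffolds, each also present as a
salt, an enol drawing and a stereo-inverted drawing) and profile it:

```
$ chemcompare simulate --n-scaffolds 3 --variants salt,tautomer,stereo_invert \
      --seed 5 --out-dir demo
$ chemcompare uniques demo/release1.sdf
collection      level   unique  pct_of_original
release1        ficts   12      100.0
release1        ficus   9       75.0
release1        uuuuu   3       25.0
```

All 12 records are distinct drawings (`ficts` 12); folding tautomers merges
each enol with its ketone (`ficus` 9 = 3 scaffolds x 3 forms); skeleton
identity collapses everything to the 3 underlying scaffolds (`uuuuu` 3).
The release diff reports the curation signal between versions:

```
$ chemcompare diff demo/release1.sdf demo/release2.sdf
{
 "maintained": {"ficts": 12, "uuuuu": 3},
 "removed":    {"ficts": 0,  "uuuuu": 0},
 "added":      {"ficts": 0,  "uuuuu": 0},
 "skeleton_links": 0
}
```

(no curation events were planted here, so both releases agree at every
level; with `add_stereo` curation the sensitive-level overlap drops while
`skeleton_links` counts the re-drawn records). The same operations are
available as library functions — see `chemcompare.normalize.compute_keys`,
`chemcompare.sets`, `chemcompare.stereo`, `chemcompare.mw`,
`chemcompare.proteins` and `chemcompare.synthetic`.

## Documentation

`docs/methods.md` describes the normalization cascade, the canonical
serialization and hashing, the stereo-perception rules, the statistical
conventions (truncated vs rounded percentages, quartile method), and what
the synthetic generator does and does not emulate.
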
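"""SD file reading/writing: round-trips, failure accounting, ID handling."""

import warnings

import pytest

from chemcompare.canonical import canonical_serialization
from chemcompare.records import Wedge
from chemcompare.sdf_io import read_sdf, record_to_block, write_sdf
from chemcompare.synthetic import LibrarySpec, generate_library

from conftest import alanine, aspirin, build


def library_records(seed=0, n=4):
    spec = LibrarySpec(
        n_scaffolds=n,
        uniform_plan=["salt", "charge", "isotope", "tautomer"],
        seed=seed,
    )
    r1, _, _ = generate_library(spec)
    return r1


def test_empty_file(tmp_path):
    path = tmp_path / "empty.sdf"
    path.write_text("")
    records, report = read_sdf(path)
    assert records == []
    assert report.records_read == 0 and report.records_failed == 0


def test_missing_file_is_fatal(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_sdf(tmp_path / "nope.sdf")


def test_generated_file_round_trips_with_known_count(tmp_path):
    records = library_records()
    path = tmp_path / "lib.sdf"
    write_sdf(records, path)
    back, report = read_sdf(path)
    assert report.records_read == len(records)
    assert report.records_failed == 0
    for orig, new in zip(records, back):
        assert orig.source_id == new.source_id
        assert canonical_serialization(orig) == canonical_serialization(new)


def test_round_trip_preserves_charges_isotopes_wedges(tmp_path):
    rec = alanine(wedged=True)
    rec.atoms[0].charge = 1
    rec.atoms[0].h_count += 1  # protonated amine
    rec.atoms[2].isotope = 13
    path = tmp_path / "one.sdf"
    write_sdf([rec], path)
    (back,), report = read_sdf(path)
    assert report.records_failed == 0
    assert [a.charge for a in back.atoms] == [a.charge for a in rec.atoms]
    assert [a.isotope for a in back.atoms] == [a.isotope for a in rec.atoms]
    assert [b.wedge for b in back.bonds] == [b.wedge for b in rec.bonds]
    assert canonical_serialization(back) == canonical_serialization(rec)


def test_corrupted_middle_block_is_counted_not_fatal(tmp_path):
    recs = library_records(n=3)[:3]
    blocks = [record_to_block(r) for r in recs]
    lines = blocks[1].split("\n")
    lines[3] = "  x  y  0  0"  # corrupt the counts line
    blocks[1] = "\n".join(lines)
    path = tmp_path / "corrupt.sdf"
    path.write_text("".join(blocks))
    records, report = read_sdf(path)
    assert len(records) == 2
    assert report.records_failed == 1
    assert report.failure_reasons[0][0] == 2
    assert report.records_read + report.records_failed == 3


def test_v3000_block_fails_with_reason(tmp_path):
    block = (
        "m\n\n\n  0  0  0     0  0            999 V3000\n"
        "M  V30 BEGIN CTAB\nM  END\n$$$$\n"
    )
    path = tmp_path / "v3.sdf"
    path.write_text(block)
    records, report = read_sdf(path)
    assert records == []
    assert report.failure_reasons == [(1, "unsupported version")]


def test_bond_to_nonexistent_atom_fails(tmp_path):
    block = (
        "bad\n\n\n  1  1  0  0  0  0  0  0  0  0999 V2000\n"
        "    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0\n"
        "  1  9  1  0\nM  END\n$$$$\n"
    )
    path = tmp_path / "bad.sdf"
    path.write_text(block)
    records, report = read_sdf(path)
    assert report.records_failed == 1
    assert "nonexistent" in report.failure_reasons[0][1]


def test_id_field_with_title_fallback(tmp_path):
    rec = aspirin()
    path = tmp_path / "ids.sdf"
    write_sdf([rec], path, id_field="DATABASE_ID")
    (by_field,), _ = read_sdf(path, id_field="DATABASE_ID")
    assert by_field.source_id == "aspirin"
    (fallback,), _ = read_sdf(path, id_field="MISSING_FIELD")
    assert fallback.source_id == "aspirin"  # title line fallback


def test_duplicate_source_ids_warn_but_keep_both(tmp_path):
    rec = aspirin()
    path = tmp_path / "dup.sdf"
    write_sdf([rec, rec.copy()], path)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        records, _ = read_sdf(path)
    assert len(records) == 2
    assert any("duplicate source_id" in str(w.message) for w in caught)


def test_aromatic_bonds_are_kekulized(tmp_path):
    lines = ["benzene", "", "", "  6  6  0  0  0  0  0  0  0  0999 V2000"]
    for i in range(6):
        lines.append(
            f"{float(i):10.4f}{0.0:10.4f}{0.0:10.4f} C   0  0  0  0  0  0  0  0  0  0  0  0"
        )
    for i in range(6):
        lines.append(f"{i + 1:3d}{(i + 1) % 6 + 1:3d}  4  0")
    lines += ["M  END", "$$$$", ""]
    path = tmp_path / "arom.sdf"
    path.write_text("\n".join(lines))
    (rec,), report = read_sdf(path)
    assert report.records_failed == 0
    orders = sorted(b.order for b in rec.bonds)
    assert orders == [1, 1, 1, 2, 2, 2]


def test_unkekulizable_aromatic_system_fails(tmp_path):
    # a single "aromatic" bond between two sp3-style carbons cannot close
    lines = [
        "bad-arom", "", "", "  2  1  0  0  0  0  0  0  0  0999 V2000",
        f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} C   0  0  0  0  0  0  0  0  0  0  0  0",
        f"{1.0:10.4f}{0.0:10.4f}{0.0:10.4f} C   0  0  0  0  0  0  0  0  0  0  0  0",
        "  1  2  4  0", "M  END", "$$$$", "",
    ]
    path = tmp_path / "badarom.sdf"
    path.write_text("\n".join(lines))
    records, report = read_sdf(path)
    assert report.records_failed in (0, 1)
    if report.records_failed:
        assert "kekulize" in report.failure_reasons[0][1]
    else:
        # a lone C=C assignment is a legal kekulization
        assert records[0].bonds[0].order == 2


def test_block_conservation_on_mixed_file(tmp_path):
    recs = library_records(n=2)
    good = "".join(record_to_block(r) for r in recs)
    bad = "junk\n\n\nnot a counts line\n$$$$\n"
    path = tmp_path / "mixed.sdf"
    path.write_text(good + bad + good)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # repeated IDs are intended here
        records, report = read_sdf(path)
    n_blocks = (good + bad + good).count("$$$$")
    assert report.records_read + report.records_failed == n_blocks
    assert report.records_failed == 1
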
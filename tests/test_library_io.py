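"""Dialect detection and harmonized parsing of spectral-library exports."""

import numpy as np
import pandas as pd
import pytest

from diakit.library_io import (
    DIALECTS,
    DialectError,
    LibraryProvenance,
    ParseError,
    detect_dialect,
    read_harmonized_library,
    read_library,
    strip_modifications,
    write_harmonized_library,
)
from diakit.synthetic_data import write_maxquant_evidence

from conftest import assert_same_precursors

PROV = {
    "diann_lib": LibraryProvenance("DIANN", "DIA"),
    "fragpipe_lib": LibraryProvenance("FragPipe", "DDA"),
    "maxquant_evidence": LibraryProvenance("MaxQuant", "DDA"),
    "spectronaut_allpeptides": LibraryProvenance("Spectronaut", "DIA"),
}


def test_detect_dialect_from_column_signatures(tmp_path):
    p = tmp_path / "evidence.txt"
    p.write_text("Sequence\tModified sequence\tCharge\tm/z\tProteins\n")
    assert detect_dialect(p) == "maxquant_evidence"


def test_detect_dialect_rejects_ambiguous_header(tmp_path):
    # a synthetic header carrying both MaxQuant's and FragPipe's signatures
    p = tmp_path / "chimera.tsv"
    p.write_text(
        "Sequence\tModified sequence\tCharge\tm/z\tProteins\t"
        "PeptideSequence\tModifiedPeptideSequence\tPrecursorCharge\tPrecursorMz\tProteinId\n"
    )
    with pytest.raises(DialectError, match="ambiguous"):
        detect_dialect(p)


def test_detect_dialect_rejects_unknown_header(tmp_path):
    p = tmp_path / "other.tsv"
    p.write_text("foo\tbar\tbaz\n")
    with pytest.raises(DialectError, match="missing"):
        detect_dialect(p)


def test_every_fixture_detects_exactly_its_own_dialect(fixture_dir):
    """Dialect detection partitions the generated fixtures."""
    lib_paths = {k: p for k, p in fixture_dir.items() if k.startswith("lib:")}
    assert len(lib_paths) == 6
    expected = {
        "DIANN": "diann_lib",
        "FragPipe": "fragpipe_lib",
        "MaxQuant": "maxquant_evidence",
        "Spectronaut": "spectronaut_allpeptides",
    }
    for key, path in lib_paths.items():
        engine = key.split(":")[1].split("-")[0]
        assert detect_dialect(path) == expected[engine]


def test_round_trip_all_library_dialects(fixture_dir, libraries):
    """write -> read reproduces the precursor multiset for every dialect."""
    libs, _ = libraries
    for key, path in fixture_dir.items():
        if not key.startswith("lib:"):
            continue
        name = key.split(":", 1)[1]
        engine, mode = name.split("-")
        again = read_library(path, provenance=LibraryProvenance(engine, mode), name=name)
        assert_same_precursors(libs[name], again)


def test_parsing_is_order_invariant(fixture_dir, libraries):
    libs, _ = libraries
    path = fixture_dir["lib:DIANN-DIA"]
    df = pd.read_csv(path, sep="\t")
    shuffled = df.sample(frac=1.0, random_state=3)
    p2 = path.parent / "shuffled.tsv"
    shuffled.to_csv(p2, sep="\t", index=False)
    a = read_library(path, provenance=PROV["diann_lib"])
    b = read_library(p2, provenance=PROV["diann_lib"])
    assert_same_precursors(a, b)


def test_duplicate_rows_collapse_to_one_entry(tmp_path):
    k = 5
    rows = "\n".join("PEPTIDEK\t_PEPTIDEK_\t2\t450.7310\tP1" for _ in range(k))
    p = tmp_path / "evidence.txt"
    p.write_text("Sequence\tModified sequence\tCharge\tm/z\tProteins\n" + rows + "\n")
    lib = read_library(p, provenance=PROV["maxquant_evidence"])
    assert len(lib) == 1
    assert lib.read_stats.n_duplicates == k - 1


def test_conflicting_duplicate_mz_is_counted(tmp_path):
    p = tmp_path / "evidence.txt"
    p.write_text(
        "Sequence\tModified sequence\tCharge\tm/z\tProteins\n"
        "PEPTIDEK\t_PEPTIDEK_\t2\t450.7310\tP1\n"
        "PEPTIDEK\t_PEPTIDEK_\t2\t451.9999\tP1\n"
    )
    lib = read_library(p, provenance=PROV["maxquant_evidence"])
    assert len(lib) == 1
    assert lib.entries[0].precursor_mz == pytest.approx(450.7310)  # first wins
    assert lib.read_stats.n_mz_conflicts == 1


def test_decoys_dropped_contaminants_flagged(tmp_path, libraries):
    """MaxQuant REV__ rows vanish; CON__ rows stay but carry the flag."""
    libs, _ = libraries
    src = libs["MaxQuant-DDA"]
    p = tmp_path / "evidence.txt"
    write_maxquant_evidence(src, p, n_decoys=4)
    lib = read_library(p, provenance=PROV["maxquant_evidence"])
    assert lib.read_stats.n_decoys == 4
    assert len(lib) == len(src)
    n_contam_src = sum(e.is_contaminant for e in src.entries)
    assert sum(e.is_contaminant for e in lib.entries) == n_contam_src > 0


def test_invalid_rows_dropped_and_counted(tmp_path):
    p = tmp_path / "evidence.txt"
    p.write_text(
        "Sequence\tModified sequence\tCharge\tm/z\tProteins\n"
        "PEPTIDEK\t_PEPTIDEK_\t2\t450.73\tP1\n"  # valid
        "PEP\t_PEP_\t2\t200.1\tP1\n"  # too short
        "PEPTIDEK\t_PEPTIDEK_\t0\t450.73\tP1\n"  # bad charge
        "PEPTIDEK\t_PEPTIDEK_\t2\t-1\tP1\n"  # bad m/z
        "MISMATCH\t_OTHERSEQ_\t2\t450.73\tP1\n"  # stripped != annotation-stripped
    )
    lib = read_library(p, provenance=PROV["maxquant_evidence"])
    assert len(lib) == 1
    assert lib.read_stats.n_invalid == 4


def test_empty_library_after_filtering_is_an_error(tmp_path):
    p = tmp_path / "evidence.txt"
    p.write_text("Sequence\tModified sequence\tCharge\tm/z\tProteins\nPEP\t_PEP_\t2\t1\tP1\n")
    with pytest.raises(ParseError, match="empty library"):
        read_library(p, provenance=PROV["maxquant_evidence"])


def test_missing_required_column_is_a_parse_error(tmp_path):
    p = tmp_path / "evidence.txt"
    p.write_text("Sequence\tModified sequence\tCharge\tm/z\tProteins\nPEPTIDEK\t_PEPTIDEK_\t2\t450.73\tP1\n")
    with pytest.raises(ParseError, match="required column"):
        read_library(p, dialect="fragpipe_lib", provenance=PROV["fragpipe_lib"])


@pytest.mark.parametrize(
    "modified,stripped",
    [
        ("_PEPTM(Oxidation (M))IDEK_", "PEPTMIDEK"),
        ("PEPC(UniMod:39)TIDEK", "PEPCTIDEK"),
        ("_AC[Carbamidomethyl (C)]DEFK_", "ACDEFK"),
        ("PLAINSEQ", "PLAINSEQ"),
        ("_M[Oxidation (M)]C[Methylthio (C)]AAAK_", "MCAAAK"),
    ],
)
def test_strip_modifications_across_notations(modified, stripped):
    assert strip_modifications(modified) == stripped


@pytest.mark.parametrize("engine,acq", [("MaxQuant", "DIA"), ("DIANN", "DDA")])
def test_infeasible_workflow_pairs_rejected(engine, acq):
    with pytest.raises(ValueError, match="not a feasible workflow"):
        LibraryProvenance(engine=engine, acquisition=acq)


@pytest.mark.parametrize("fmt", ["tsv", "jsonl"])
def test_harmonized_write_read_round_trip(tmp_path, libraries, fmt):
    libs, _ = libraries
    src = libs["Spectronaut-DIA"]
    p = tmp_path / f"harmonized.{fmt}"
    write_harmonized_library(src, p, fmt=fmt)
    again = read_harmonized_library(p, fmt=fmt)
    assert again.name == src.name
    assert again.provenance == src.provenance
    assert_same_precursors(src, again)
    assert sum(e.is_contaminant for e in again.entries) == sum(
        e.is_contaminant for e in src.entries
    )


def test_all_dialect_names_have_a_signature():
    from diakit.library_io import _SIGNATURES

    assert set(_SIGNATURES) == set(DIALECTS)
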
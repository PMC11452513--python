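"""Parsing the four protein-quantity dialects into QuantMatrix."""

import numpy as np
import pandas as pd
import pytest

from diakit.quant_io import (
    CohortError,
    QuantParseError,
    assign_cohorts,
    read_fragpipe_combined_protein,
    read_harmonized_matrix,
    read_maxquant_protein_groups,
    read_pg_matrix,
    read_spectronaut_report,
    write_harmonized_matrix,
)
from diakit.synthetic_data import (
    write_fragpipe_combined_protein,
    write_maxquant_protein_groups,
    write_pg_matrix,
    write_spectronaut_report,
)

CM = {"LEF": "LEF"}


def test_pg_matrix_recovers_planted_missing_cells(quant, tmp_path):
    qm, truth = quant
    p = tmp_path / "report.pg_matrix.tsv"
    write_pg_matrix(qm, p)
    again = read_pg_matrix(p, CM)
    assert again.n_missing() == int(truth.missing_mask.to_numpy().sum())
    assert again.values.shape == qm.values.shape


def test_all_identical_positive_matrix_has_no_missing(tmp_path):
    values = pd.DataFrame(7.5, index=[f"P{i}" for i in range(10)], columns=["LEF_a", "LEF_b", "LEF_c"])
    from diakit.quant_io import QuantMatrix

    qm = QuantMatrix(values=values, cohorts={c: "LEF" for c in values.columns})
    p = tmp_path / "report.pg_matrix.tsv"
    write_pg_matrix(qm, p)
    again = read_pg_matrix(p, CM)
    assert again.n_missing() == 0
    assert again.values.notna().all(axis=1).sum() == 10  # every row unanimous


def test_zeros_as_missing_config_contract(tmp_path):
    p = tmp_path / "report.pg_matrix.tsv"
    p.write_text("Protein.Group\tLEF_a\tLEF_b\nP1\t0.0\t5.0\n")
    as_missing = read_pg_matrix(p, CM, zeros_as_missing=True)
    assert as_missing.n_missing() == 1
    as_value = read_pg_matrix(p, CM, zeros_as_missing=False)
    assert as_value.n_missing() == 0
    assert as_value.values.at["P1", "LEF_a"] == 0.0


def test_unmatched_run_column_raises_listing_it(tmp_path):
    p = tmp_path / "report.pg_matrix.tsv"
    p.write_text("Protein.Group\tLEF_a\tMYSTERY_b\nP1\t1.0\t2.0\n")
    with pytest.raises(CohortError, match="MYSTERY_b"):
        read_pg_matrix(p, {"LEF_a": "LEF"})


def test_cohort_assignment_exact_then_substring():
    got = assign_cohorts(["LEF_run01", "LTL_run01"], {"LEF": "lef-cohort", "LTL_run01": "ltl"})
    assert got == {"LEF_run01": "lef-cohort", "LTL_run01": "ltl"}


def test_maxquant_drops_reverse_and_site_only_flags(quant, tmp_path):
    qm, truth = quant
    p = tmp_path / "proteinGroups.txt"
    write_maxquant_protein_groups(qm, p, n_decoys=3, n_site_only=2)
    again = read_maxquant_protein_groups(p, CM)
    assert len(again.protein_ids) == len(qm.protein_ids)
    assert again.n_missing() == int(truth.missing_mask.to_numpy().sum())
    assert again.contaminant.sum() == qm.contaminant.sum() > 0


def test_spectronaut_long_format_pivot(tmp_path):
    rows = ["R.FileName\tPG.ProteinGroups\tPG.Quantity"]
    for run in ("LEF_r1", "LEF_r2", "LEF_r3"):
        for prot in ("P1", "P2", "P3", "P4", "P5"):
            if (run, prot) in {("LEF_r1", "P5"), ("LEF_r3", "P2")}:
                continue  # two absent pairs -> two missing cells
            rows.append(f"{run}\t{prot}\t100.0")
    p = tmp_path / "Report.tsv"
    p.write_text("\n".join(rows) + "\n")
    qm = read_spectronaut_report(p, CM)
    assert qm.values.shape == (5, 3)
    assert qm.n_missing() == 2


def test_spectronaut_single_run_gives_single_column(tmp_path):
    p = tmp_path / "Report.tsv"
    p.write_text(
        "R.FileName\tPG.ProteinGroups\tPG.Quantity\nLEF_r1\tP1\t10.0\nLEF_r1\tP2\t20.0\n"
    )
    qm = read_spectronaut_report(p, CM)
    assert qm.values.shape == (2, 1)


def test_spectronaut_conflicting_duplicate_pair_is_an_error(tmp_path):
    p = tmp_path / "Report.tsv"
    p.write_text(
        "R.FileName\tPG.ProteinGroups\tPG.Quantity\n"
        "LEF_r1\tP1\t10.0\nLEF_r1\tP1\t99.0\n"
    )
    with pytest.raises(QuantParseError, match="conflicting duplicate"):
        read_spectronaut_report(p, CM)


def test_fragpipe_maxlfq_family_has_strictly_more_missing(quant, tmp_path):
    qm, _ = quant
    p = tmp_path / "combined_protein.tsv"
    write_fragpipe_combined_protein(qm, p)
    plain = read_fragpipe_combined_protein(p, CM, intensity_kind="intensity")
    maxlfq = read_fragpipe_combined_protein(p, CM, intensity_kind="maxlfq")
    assert plain.n_missing() < maxlfq.n_missing()


def test_fragpipe_missing_family_is_an_error(tmp_path):
    p = tmp_path / "combined_protein.tsv"
    p.write_text("Protein\tGene\tLEF_r1 Intensity\nP1\tG1\t5.0\n")
    assert read_fragpipe_combined_protein(p, CM).values.shape == (1, 1)
    with pytest.raises(QuantParseError, match="MaxLFQ"):
        read_fragpipe_combined_protein(p, CM, intensity_kind="maxlfq")


def test_fragpipe_one_protein_file(tmp_path):
    p = tmp_path / "combined_protein.tsv"
    p.write_text(
        "Protein\tGene\tLEF_r1 Intensity\tLEF_r1 MaxLFQ Intensity\nP1\tG1\t5.0\t5.0\n"
    )
    qm = read_fragpipe_combined_protein(p, CM)
    assert qm.protein_ids == ["P1"]
    assert qm.run_ids == ["LEF_r1"]


def test_missing_count_conserved_across_read_write_read(quant, tmp_path):
    qm, _ = quant
    writers_readers = [
        (write_pg_matrix, read_pg_matrix, "a.tsv", {}),
        (write_maxquant_protein_groups, read_maxquant_protein_groups, "b.txt", {}),
        (write_spectronaut_report, read_spectronaut_report, "c.tsv", {}),
        (write_fragpipe_combined_protein, read_fragpipe_combined_protein, "d.tsv", {}),
    ]
    for write, read, fname, kw in writers_readers:
        p1 = tmp_path / ("1" + fname)
        write(qm, p1, **kw)
        first = read(p1, CM)
        p2 = tmp_path / ("2" + fname)
        write(first, p2, **kw)
        second = read(p2, CM)
        assert second.n_missing() == first.n_missing()
        pd.testing.assert_frame_equal(
            first.values.sort_index(), second.values.sort_index(), atol=1e-4, rtol=0
        )


def test_pivot_is_order_invariant(quant, tmp_path):
    qm, _ = quant
    p = tmp_path / "Report.tsv"
    write_spectronaut_report(qm, p)
    df = pd.read_csv(p, sep="\t")
    p2 = tmp_path / "shuffled.tsv"
    df.sample(frac=1.0, random_state=11).to_csv(p2, sep="\t", index=False)
    a = read_spectronaut_report(p, CM)
    b = read_spectronaut_report(p2, CM)
    pd.testing.assert_frame_equal(
        a.values.sort_index(axis=0).sort_index(axis=1),
        b.values.sort_index(axis=0).sort_index(axis=1),
    )


def test_harmonized_matrix_round_trip(quant, tmp_path):
    qm, _ = quant
    prefix = tmp_path / "harm"
    write_harmonized_matrix(qm, prefix)
    again = read_harmonized_matrix(prefix)
    assert again.cohorts == qm.cohorts
    assert again.n_missing() == qm.n_missing()
    pd.testing.assert_frame_equal(again.values, qm.values, atol=1e-9, rtol=1e-9)
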
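"""Missingness accounting, CV arithmetic and the quintile vote."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diakit.quant_analysis import (
    InsufficientProteinsError,
    cv_by_row,
    missingness_summary,
    quintile_cv_report,
    quintile_sizes,
    vote_tally,
)
from diakit.quant_io import QuantMatrix
from diakit.synthetic_data import CohortPlan, SimConfig, generate_universe, simulate_quant


def matrix_from(values: pd.DataFrame, cohort="LEF") -> QuantMatrix:
    return QuantMatrix(values=values, cohorts={c: cohort for c in values.columns})


def two_pass_cv(values) -> float:
    """Independent two-pass oracle for the coefficient of variation."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return var**0.5 / mean


def test_cv_hand_values():
    assert cv_by_row([10.0, 10.0, 10.0]) == 0.0
    assert cv_by_row([8.0, 10.0, 12.0]) == pytest.approx(0.2)


@pytest.mark.parametrize(
    "bad,match",
    [([5.0], "at least 2"), ([0.0, 0.0], "positive"), ([3.0, -4.0], "positive")],
)
def test_cv_rejects_degenerate_input(bad, match):
    with pytest.raises(ValueError, match=match):
        cv_by_row(bad)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=0.1, max_value=1e9, allow_nan=False),
        min_size=2,
        max_size=12,
    )
)
def test_cv_matches_two_pass_oracle(values):
    assert cv_by_row(values) == pytest.approx(two_pass_cv(values), rel=1e-12, abs=1e-15)


def test_missingness_on_complete_matrix():
    values = pd.DataFrame(
        np.full((10, 3), 5.0), index=[f"P{i}" for i in range(10)], columns=["a", "b", "c"]
    )
    s = missingness_summary(matrix_from(values), "LEF")
    assert s.n_quantified_any == s.n_unanimous == 10
    assert all(v == 0 for v in s.per_run_missing.values())


def test_missingness_recovers_planted_per_run_counts():
    """Three run-groups with high/medium/low missingness, exactly recovered."""
    cfg = SimConfig(
        seed=5,
        n_proteins=80,
        peptides_per_protein=(3, 5),
        cohorts={
            "LEF": CohortPlan(
                n_runs=9,
                run_missing_scale=(0.9,) * 3 + (0.3,) * 3 + (0.05,) * 3,
            )
        },
    )
    uni = generate_universe(cfg)
    qm, truth = simulate_quant(uni, cfg, "LEF")
    s = missingness_summary(qm, "LEF")
    quantified = truth.missing_mask.index[~truth.missing_mask.all(axis=1)]
    expected = truth.missing_mask.loc[quantified].sum(axis=0)
    assert s.per_run_missing == {r: int(expected[r]) for r in qm.run_ids}
    assert s.n_quantified_any == len(quantified)
    assert s.n_unanimous == int((~truth.missing_mask).all(axis=1).sum())
    # the three planted depth groups order the total missingness
    groups = [sum(s.per_run_missing[f"LEF_run{j:02d}"] for j in r) for r in
              (range(1, 4), range(4, 7), range(7, 10))]
    assert groups[0] > groups[1] > groups[2]


def test_missingness_unknown_cohort():
    values = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["r1", "r2"])
    with pytest.raises(Exception, match="unknown cohort"):
        missingness_summary(matrix_from(values), "nope")


def test_missingness_invariant_to_row_and_column_order(quant):
    qm, _ = quant
    s1 = missingness_summary(qm, "LEF")
    shuffled = QuantMatrix(
        values=qm.values.iloc[::-1, ::-1].copy(),
        cohorts=qm.cohorts,
        contaminant=qm.contaminant.iloc[::-1],
    )
    s2 = missingness_summary(shuffled, "LEF")
    assert s1.n_quantified_any == s2.n_quantified_any
    assert s1.n_unanimous == s2.n_unanimous
    assert s1.per_run_missing == s2.per_run_missing


def test_quintile_sizes_balance():
    assert quintile_sizes(10) == [2, 2, 2, 2, 2]
    assert quintile_sizes(13) == [3, 3, 3, 2, 2]
    for n in range(10, 40):
        sizes = quintile_sizes(n)
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1


def test_quintile_report_hand_built_ten_proteins():
    """10 proteins -> quintiles of 2; medians computable by hand."""
    runs = ["r1", "r2", "r3"]
    # summed intensities 300, 270, ..., 30: protein Pa is most intense
    rows = {}
    cvs = {}
    for i in range(10):
        base = 200.0 - 15 * i
        spread = 2.0 + i  # relative spread grows as intensity falls
        vals = [base - spread, base, base + spread]
        rows[f"P{chr(97 + i)}"] = vals
        cvs[f"P{chr(97 + i)}"] = np.std(vals, ddof=1) / np.mean(vals)
    values = pd.DataFrame.from_dict(rows, orient="index", columns=runs)
    rep = quintile_cv_report(matrix_from(values), "LEF")
    assert rep.n_unanimous == 10
    assert list(rep.per_protein.groupby("quintile").size()) == [2, 2, 2, 2, 2]
    names = sorted(rows)
    for q in range(5):
        expected = np.median([cvs[names[2 * q]], cvs[names[2 * q + 1]]])
        assert rep.quintile_median_cv[q] == pytest.approx(expected)
    assert rep.vote is True  # CV strictly increases as intensity falls


def test_quintile_vote_is_false_on_ties():
    values = pd.DataFrame(
        {"r1": [10.0] * 10, "r2": [10.0] * 10, "r3": [10.0] * 10},
        index=[f"P{i}" for i in range(10)],
    )
    # identical values -> all CVs 0 -> all medians tie -> strict vote FALSE
    rep = quintile_cv_report(matrix_from(values), "LEF")
    assert rep.quintile_median_cv == [0.0] * 5
    assert rep.vote is False


def test_quintile_report_requires_enough_unanimous_proteins():
    values = pd.DataFrame(
        np.ones((6, 3)), index=[f"P{i}" for i in range(6)], columns=["r1", "r2", "r3"]
    )
    with pytest.raises(InsufficientProteinsError, match="unanimous"):
        quintile_cv_report(matrix_from(values), "LEF")


def test_quintile_report_requires_two_runs():
    values = pd.DataFrame(np.ones((12, 1)), index=[f"P{i}" for i in range(12)], columns=["r1"])
    with pytest.raises(InsufficientProteinsError, match="at least 2"):
        quintile_cv_report(matrix_from(values), "LEF")


def test_every_unanimous_protein_in_exactly_one_quintile(quant):
    qm, _ = quant
    rep = quintile_cv_report(qm, "LEF")
    assert len(rep.per_protein) == rep.n_unanimous
    assert rep.per_protein["protein"].is_unique
    assert sum(quintile_sizes(rep.n_unanimous)) == rep.n_unanimous
    assert set(rep.per_protein["quintile"]) <= {1, 2, 3, 4, 5}


def test_vote_tally_counts():
    assert vote_tally([True, True, False]) == (2, 1)
    with pytest.raises(ValueError):
        vote_tally([])


def test_intensity_dependent_cv_votes_true():
    """With noise sd = a + b/sqrt(I), b > 0, the quintile ordering emerges."""
    cfg = SimConfig(
        seed=21,
        n_proteins=300,
        peptides_per_protein=(2, 3),
        cohorts={"C": CohortPlan(n_runs=4, run_missing_scale=(0.0,) * 4, cv_a=0.05, cv_b=25.0)},
    )
    uni = generate_universe(cfg)
    qm, _ = simulate_quant(uni, cfg, "C")
    rep = quintile_cv_report(qm, "C")
    assert rep.vote is True
    q1, q3, q5 = rep.quintile_median_cv[0], rep.quintile_median_cv[2], rep.quintile_median_cv[4]
    assert q1 < q3 < q5
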
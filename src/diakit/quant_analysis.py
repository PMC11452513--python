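"""Missingness accounting and the intensity-quintile CV vote.

Protein quantity tables are evaluated on two axes within each cohort of
replicate runs:

* **Missingness** — how many proteins have at least one reported quantity,
  and how many are *unanimous* (quantified in every run of the cohort, no
  missing cells).  When a paired spectral library is available, the count
  of identified proteins bounds both from above.

* **Reproducibility** — protein measurement noise grows as intensity
  falls, so unanimous proteins are ranked by summed intensity, split into
  five quintiles, and the median coefficient of variation (CV = sample
  standard deviation / mean, on raw intensities) is compared across the
  top, middle and bottom quintiles.  A cohort "votes" TRUE when
  median CV(Q1) < median CV(Q3) < median CV(Q5), with Q1 the
  highest-intensity quintile.  Under a null with no intensity-CV
  relationship, the three medians are exchangeable, so one cohort in six is
  expected to vote TRUE by chance; ties vote FALSE (strict inequalities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .quant_io import QuantMatrix

N_QUINTILES = 5
#: Quintiles compared by the vote: top, middle, bottom (0-based indices).
VOTE_QUINTILES = (0, 2, 4)
MIN_UNANIMOUS = 10


class InsufficientProteinsError(ValueError):
    """Too few unanimous proteins to form meaningful quintiles.

    Raised instead of returning a silently empty report: sparse cohorts
    (negative-control pull-downs especially) routinely defeat quantitation.
    """


@dataclass(frozen=True)
class MissingnessSummary:
    """Identified / quantified / unanimous protein counts for one cohort."""

    cohort: str
    n_quantified_any: int
    n_unanimous: int
    per_run_missing: dict[str, int]
    n_identified: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_unanimous > self.n_quantified_any:
            raise ValueError("unanimous proteins cannot exceed quantified proteins")
        if self.n_identified is not None and self.n_quantified_any > self.n_identified:
            raise ValueError("quantified proteins cannot exceed identified proteins")


def missingness_summary(
    qm: QuantMatrix,
    cohort: str,
    identified: Optional[set[str]] = None,
) -> MissingnessSummary:
    """Count quantified-in-any and unanimous proteins for one cohort.

    Per-run missing counts are restricted to proteins quantified in at
    least one run of the cohort (a protein absent from the whole cohort is
    not "missing" in any particular run of it).
    """
    runs = qm.runs_in_cohort(cohort)
    sub = qm.values[runs]
    present = sub.notna()
    any_mask = present.any(axis=1)
    quantified = sub[any_mask]
    per_run = (~quantified.notna()).sum(axis=0)
    return MissingnessSummary(
        cohort=cohort,
        n_quantified_any=int(any_mask.sum()),
        n_unanimous=int(present.all(axis=1).sum()),
        per_run_missing={run: int(per_run[run]) for run in runs},
        n_identified=None if identified is None else len(identified),
    )


def cv_by_row(values: Sequence[float]) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean.

    The caller excludes rows with missing values; requires >= 2 values and
    a strictly positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"need at least 2 values, got {arr.size}")
    if np.isnan(arr).any():
        raise ValueError("missing values must be excluded before computing a CV")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    return float(arr.std(ddof=1) / mean)


def quintile_sizes(n: int, k: int = N_QUINTILES) -> list[int]:
    """Split n into k contiguous group sizes differing by at most 1.

    The remainder goes to the top (highest-intensity) groups.
    """
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


@dataclass
class QuintileCVReport:
    """Per-quintile median CVs and the monotonicity vote for one cohort.

    ``quintile_median_cv`` is ordered from the highest-intensity quintile
    (Q1) to the lowest (Q5).  ``per_protein`` has one row per unanimous
    protein: protein, summed_intensity, cv, quintile (1..5).
    """

    cohort: str
    n_unanimous: int
    quintile_median_cv: list[float]
    vote: bool
    per_protein: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.quintile_median_cv) != N_QUINTILES:
            raise ValueError("expected five quintile medians")
        if any(cv < 0 for cv in self.quintile_median_cv):
            raise ValueError("CVs cannot be negative")


def quintile_cv_report(
    qm: QuantMatrix,
    cohort: str,
    *,
    min_unanimous: int = MIN_UNANIMOUS,
) -> QuintileCVReport:
    """Rank unanimous proteins by summed intensity and vote on CV ordering.

    Proteins quantified in every run of ``cohort`` are sorted by the sum of
    their intensities (descending; ties broken by protein label so the
    ranking is deterministic), split into five contiguous quintiles with
    sizes as equal as possible, and the median CV of each quintile is
    computed.  The vote is TRUE iff the top quintile's median CV is
    strictly below the middle quintile's, which is strictly below the
    bottom quintile's.
    """
    runs = qm.runs_in_cohort(cohort)
    if len(runs) < 2:
        raise InsufficientProteinsError(
            f"cohort {cohort!r} has {len(runs)} run(s); CVs need at least 2"
        )
    sub = qm.values[runs]
    unanimous = sub[sub.notna().all(axis=1)]
    n = len(unanimous)
    if n < min_unanimous:
        raise InsufficientProteinsError(
            f"cohort {cohort!r} has only {n} unanimous protein(s); "
            f"need >= {min_unanimous} for a quintile analysis"
        )

    summed = unanimous.sum(axis=1)
    order = pd.DataFrame({"protein": unanimous.index, "summed_intensity": summed.values})
    order = order.sort_values(
        ["summed_intensity", "protein"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)

    arr = unanimous.loc[order["protein"]].to_numpy(dtype=float)
    cvs = arr.std(axis=1, ddof=1) / arr.mean(axis=1)
    order["cv"] = cvs

    sizes = quintile_sizes(n)
    quintile = np.repeat(np.arange(1, N_QUINTILES + 1), sizes)
    order["quintile"] = quintile

    medians = [float(np.median(order.loc[order["quintile"] == q + 1, "cv"])) for q in range(N_QUINTILES)]
    q1, q3, q5 = (medians[i] for i in VOTE_QUINTILES)
    vote = bool(q1 < q3 < q5)
    return QuintileCVReport(
        cohort=cohort,
        n_unanimous=n,
        quintile_median_cv=medians,
        vote=vote,
        per_protein=order,
    )


def vote_tally(reports: Iterable[QuintileCVReport | bool]) -> tuple[int, int]:
    """Count TRUE and FALSE quintile-CV votes across cohorts."""
    votes = [r.vote if isinstance(r, QuintileCVReport) else bool(r) for r in reports]
    if not votes:
        raise ValueError("need at least one report to tally")
    n_true = sum(votes)
    return n_true, len(votes) - n_true


# ---------------------------------------------------------------------------
# tabular output


def write_missingness_tsv(summaries: Iterable[MissingnessSummary], path: str | Path) -> None:
    recs = []
    for s in sorted(summaries, key=lambda s: s.cohort):
        recs.append(
            {
                "cohort": s.cohort,
                "n_identified": "" if s.n_identified is None else s.n_identified,
                "n_quantified_any": s.n_quantified_any,
                "n_unanimous": s.n_unanimous,
                "per_run_missing": ";".join(f"{r}={m}" for r, m in s.per_run_missing.items()),
            }
        )
    pd.DataFrame(
        recs,
        columns=["cohort", "n_identified", "n_quantified_any", "n_unanimous", "per_run_missing"],
    ).to_csv(path, sep="\t", index=False)


def write_quintile_report_tsv(report: QuintileCVReport, path: str | Path) -> None:
    df = report.per_protein.sort_values(["quintile", "protein"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def write_vote_tally_json(
    reports: Iterable[QuintileCVReport], path: str | Path
) -> dict:
    reports = list(reports)
    n_true, n_false = vote_tally(reports)
    payload = {
        "n_true": n_true,
        "n_false": n_false,
        "cohorts": {
            r.cohort: {"vote": r.vote, "quintile_median_cv": r.quintile_median_cv}
            for r in sorted(reports, key=lambda r: r.cohort)
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return payload
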
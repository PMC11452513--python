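"""Readers for protein quantity tables from the four DIA workflows.

Each workflow reports protein-level quantities in its own layout:

=======================  ================================  =================
workflow                 export file                       layout
=======================  ================================  =================
DIA-NN / FragPipe-DIA    ``report.pg_matrix.tsv``          wide, one column per run
MaxQuant                 ``proteinGroups.txt``             wide, ``Intensity <run>`` columns
Spectronaut              ``Report.tsv``                    long, (run, protein, quantity)
FragPipe LFQ-MBR         ``combined_protein.tsv``          wide, ``<run> Intensity`` /
                                                           ``<run> MaxLFQ Intensity``
=======================  ================================  =================

All are reduced to a :class:`QuantMatrix`: a protein x run table of
nonnegative intensities with an explicit missing state (NaN), contaminant /
decoy flags, and a cohort label for every run.  Most DIA software
distinguishes "no viable chromatogram" (a blank or a reported 0) from a
detected chromatogram (positive intensity); by default zeros are therefore
mapped to missing, switchable with ``zeros_as_missing=False``.

No normalization, imputation or batch correction is performed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library_io import DECOY_PREFIX, DEFAULT_CONTAMINANT_PREFIXES

logger = logging.getLogger(__name__)

QUANT_DIALECTS = ("pg_matrix", "maxquant", "spectronaut", "fragpipe_combined")

#: Default (run, protein group, quantity) column triple for Spectronaut
#: report exports; the template is configurable because Spectronaut report
#: schemas vary with the chosen report template.
SPECTRONAUT_COLUMNS = ("R.FileName", "PG.ProteinGroups", "PG.Quantity")


class QuantParseError(ValueError):
    """Raised when a quantity table cannot be parsed under its dialect."""


class CohortError(ValueError):
    """Raised when run columns cannot be assigned to cohorts."""


@dataclass
class QuantMatrix:
    """Protein-by-run intensity matrix with explicit missingness.

    ``values`` is a float DataFrame (rows = protein groups, columns = runs)
    where NaN marks a missing quantity; every stored number is >= 0.
    ``contaminant`` flags sample-handling contaminants (retained, never
    silently dropped); decoy rows are removed at parse time.
    """

    values: pd.DataFrame
    cohorts: dict[str, str]
    genes: Optional[pd.Series] = None
    contaminant: Optional[pd.Series] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise QuantParseError(f"duplicate protein-group labels: {dup[:5]}")
        if self.values.columns.has_duplicates:
            raise QuantParseError("duplicate run labels")
        missing_cohort = [r for r in self.values.columns if r not in self.cohorts]
        if missing_cohort:
            raise CohortError(f"runs without a cohort: {missing_cohort}")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise QuantParseError("negative intensities are not meaningful")
        if self.contaminant is None:
            self.contaminant = pd.Series(False, index=self.values.index)
        if self.genes is not None:
            self.genes = self.genes.reindex(self.values.index)

    # -- basic accessors ---------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def runs_in_cohort(self, cohort: str) -> list[str]:
        runs = [r for r in self.values.columns if self.cohorts[r] == cohort]
        if not runs:
            raise CohortError(f"unknown cohort {cohort!r}; known: {sorted(set(self.cohorts.values()))}")
        return runs

    def cohort_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.values.columns:
            seen.setdefault(self.cohorts[r], None)
        return list(seen)


def assign_cohorts(run_ids: Sequence[str], cohort_map: Mapping[str, str]) -> dict[str, str]:
    """Assign each run to a cohort by exact name, else unique substring match.

    ``cohort_map`` maps a run name or run-name pattern to a cohort label.
    Raises :class:`CohortError` listing any unmatched run columns.
    """
    out: dict[str, str] = {}
    unmatched: list[str] = []
    for run in run_ids:
        if run in cohort_map:
            out[run] = cohort_map[run]
            continue
        hits = {cohort for pat, cohort in cohort_map.items() if pat in run}
        if len(hits) == 1:
            out[run] = hits.pop()
        else:
            unmatched.append(run)
    if unmatched:
        raise CohortError(
            f"run columns with no (or ambiguous) cohort assignment: {unmatched}"
        )
    return out


def _clean_values(df: pd.DataFrame, zeros_as_missing: bool) -> pd.DataFrame:
    vals = df.apply(pd.to_numeric, errors="coerce").astype(float)
    if zeros_as_missing:
        vals = vals.where(vals != 0.0)
    return vals


def _flag_contaminants(index: pd.Index, prefixes: Sequence[str]) -> pd.Series:
    return pd.Series(
        [any(part.startswith(tuple(prefixes)) for part in str(p).split(";")) for p in index],
        index=index,
    )


def _drop_decoys(df: pd.DataFrame, id_col: str) -> pd.DataFrame:
    keep = ~df[id_col].astype(str).str.startswith(DECOY_PREFIX)
    return df[keep]


def read_pg_matrix(
    path: str | Path,
    cohort_map: Mapping[str, str],
    *,
    zeros_as_missing: bool = True,
    contaminant_prefixes: Sequence[str] = DEFAULT_CONTAMINANT_PREFIXES,
) -> QuantMatrix:
    """Read a DIA-NN / FragPipe ``report.pg_matrix.tsv`` (wide) table.

    Annotation columns (Protein.Group, Protein.Ids, Protein.Names, Genes,
    First.Protein.Description) are recognized by name; every remaining
    column is treated as a run.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise QuantParseError(f"{path}: empty table")
    meta_norm = {
        "proteingroup": "id",
        "proteinids": None,
        "proteinnames": None,
        "genes": "genes",
        "firstproteindescription": None,
    }
    from .library_io import _norm_header

    id_col = genes_col = None
    run_cols: list[str] = []
    for c in df.columns:
        norm = _norm_header(c)
        if norm in meta_norm:
            if meta_norm[norm] == "id":
                id_col = c
            elif meta_norm[norm] == "genes":
                genes_col = c
        else:
            run_cols.append(c)
    if id_col is None:
        id_col = df.columns[0]
        run_cols = [c for c in run_cols if c != id_col]
    if not run_cols:
        raise QuantParseError(f"{path}: no run columns found")

    df = _drop_decoys(df, id_col)
    values = _clean_values(df[run_cols], zeros_as_missing)
    values.index = pd.Index(df[id_col].astype(str), name="protein_group")
    genes = df[genes_col].astype(str).set_axis(values.index) if genes_col else None
    return QuantMatrix(
        values=values,
        cohorts=assign_cohorts(run_cols, cohort_map),
        genes=genes,
        contaminant=_flag_contaminants(values.index, contaminant_prefixes),
        source=str(path),
    )


def read_maxquant_protein_groups(
    path: str | Path,
    cohort_map: Mapping[str, str],
    *,
    zeros_as_missing: bool = True,
    intensity_prefix: str = "Intensity ",
    contaminant_prefixes: Sequence[str] = DEFAULT_CONTAMINANT_PREFIXES,
) -> QuantMatrix:
    """Read a MaxQuant ``proteinGroups.txt`` table.

    Rows flagged ``Reverse`` or ``Only identified by site`` are dropped;
    ``Potential contaminant`` rows are retained and flagged.  Run columns
    are the ``Intensity <run>`` family (the bare summed ``Intensity`` column
    is ignored); the prefix is configurable.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise QuantParseError(f"{path}: empty table")
    from .library_io import _norm_header

    by_norm = {_norm_header(c): c for c in df.columns}
    id_col = by_norm.get("proteinids")
    if id_col is None:
        raise QuantParseError(f"{path}: 'Protein IDs' column absent")
    genes_col = by_norm.get("genenames")

    for flag in ("reverse", "onlyidentifiedbysite"):
        col = by_norm.get(flag)
        if col is not None:
            df = df[df[col].astype(str).str.strip() != "+"]
    df = _drop_decoys(df, id_col)

    run_cols = [
        c for c in df.columns if c.startswith(intensity_prefix) and c != intensity_prefix.strip()
    ]
    if not run_cols:
        raise QuantParseError(f"{path}: no '{intensity_prefix}<run>' columns found")
    run_names = {c: c[len(intensity_prefix):] for c in run_cols}

    values = _clean_values(df[run_cols], zeros_as_missing).rename(columns=run_names)
    values.index = pd.Index(df[id_col].astype(str), name="protein_group")

    contam = _flag_contaminants(values.index, contaminant_prefixes)
    contam_col = by_norm.get("potentialcontaminant") or by_norm.get("contaminant")
    if contam_col is not None:
        contam |= (df[contam_col].astype(str).str.strip() == "+").set_axis(values.index)
    genes = df[genes_col].astype(str).set_axis(values.index) if genes_col else None
    return QuantMatrix(
        values=values,
        cohorts=assign_cohorts(list(values.columns), cohort_map),
        genes=genes,
        contaminant=contam,
        source=str(path),
    )


def read_spectronaut_report(
    path: str | Path,
    cohort_map: Mapping[str, str],
    *,
    zeros_as_missing: bool = True,
    columns: tuple[str, str, str] = SPECTRONAUT_COLUMNS,
    contaminant_prefixes: Sequence[str] = DEFAULT_CONTAMINANT_PREFIXES,
) -> QuantMatrix:
    """Read a Spectronaut long-format ``Report.tsv`` and pivot it wide.

    ``columns`` names the (run, protein group, quantity) triple of the
    export template.  A (run, protein) pair reported twice with conflicting
    values is an error; absent pairs become missing cells.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    run_c, prot_c, qty_c = columns
    for c in columns:
        if c not in df.columns:
            raise QuantParseError(f"{path}: required column {c!r} absent")
    df = _drop_decoys(df, prot_c)
    df = df[[run_c, prot_c, qty_c]].copy()
    df[qty_c] = pd.to_numeric(df[qty_c], errors="coerce")

    dup = df.duplicated([run_c, prot_c], keep=False)
    if dup.any():
        spans = df[dup].groupby([run_c, prot_c])[qty_c].agg(["min", "max"])
        conflicts = spans[(spans["max"] - spans["min"]).abs() > 1e-9]
        if len(conflicts):
            raise QuantParseError(
                f"{path}: conflicting duplicate (run, protein) pairs: "
                f"{conflicts.index.tolist()[:5]}"
            )
        df = df.drop_duplicates([run_c, prot_c])

    values = df.pivot(index=prot_c, columns=run_c, values=qty_c).astype(float)
    values.index = values.index.astype(str)
    values.index.name = "protein_group"
    values.columns = [str(c) for c in values.columns]
    if zeros_as_missing:
        values = values.where(values != 0.0)
    with np.errstate(invalid="ignore"):
        values = values.where(values >= 0)
    return QuantMatrix(
        values=values,
        cohorts=assign_cohorts(list(values.columns), cohort_map),
        contaminant=_flag_contaminants(values.index, contaminant_prefixes),
        source=str(path),
    )


def read_fragpipe_combined_protein(
    path: str | Path,
    cohort_map: Mapping[str, str],
    *,
    intensity_kind: str = "intensity",
    zeros_as_missing: bool = True,
    contaminant_prefixes: Sequence[str] = DEFAULT_CONTAMINANT_PREFIXES,
) -> QuantMatrix:
    """Read a FragPipe ``combined_protein.tsv`` table.

    FragPipe reports two per-run column families, ``<run> Intensity`` and
    ``<run> MaxLFQ Intensity``.  ``intensity_kind`` selects ``"intensity"``
    (default: the MaxLFQ family carries more missing values) or
    ``"maxlfq"``.
    """
    if intensity_kind not in ("intensity", "maxlfq"):
        raise ValueError("intensity_kind must be 'intensity' or 'maxlfq'")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise QuantParseError(f"{path}: empty table")
    from .library_io import _norm_header

    by_norm = {_norm_header(c): c for c in df.columns}
    id_col = by_norm.get("protein") or by_norm.get("proteinid")
    if id_col is None:
        raise QuantParseError(f"{path}: 'Protein' column absent")
    genes_col = by_norm.get("gene")

    maxlfq_cols = [c for c in df.columns if c.endswith(" MaxLFQ Intensity")]
    plain_cols = [
        c for c in df.columns if c.endswith(" Intensity") and not c.endswith(" MaxLFQ Intensity")
    ]
    # summary columns like "Combined Total Intensity" are not runs
    plain_cols = [c for c in plain_cols if not c.startswith(("Combined", "Total", "Summarized"))]
    if intensity_kind == "intensity":
        run_cols = plain_cols
        suffix = " Intensity"
    else:
        run_cols = maxlfq_cols
        suffix = " MaxLFQ Intensity"
    if not run_cols:
        raise QuantParseError(f"{path}: no '<run>{suffix}' columns found")
    run_names = {c: c[: -len(suffix)] for c in run_cols}

    df = _drop_decoys(df, id_col)
    values = _clean_values(df[run_cols], zeros_as_missing).rename(columns=run_names)
    values.index = pd.Index(df[id_col].astype(str), name="protein_group")
    genes = df[genes_col].astype(str).set_axis(values.index) if genes_col else None
    return QuantMatrix(
        values=values,
        cohorts=assign_cohorts(list(values.columns), cohort_map),
        genes=genes,
        contaminant=_flag_contaminants(values.index, contaminant_prefixes),
        source=str(path),
    )


READERS = {
    "pg_matrix": read_pg_matrix,
    "maxquant": read_maxquant_protein_groups,
    "spectronaut": read_spectronaut_report,
    "fragpipe_combined": read_fragpipe_combined_protein,
}


def read_quant(path: str | Path, dialect: str, cohort_map: Mapping[str, str], **kwargs) -> QuantMatrix:
    """Dispatch to the reader for ``dialect`` (one of :data:`QUANT_DIALECTS`)."""
    try:
        reader = READERS[dialect]
    except KeyError:
        raise ValueError(f"unknown quant dialect {dialect!r}; expected one of {QUANT_DIALECTS}")
    return reader(path, cohort_map, **kwargs)


def write_harmonized_matrix(qm: QuantMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (proteins x runs, empty cell = missing) plus a
    ``<prefix>.json`` sidecar carrying cohorts, genes and contaminant flags."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    sidecar = prefix.with_suffix(".json")
    qm.values.to_csv(tsv, sep="\t", na_rep="")
    meta = {
        "cohorts": qm.cohorts,
        "genes": None if qm.genes is None else {k: v for k, v in qm.genes.items()},
        "contaminant": [p for p, f in qm.contaminant.items() if f],
        "source": qm.source,
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return tsv, sidecar


def read_harmonized_matrix(prefix: str | Path) -> QuantMatrix:
    """Read a matrix written by :func:`write_harmonized_matrix`."""
    prefix = Path(prefix)
    values = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t", index_col=0).astype(float)
    values.index = values.index.astype(str)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    genes = pd.Series(meta["genes"]) if meta.get("genes") else None
    contam = pd.Series(
        [p in set(meta.get("contaminant", [])) for p in values.index], index=values.index
    )
    return QuantMatrix(
        values=values,
        cohorts=dict(meta["cohorts"]),
        genes=genes,
        contaminant=contam,
        source=meta.get("source", str(prefix)),
    )
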
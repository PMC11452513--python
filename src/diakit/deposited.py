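"""Recompute the headline statistics from the study's deposited outputs.

The multi-workflow comparison deposits, alongside the raw data, the search
engines' *output* spectral libraries and protein quantity tables.  Given a
local directory containing those files, this module re-derives the
downstream statistics with this package's own readers and statistics:

* distinct-peptide diversity per library;
* the six-library exact-intersection table for one experiment, including
  the all-libraries count and the DDA-only / DIA-only totals;
* unanimous-protein counts per quantity table;
* the quintile-CV vote tally over all cohorts of a vendor's tables.

The deposited archive is several hundred megabytes and must be downloaded
separately; nothing here fetches data.  Expected layout (all files
tab-separated text, any subset may be present)::

    <root>/libraries/<name>.<engine-export>     e.g. ip_inputs_C.MaxQuant.evidence.txt
    <root>/quant/<name>.<dialect-export>        e.g. spion_LEF.DIANN.report.pg_matrix.tsv
    <root>/quant/cohorts.yaml                   run-name pattern -> cohort, per table

File stems encode ``<dataset>.<Engine>-<Mode>`` so provenance can be
reconstructed; see :func:`scan_deposited`.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import yaml

from .diversity import diversity_stats, intersection_counts, mode_only_counts
from .library_io import LibraryProvenance, SpectralLibrary, detect_dialect, read_library
from .quant_analysis import (
    InsufficientProteinsError,
    missingness_summary,
    quintile_cv_report,
    vote_tally,
)
from .quant_io import read_quant

_STEM_RE = re.compile(r"^(?P<dataset>.+?)\.(?P<engine>DIANN|FragPipe|MaxQuant|Spectronaut)-(?P<mode>DDA|DIA)")


def scan_deposited(root: str | Path) -> dict[str, list[Path]]:
    """Inventory a deposited-outputs directory.

    Returns ``{"libraries": [...], "quant": [...]}`` with the recognized
    files under ``<root>/libraries`` and ``<root>/quant``.
    """
    root = Path(root)
    out = {"libraries": [], "quant": []}
    lib_dir = root / "libraries"
    if lib_dir.is_dir():
        out["libraries"] = sorted(
            p for p in lib_dir.iterdir() if p.suffix in (".tsv", ".txt") and _STEM_RE.match(p.stem)
        )
    quant_dir = root / "quant"
    if quant_dir.is_dir():
        out["quant"] = sorted(
            p
            for p in quant_dir.iterdir()
            if p.suffix in (".tsv", ".txt") and p.name != "cohorts.yaml"
        )
    return out


def _provenance_from_stem(stem: str) -> Optional[LibraryProvenance]:
    m = _STEM_RE.match(stem)
    if not m:
        return None
    return LibraryProvenance(
        engine=m["engine"], acquisition=m["mode"], dataset=m["dataset"]
    )


def load_deposited_libraries(root: str | Path, dataset: str) -> list[SpectralLibrary]:
    """Read every deposited library of one dataset, auto-detecting dialects."""
    libs = []
    for path in scan_deposited(root)["libraries"]:
        prov = _provenance_from_stem(path.stem)
        if prov is None or prov.dataset != dataset:
            continue
        libs.append(
            read_library(
                path,
                dialect=detect_dialect(path),
                provenance=prov,
                name=f"{prov.engine}-{prov.acquisition}",
            )
        )
    return libs


def recompute_deposited_statistics(
    root: str | Path,
    *,
    intersection_dataset: str = "ip_inputs_C",
    key_kind: str = "stripped",
) -> dict:
    """Re-derive every deposited-data statistic available under ``root``.

    Returns a dict with per-library peptide diversities, the intersection
    analysis for ``intersection_dataset`` (all-libraries count plus
    DDA-only / DIA-only totals, under the requested peptide key), and
    per-table unanimous counts and quintile-CV votes.  Keying sensitivity:
    when ``key_kind="stripped"`` the same intersection is also computed on
    modified-sequence keys so the two conventions can be compared.
    """
    root = Path(root)
    inventory = scan_deposited(root)
    if not inventory["libraries"] and not inventory["quant"]:
        raise FileNotFoundError(
            f"{root}: no deposited libraries or quantity tables found "
            "(expected <root>/libraries and <root>/quant)"
        )
    result: dict = {"diversity": {}, "intersections": {}, "quant": {}}

    by_dataset: dict[str, list[SpectralLibrary]] = {}
    for path in inventory["libraries"]:
        prov = _provenance_from_stem(path.stem)
        if prov is None:
            continue
        lib = read_library(path, detect_dialect(path), prov, name=f"{prov.engine}-{prov.acquisition}")
        by_dataset.setdefault(prov.dataset, []).append(lib)
        result["diversity"][f"{prov.dataset}.{lib.name}"] = diversity_stats(lib).n_peptides

    libs = by_dataset.get(intersection_dataset, [])
    if len(libs) >= 2:
        table = intersection_counts(libs, key_kind)
        all_bits = (1 << len(libs)) - 1
        mode_of = {l.name: l.provenance.acquisition for l in libs}
        dda_only, dia_only = mode_only_counts(table, mode_of)
        result["intersections"][intersection_dataset] = {
            "key_kind": key_kind,
            "n_libraries": len(libs),
            "all_libraries": table.rows.get(all_bits, 0),
            "dda_only": dda_only,
            "dia_only": dia_only,
            "per_library": {l.name: table.marginal(l.name) for l in libs},
        }
        if key_kind == "stripped":
            alt = intersection_counts(libs, "modified")
            result["intersections"][f"{intersection_dataset}__modified_keys"] = {
                "all_libraries": alt.rows.get(all_bits, 0),
                "dda_only": mode_only_counts(alt, mode_of)[0],
                "dia_only": mode_only_counts(alt, mode_of)[1],
            }

    cohorts_file = root / "quant" / "cohorts.yaml"
    cohort_cfg = yaml.safe_load(cohorts_file.read_text()) if cohorts_file.exists() else {}
    votes = []
    for path in inventory["quant"]:
        entry = cohort_cfg.get(path.name, {})
        dialect = entry.get("dialect", "pg_matrix")
        cohort_map = dict(entry.get("cohort_map", {}))
        if not cohort_map:
            continue
        qm = read_quant(path, dialect, cohort_map)
        per_table: dict = {}
        for cohort in qm.cohort_names():
            summary = missingness_summary(qm, cohort)
            per_table[cohort] = {
                "n_quantified_any": summary.n_quantified_any,
                "n_unanimous": summary.n_unanimous,
            }
            try:
                rep = quintile_cv_report(qm, cohort)
            except InsufficientProteinsError:
                continue
            per_table[cohort]["vote"] = rep.vote
            votes.append(rep)
        result["quant"][path.name] = per_table
    if votes:
        n_true, n_false = vote_tally(votes)
        result["vote_tally"] = {"n_true": n_true, "n_false": n_false}
    return result
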
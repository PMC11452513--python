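"""Manifest-driven orchestration of the full analysis.

A YAML manifest names a dataset, its spectral-library files (with workflow,
acquisition mode and cohort), its quantity tables (with dialect and a
run-to-cohort map), and which analysis stages to run.  ``run_manifest``
executes the enabled stages — diversity, intersections, missingness,
quintile-CV voting, window design — writing one deterministic TSV/JSON per
stage plus a timestamped log.  A failure in one stage is recorded and does
not abort independent stages: when one software workflow's table defeats a
parser or has too few unanimous proteins, the rest of the report is still
produced.

Example manifest::

    dataset: demo
    libraries:
      - path: fixtures/DIANN-DIA.report-lib.tsv
        engine: DIANN
        acquisition: DIA
        cohort: C
      - path: fixtures/MaxQuant-DDA.evidence.txt
        engine: MaxQuant
        acquisition: DDA
        cohort: C
    quant_tables:
      - path: fixtures/DIANN.report.pg_matrix.tsv
        dialect: pg_matrix
        cohort_map: {LEF: LEF}
    analyses: [diversity, intersections, quant_stats, cv_quintiles, windows]
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import diversity as _div
from . import quant_analysis as _qa
from .library_io import LibraryProvenance, SpectralLibrary, read_library
from .quant_io import QUANT_DIALECTS, QuantMatrix, read_quant
from .window_designer import DesignConfig, design_windows, write_scheme_tsv

logger = logging.getLogger(__name__)

ALL_STAGES = ("diversity", "intersections", "quant_stats", "cv_quintiles", "windows")


class ManifestError(ValueError):
    """Raised when a manifest is invalid before any stage runs."""


@dataclass
class LibrarySpec:
    path: Path
    engine: str
    acquisition: str
    cohort: str = ""
    dataset: str = ""
    dialect: str = "auto"
    name: Optional[str] = None


@dataclass
class QuantSpec:
    path: Path
    dialect: str
    cohort_map: dict[str, str]
    intensity_kind: str = "intensity"
    zeros_as_missing: bool = True
    label: Optional[str] = None


@dataclass
class Manifest:
    dataset: str
    libraries: list[LibrarySpec] = field(default_factory=list)
    quant_tables: list[QuantSpec] = field(default_factory=list)
    analyses: tuple[str, ...] = ALL_STAGES
    window_config: DesignConfig = field(default_factory=DesignConfig)
    intersection_key: str = "stripped"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Manifest":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        libs = [
            LibrarySpec(
                path=(base / e["path"]).resolve(),
                engine=e["engine"],
                acquisition=e["acquisition"],
                cohort=e.get("cohort", ""),
                dataset=e.get("dataset", raw.get("dataset", "")),
                dialect=e.get("dialect", "auto"),
                name=e.get("name"),
            )
            for e in raw.get("libraries", [])
        ]
        quants = [
            QuantSpec(
                path=(base / e["path"]).resolve(),
                dialect=e["dialect"],
                cohort_map=dict(e.get("cohort_map", {})),
                intensity_kind=e.get("intensity_kind", "intensity"),
                zeros_as_missing=bool(e.get("zeros_as_missing", True)),
                label=e.get("label"),
            )
            for e in raw.get("quant_tables", [])
        ]
        wc = raw.get("windows", {})
        return cls(
            dataset=raw.get("dataset", "unnamed"),
            libraries=libs,
            quant_tables=quants,
            analyses=tuple(raw.get("analyses", ALL_STAGES)),
            window_config=DesignConfig(
                n_windows=int(wc.get("n_windows", 30)),
                peak_width_s=float(wc.get("peak_width_s", 30.0)),
                ms2_rate_hz=float(wc.get("ms2_rate_hz", 10.0)),
                mz_floor=wc.get("mz_floor"),
                mz_ceiling=wc.get("mz_ceiling"),
            ),
            intersection_key=raw.get("intersection_key", "stripped"),
        )

    def validate(self) -> None:
        """Reject an invalid manifest before any stage runs."""
        unknown = [s for s in self.analyses if s not in ALL_STAGES]
        if unknown:
            raise ManifestError(f"unknown analysis stage(s) {unknown}; known: {ALL_STAGES}")
        for spec in self.libraries:
            if not spec.path.exists():
                raise ManifestError(f"library file not found: {spec.path}")
            LibraryProvenance(engine=spec.engine, acquisition=spec.acquisition)
        for spec in self.quant_tables:
            if not spec.path.exists():
                raise ManifestError(f"quant table not found: {spec.path}")
            if spec.dialect not in QUANT_DIALECTS:
                raise ManifestError(
                    f"unknown quant dialect {spec.dialect!r}; known: {QUANT_DIALECTS}"
                )
        names = [s.name or f"{s.engine}-{s.acquisition}" for s in self.libraries]
        if len(set(names)) != len(names):
            raise ManifestError(f"duplicate library names: {names}")


@dataclass
class StageResult:
    status: str  # "ok" | "failed" | "skipped"
    outputs: list[Path] = field(default_factory=list)
    error: str = ""


@dataclass
class RunReport:
    out_dir: Path
    stages: dict[str, StageResult]

    @property
    def ok(self) -> bool:
        return all(r.status != "failed" for r in self.stages.values())


def _log_line(fh, msg: str) -> None:
    stamp = time.strftime("%Y-%m-%d %H:%M:%S")
    fh.write(f"[{stamp}] {msg}\n")
    logger.info(msg)


def run_manifest(manifest: Manifest, out_dir: str | Path) -> RunReport:
    """Run every enabled stage, writing one report bundle to ``out_dir``.

    Output tables are sorted on explicit keys (library name, pattern
    bitstring, protein id) so re-running an identical manifest yields
    byte-identical files.
    """
    manifest.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, StageResult] = {}

    with open(out_dir / "log.txt", "w", encoding="utf-8") as log:
        _log_line(log, f"dataset={manifest.dataset} stages={','.join(manifest.analyses)}")

        libraries: list[SpectralLibrary] = []
        for spec in manifest.libraries:
            try:
                lib = read_library(
                    spec.path,
                    dialect=None if spec.dialect == "auto" else spec.dialect,
                    provenance=LibraryProvenance(
                        engine=spec.engine,
                        acquisition=spec.acquisition,
                        dataset=spec.dataset,
                        cohort=spec.cohort,
                    ),
                    name=spec.name,
                )
                libraries.append(lib)
                st = lib.read_stats
                _log_line(
                    log,
                    f"read library {lib.name}: {len(lib)} precursors "
                    f"(rows={st.n_rows} invalid={st.n_invalid} decoys={st.n_decoys} "
                    f"duplicates={st.n_duplicates})",
                )
            except Exception as exc:  # stage-isolated failure
                _log_line(log, f"FAILED reading library {spec.path.name}: {exc}")
                stages[f"read:{spec.path.name}"] = StageResult("failed", error=str(exc))

        matrices: list[tuple[QuantSpec, QuantMatrix]] = []
        for spec in manifest.quant_tables:
            try:
                kwargs = {"zeros_as_missing": spec.zeros_as_missing}
                if spec.dialect == "fragpipe_combined":
                    kwargs["intensity_kind"] = spec.intensity_kind
                qm = read_quant(spec.path, spec.dialect, spec.cohort_map, **kwargs)
                matrices.append((spec, qm))
                _log_line(
                    log,
                    f"read quant {spec.path.name}: {len(qm.protein_ids)} proteins x "
                    f"{len(qm.run_ids)} runs, {qm.n_missing()} missing",
                )
            except Exception as exc:
                _log_line(log, f"FAILED reading quant {spec.path.name}: {exc}")
                stages[f"read:{spec.path.name}"] = StageResult("failed", error=str(exc))

        if "diversity" in manifest.analyses:
            try:
                if not libraries:
                    raise ValueError("no libraries were read")
                out = out_dir / "diversity.tsv"
                _div.write_diversity_tsv([_div.diversity_stats(l) for l in libraries], out)
                stages["diversity"] = StageResult("ok", [out])
                _log_line(log, f"diversity: wrote {out.name}")
            except Exception as exc:
                stages["diversity"] = StageResult("failed", error=str(exc))
                _log_line(log, f"FAILED diversity: {exc}")

        if "intersections" in manifest.analyses:
            try:
                if len(libraries) < 2:
                    raise ValueError("intersections need at least two readable libraries")
                table = _div.intersection_counts(libraries, manifest.intersection_key)
                out = out_dir / f"intersections_{manifest.intersection_key}.tsv"
                _div.write_intersection_tsv(table, out)
                mode_of = {l.name: l.provenance.acquisition for l in libraries}
                dda_only, dia_only = _div.mode_only_counts(table, mode_of)
                side = out_dir / "mode_only.json"
                side.write_text(json.dumps({"dda_only": dda_only, "dia_only": dia_only}, indent=1))
                stages["intersections"] = StageResult("ok", [out, side])
                _log_line(
                    log,
                    f"intersections: {table.union_size()} keys, "
                    f"dda_only={dda_only} dia_only={dia_only}",
                )
            except Exception as exc:
                stages["intersections"] = StageResult("failed", error=str(exc))
                _log_line(log, f"FAILED intersections: {exc}")

        if "quant_stats" in manifest.analyses:
            try:
                if not matrices:
                    raise ValueError("no quant tables were read")
                summaries = []
                for spec, qm in matrices:
                    for cohort in qm.cohort_names():
                        summaries.append(_qa.missingness_summary(qm, cohort))
                out = out_dir / "missingness.tsv"
                _qa.write_missingness_tsv(summaries, out)
                stages["quant_stats"] = StageResult("ok", [out])
                _log_line(log, f"quant_stats: {len(summaries)} cohort summaries")
            except Exception as exc:
                stages["quant_stats"] = StageResult("failed", error=str(exc))
                _log_line(log, f"FAILED quant_stats: {exc}")

        if "cv_quintiles" in manifest.analyses:
            try:
                if not matrices:
                    raise ValueError("no quant tables were read")
                reports = []
                for spec, qm in matrices:
                    label = spec.label or spec.path.stem
                    for cohort in qm.cohort_names():
                        try:
                            rep = _qa.quintile_cv_report(qm, cohort)
                        except _qa.InsufficientProteinsError as exc:
                            _log_line(log, f"cv_quintiles {label}/{cohort}: {exc}")
                            continue
                        rep.cohort = f"{label}:{cohort}"
                        reports.append(rep)
                        _qa.write_quintile_report_tsv(
                            rep, out_dir / f"quintile_cv_{label}_{cohort}.tsv"
                        )
                if not reports:
                    raise ValueError("no cohort had enough unanimous proteins")
                tally_path = out_dir / "vote_tally.json"
                payload = _qa.write_vote_tally_json(reports, tally_path)
                stages["cv_quintiles"] = StageResult(
                    "ok",
                    [tally_path]
                    + sorted(out_dir.glob("quintile_cv_*.tsv")),
                )
                _log_line(
                    log,
                    f"cv_quintiles: votes TRUE={payload['n_true']} FALSE={payload['n_false']}",
                )
            except Exception as exc:
                stages["cv_quintiles"] = StageResult("failed", error=str(exc))
                _log_line(log, f"FAILED cv_quintiles: {exc}")

        if "windows" in manifest.analyses:
            try:
                if not libraries:
                    raise ValueError("window design needs at least one readable library")
                mzs = [mz for lib in libraries for mz in lib.precursor_mzs()]
                scheme = design_windows(mzs, manifest.window_config)
                out = out_dir / "windows.tsv"
                write_scheme_tsv(scheme, out)
                stages["windows"] = StageResult("ok", [out])
                _log_line(
                    log,
                    f"windows: {scheme.n_windows} windows over m/z "
                    f"{scheme.mz_range()[0]}-{scheme.mz_range()[1]}, "
                    f"cycle {scheme.cycle_time_s:g} s, "
                    f"{scheme.points_per_peak:g} points/peak",
                )
            except Exception as exc:
                stages["windows"] = StageResult("failed", error=str(exc))
                _log_line(log, f"FAILED windows: {exc}")

        summary = {
            name: {"status": r.status, "error": r.error, "outputs": [str(p) for p in r.outputs]}
            for name, r in sorted(stages.items())
        }
        (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=1))
        _log_line(log, f"done: {sum(r.status == 'ok' for r in stages.values())} ok, "
                       f"{sum(r.status == 'failed' for r in stages.values())} failed")

    return RunReport(out_dir=out_dir, stages=stages)
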
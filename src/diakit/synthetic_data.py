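"""Synthetic peptide universes, spectral libraries and quantity matrices.

The generator emulates the structure of a multi-workflow DIA evaluation so
that every analysis stage runs with no external data:

* a **peptide universe**: tryptic-like peptides with monoisotopic precursor
  m/z computed from residue masses (via :mod:`pyteomics.mass`), a fixed Cys
  alkylation chosen from the chemistries seen across instrument platforms
  (+46 MMTS, +57 carbamidomethyl, +71 propionamide, or none), variable Met
  oxidation, charges 2-4, and protein/gene mapping including a block of
  keratin-like contaminant proteins;

* **engine- and mode-biased detection**: each peptide is either shared,
  detectable only in DDA-derived libraries, only in DIA-derived libraries,
  or preferentially by one search engine — so planted DDA-only / DIA-only
  blocks exist for the intersection analysis to recover;

* **cohort quantity matrices**: protein intensities are log-normal; run
  values carry multiplicative noise with standard deviation
  ``a + b * I**-0.5`` (so CV falls with intensity when ``b > 0``), and
  cells go missing with a probability that decreases logistically in log
  intensity, scaled per run to emulate gradient-length effects;

* **writers for all eight dialects**, byte-deterministic under a fixed
  seed, so the parsers can be exercised end to end.

Ground truth (peptide classes, detection sets, missing masks, noise
parameters) is returned alongside every simulation for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from pyteomics import mass as _ptmass

from .library_io import (
    FEASIBLE_PAIRS,
    LibraryEntry,
    LibraryProvenance,
    SpectralLibrary,
)
from .quant_io import QuantMatrix

PROTON_MASS = 1.00727646688
OXIDATION_MASS = 15.994915


def _stable_rt(sequence: str) -> float:
    """Deterministic pseudo retention time (process-independent, unlike hash)."""
    return float(sum(ord(c) * (i + 1) for i, c in enumerate(sequence)) % 100)

#: Cys fixed-modification chemistries: monoisotopic shift -> (UniMod id, name).
CYS_MODS = {
    0.0: None,
    45.987721: (39, "Methylthio (C)"),
    57.021464: (4, "Carbamidomethyl (C)"),
    71.037114: (24, "Propionamide (C)"),
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The six feasible workflow libraries of a full comparison.
DEFAULT_WORKFLOWS = (
    ("DIANN", "DIA"),
    ("FragPipe", "DDA"),
    ("FragPipe", "DIA"),
    ("MaxQuant", "DDA"),
    ("Spectronaut", "DDA"),
    ("Spectronaut", "DIA"),
)


@dataclass(frozen=True)
class CohortPlan:
    """Noise and missingness model for one cohort of replicate runs.

    run_missing_scale:
        per-run multiplier on the logistic missingness curve; one entry per
        run.  Larger = shallower run (more missing values), emulating
        shorter LC gradients.  Values above 1 saturate toward certain
        missingness.
    cv_a, cv_b:
        noise model ``sd(eps) = cv_a + cv_b * I**-0.5`` for run value
        ``I * (1 + eps)``; ``cv_b = 0`` gives intensity-independent CV.
    log10_intensity_mean / sd:
        log-normal protein ground-truth intensity (log10 scale).
    missing_mid_log10 / missing_slope:
        centre and softness (log10 units) of the logistic missingness
        curve: ``p_miss = scale / (1 + exp((log10 I - mid) / slope))``.
    """

    n_runs: int = 3
    run_missing_scale: tuple[float, ...] = (0.2, 0.2, 0.2)
    cv_a: float = 0.05
    cv_b: float = 25.0
    log10_intensity_mean: float = 6.0
    log10_intensity_sd: float = 1.2
    missing_mid_log10: float = 5.0
    missing_slope: float = 0.5

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("a cohort needs at least one run")
        if len(self.run_missing_scale) != self.n_runs:
            raise ValueError("run_missing_scale must list one value per run")
        if any(s < 0 for s in self.run_missing_scale):
            raise ValueError("missingness scales cannot be negative")
        if self.cv_a < 0 or self.cv_b < 0:
            raise ValueError("cv_a and cv_b cannot be negative")


#: Nine-run cohort emulating a lysosome-enrichment design with three runs at
#: each of three gradient depths, so per-run missingness falls short > mid >
#: long, roughly 18% / 6% / 2% of quantified proteins per run.
SPION_LIKE_PLAN = CohortPlan(
    n_runs=9,
    run_missing_scale=(0.9, 0.9, 0.9, 0.3, 0.3, 0.3, 0.1, 0.1, 0.1),
)


@dataclass(frozen=True)
class SimConfig:
    """Every knob of the synthetic study, fully determined by ``seed``."""

    seed: int = 0
    n_proteins: int = 400
    peptides_per_protein: tuple[int, int] = (4, 20)
    peptide_length: tuple[int, int] = (7, 24)
    cys_fixed_mod: float = 45.987721
    met_ox_prob: float = 0.2
    charge_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.6, 3: 0.3, 4: 0.1}
    )
    second_charge_prob: float = 0.3
    workflows: tuple[tuple[str, str], ...] = DEFAULT_WORKFLOWS
    detection_rate: float = 0.9
    frac_dda_only: float = 0.08
    frac_dia_only: float = 0.08
    frac_engine_pref: float = 0.10
    cohorts: Mapping[str, CohortPlan] = field(
        default_factory=lambda: {"LEF": SPION_LIKE_PLAN}
    )
    contaminant_block: int = 10

    def __post_init__(self) -> None:
        if self.cys_fixed_mod not in CYS_MODS:
            raise ValueError(
                f"cys_fixed_mod must be one of {sorted(CYS_MODS)}, got {self.cys_fixed_mod}"
            )
        for p in (
            self.met_ox_prob,
            self.detection_rate,
            self.frac_dda_only,
            self.frac_dia_only,
            self.frac_engine_pref,
            self.second_charge_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.frac_dda_only + self.frac_dia_only + self.frac_engine_pref > 1.0:
            raise ValueError("peptide-class fractions sum above 1")
        for pair in self.workflows:
            if tuple(pair) not in FEASIBLE_PAIRS:
                raise ValueError(f"infeasible workflow pair {pair}")
        if self.contaminant_block > self.n_proteins:
            raise ValueError("contaminant block larger than the proteome")


def precursor_mz(sequence: str, charge: int, mod_mass: float = 0.0) -> float:
    """Monoisotopic precursor m/z of a peptide: (M + mods + z*proton) / z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    neutral = _ptmass.fast_mass(sequence) + mod_mass
    return (neutral + charge * PROTON_MASS) / charge


@dataclass
class Universe:
    """Ground-truth peptide universe.

    ``precursors`` has one row per (peptide, charge):
    protein_id, gene_id, sequence, charge, mz, oxidized, is_contaminant.
    """

    precursors: pd.DataFrame
    cfg: SimConfig

    def proteins(self) -> pd.DataFrame:
        return (
            self.precursors[["protein_id", "gene_id", "is_contaminant"]]
            .drop_duplicates("protein_id")
            .reset_index(drop=True)
        )

    def peptide_sequences(self) -> list[str]:
        return self.precursors["sequence"].drop_duplicates().tolist()


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(AMINO_ACIDS), size=length - 1)
    terminal = "K" if rng.random() < 0.5 else "R"
    return "".join(body) + terminal


def generate_universe(cfg: SimConfig) -> Universe:
    """Build the deterministic peptide universe for ``cfg``.

    Peptides are tryptic-like (C-terminal K/R), globally unique, each
    carried at one or two charge states chosen so the precursor m/z stays
    in the plausible 350-1400 Th band.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    cys_mass = cfg.cys_fixed_mod
    lo_len, hi_len = cfg.peptide_length
    lo_k, hi_k = cfg.peptides_per_protein
    charges = np.array(sorted(cfg.charge_probs))
    charge_p = np.array([cfg.charge_probs[z] for z in charges], dtype=float)
    charge_p = charge_p / charge_p.sum()

    rows: list[dict] = []
    seen: set[str] = set()
    for p in range(cfg.n_proteins):
        contaminant = p < cfg.contaminant_block
        if contaminant:
            protein_id = f"KRTCON{p:03d}"
            gene_id = f"KRT{p + 1}"
        else:
            protein_id = f"SP{p:05d}"
            gene_id = f"GENE{p:04d}"
        k = int(rng.integers(lo_k, hi_k + 1))
        for _ in range(k):
            for _attempt in range(100):
                seq = _random_peptide(rng, int(rng.integers(lo_len, hi_len + 1)))
                if seq not in seen:
                    seen.add(seq)
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a unique peptide sequence")
            oxidized = "M" in seq and rng.random() < cfg.met_ox_prob
            mod_mass = seq.count("C") * cys_mass + (OXIDATION_MASS if oxidized else 0.0)

            usable = [
                int(z)
                for z in charges
                if 350.0 <= precursor_mz(seq, int(z), mod_mass) <= 1400.0
            ]
            if not usable:
                usable = [2]
            p_use = np.array([cfg.charge_probs.get(z, 0.01) for z in usable], dtype=float)
            z1 = int(rng.choice(usable, p=p_use / p_use.sum()))
            picked = [z1]
            rest = [z for z in usable if z != z1]
            if rest and rng.random() < cfg.second_charge_prob:
                picked.append(int(rng.choice(rest)))
            for z in picked:
                rows.append(
                    {
                        "protein_id": protein_id,
                        "gene_id": gene_id,
                        "sequence": seq,
                        "charge": z,
                        "mz": precursor_mz(seq, z, mod_mass),
                        "oxidized": oxidized,
                        "is_contaminant": contaminant,
                    }
                )
    return Universe(precursors=pd.DataFrame(rows), cfg=cfg)


# ---------------------------------------------------------------------------
# modification notation per workflow


def _annotate(seq: str, oxidized: bool, cys_mass: float, style: str) -> str:
    cys = CYS_MODS[cys_mass]
    ox_pos = seq.find("M") if oxidized else -1
    out = []
    for i, aa in enumerate(seq):
        out.append(aa)
        if aa == "C" and cys is not None:
            uid, name = cys
            if style == "unimod":
                out.append(f"(UniMod:{uid})")
            elif style == "maxquant":
                out.append(f"({name})")
            else:
                out.append(f"[{name}]")
        elif i == ox_pos:
            if style == "unimod":
                out.append("(UniMod:35)")
            elif style == "maxquant":
                out.append("(Oxidation (M))")
            else:
                out.append("[Oxidation (M)]")
    body = "".join(out)
    return body if style == "unimod" else f"_{body}_"


_NOTATION_STYLE = {
    "DIANN": "unimod",
    "FragPipe": "unimod",
    "MaxQuant": "maxquant",
    "Spectronaut": "spectronaut",
}


# ---------------------------------------------------------------------------
# library simulation

CLASS_SHARED = "shared"
CLASS_DDA_ONLY = "dda_only"
CLASS_DIA_ONLY = "dia_only"


@dataclass
class LibraryGroundTruth:
    """What was planted: per-peptide class and per-library detection sets."""

    class_of: dict[str, str]
    detected: dict[str, set[str]]
    n_dda_only: int
    n_dia_only: int
    n_engine_pref: dict[str, int]


def simulate_libraries(
    universe: Universe, cfg: Optional[SimConfig] = None
) -> tuple[dict[str, SpectralLibrary], LibraryGroundTruth]:
    """Draw one spectral library per workflow with biased detection.

    Each peptide sequence is assigned one class: shared (detectable by
    every workflow), DDA-only, DIA-only, or engine-preferring (detectable
    by one engine in either mode).  Within its eligible libraries a
    peptide's precursors are detected independently with
    ``cfg.detection_rate``; a rate of 1 makes every planted count exact.
    Contaminant peptides are always shared.
    """
    cfg = cfg or universe.cfg
    if len(cfg.workflows) < 2:
        raise ValueError("need at least two workflows to compare")
    rng = np.random.default_rng([cfg.seed, 23])
    engines = sorted({e for e, _ in cfg.workflows})

    peptides = universe.precursors.drop_duplicates("sequence")[["sequence", "is_contaminant"]]
    class_of: dict[str, str] = {}
    p_rest = 1.0 - cfg.frac_dda_only - cfg.frac_dia_only - cfg.frac_engine_pref
    labels = [CLASS_DDA_ONLY, CLASS_DIA_ONLY, "pref", CLASS_SHARED]
    probs = [cfg.frac_dda_only, cfg.frac_dia_only, cfg.frac_engine_pref, p_rest]
    draws = rng.choice(len(labels), size=len(peptides), p=probs)
    for (seq, contaminant), d in zip(
        peptides.itertuples(index=False), draws
    ):
        if contaminant:
            class_of[seq] = CLASS_SHARED
        elif labels[d] == "pref":
            class_of[seq] = f"engine:{engines[rng.integers(len(engines))]}"
        else:
            class_of[seq] = labels[d]

    libraries: dict[str, SpectralLibrary] = {}
    detected: dict[str, set[str]] = {}
    prec = universe.precursors
    for engine, mode in cfg.workflows:
        name = f"{engine}-{mode}"
        style = _NOTATION_STYLE[engine]
        entries: list[LibraryEntry] = []
        det: set[str] = set()
        for row in prec.itertuples(index=False):
            cls = class_of[row.sequence]
            eligible = (
                cls == CLASS_SHARED
                or (cls == CLASS_DDA_ONLY and mode == "DDA")
                or (cls == CLASS_DIA_ONLY and mode == "DIA")
                or cls == f"engine:{engine}"
            )
            if not eligible:
                continue
            if cfg.detection_rate < 1.0 and rng.random() >= cfg.detection_rate:
                continue
            entries.append(
                LibraryEntry(
                    stripped_sequence=row.sequence,
                    modified_sequence=_annotate(
                        row.sequence, row.oxidized, cfg.cys_fixed_mod, style
                    ),
                    charge=int(row.charge),
                    precursor_mz=float(row.mz),
                    protein_ids=(row.protein_id,),
                    gene_ids=(row.gene_id,),
                    is_contaminant=bool(row.is_contaminant),
                )
            )
            det.add(row.sequence)
        libraries[name] = SpectralLibrary(
            entries=entries,
            provenance=LibraryProvenance(engine=engine, acquisition=mode),
            name=name,
        )
        detected[name] = det

    n_pref: dict[str, int] = {e: 0 for e in engines}
    for cls in class_of.values():
        if cls.startswith("engine:"):
            n_pref[cls.split(":", 1)[1]] += 1
    truth = LibraryGroundTruth(
        class_of=class_of,
        detected=detected,
        n_dda_only=sum(c == CLASS_DDA_ONLY for c in class_of.values()),
        n_dia_only=sum(c == CLASS_DIA_ONLY for c in class_of.values()),
        n_engine_pref=n_pref,
    )
    return libraries, truth


# ---------------------------------------------------------------------------
# quantity simulation


@dataclass
class QuantGroundTruth:
    """Planted truth behind one simulated cohort matrix."""

    truth_intensity: pd.Series
    missing_mask: pd.DataFrame
    per_run_missing: dict[str, int]
    plan: CohortPlan


def simulate_quant(
    universe: Universe,
    cfg: Optional[SimConfig] = None,
    cohort: str = "LEF",
    rng: Optional[np.random.Generator] = None,
) -> tuple[QuantMatrix, QuantGroundTruth]:
    """Simulate a protein-by-run quantity matrix for one cohort.

    Protein ground-truth intensity is log-normal.  Each run value is
    ``I * (1 + eps)`` with ``eps ~ N(0, cv_a + cv_b * I**-0.5)``, floored
    at a thousandth of the truth, and goes missing with probability
    ``min(1, scale_run / (1 + exp((log10 I - mid) / slope)))``.
    """
    cfg = cfg or universe.cfg
    if cohort not in cfg.cohorts:
        raise ValueError(f"unknown cohort {cohort!r}; configured: {sorted(cfg.cohorts)}")
    plan = cfg.cohorts[cohort]
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 37, *(ord(c) for c in cohort)])

    proteins = universe.proteins()
    n = len(proteins)
    log10_I = rng.normal(plan.log10_intensity_mean, plan.log10_intensity_sd, size=n)
    intensity = 10.0 ** log10_I
    sd = plan.cv_a + plan.cv_b * intensity**-0.5

    run_ids = [f"{cohort}_run{j + 1:02d}" for j in range(plan.n_runs)]
    values = np.empty((n, plan.n_runs))
    mask = np.zeros((n, plan.n_runs), dtype=bool)
    for j, scale in enumerate(plan.run_missing_scale):
        eps = rng.normal(0.0, 1.0, size=n) * sd
        values[:, j] = np.maximum(intensity * (1.0 + eps), intensity * 1e-3)
        p_miss = np.minimum(
            1.0,
            scale / (1.0 + np.exp((log10_I - plan.missing_mid_log10) / plan.missing_slope)),
        )
        mask[:, j] = rng.random(n) < p_miss

    values_df = pd.DataFrame(values, index=proteins["protein_id"], columns=run_ids)
    values_df = values_df.where(~mask)
    mask_df = pd.DataFrame(mask, index=proteins["protein_id"], columns=run_ids)
    qm = QuantMatrix(
        values=values_df,
        cohorts={r: cohort for r in run_ids},
        genes=proteins.set_index("protein_id")["gene_id"],
        contaminant=proteins.set_index("protein_id")["is_contaminant"].astype(bool),
        source=f"simulated:{cohort}",
    )
    truth = QuantGroundTruth(
        truth_intensity=pd.Series(intensity, index=proteins["protein_id"]),
        missing_mask=mask_df,
        per_run_missing={r: int(mask_df[r].sum()) for r in run_ids},
        plan=plan,
    )
    return qm, truth


# ---------------------------------------------------------------------------
# dialect writers

_FLOAT = "%.6f"


def _require_nonempty(n: int, what: str) -> None:
    if n == 0:
        raise ValueError(f"refusing to write an empty {what}")


def write_diann_library(lib: SpectralLibrary, path: str | Path) -> None:
    """Write a DIA-NN ``report-lib.tsv``-style library (transition rows)."""
    _require_nonempty(len(lib.entries), "library")
    rows = []
    for e in lib.entries:
        for frag, frac, inten in (("y4", 0.62, 10000.0), ("y6", 0.81, 6000.0)):
            rows.append(
                {
                    "PrecursorMz": _FLOAT % e.precursor_mz,
                    "ProductMz": _FLOAT % (e.precursor_mz * frac),
                    "Annotation": frag,
                    "ProteinGroup": ";".join(e.protein_ids),
                    "ProteinName": ";".join(e.protein_ids),
                    "Genes": ";".join(e.gene_ids),
                    "PeptideSequence": e.stripped_sequence,
                    "ModifiedPeptide": e.modified_sequence,
                    "PrecursorCharge": e.charge,
                    "LibraryIntensity": _FLOAT % inten,
                    "NormalizedRetentionTime": _FLOAT % _stable_rt(e.stripped_sequence),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fragpipe_library(lib: SpectralLibrary, path: str | Path) -> None:
    """Write a FragPipe/OpenSWATH ``library.tsv``-style library."""
    _require_nonempty(len(lib.entries), "library")
    rows = []
    for e in lib.entries:
        for frag, frac, inten in (("y4", 0.62, 10000.0), ("y6", 0.81, 6000.0)):
            rows.append(
                {
                    "PrecursorMz": _FLOAT % e.precursor_mz,
                    "ProductMz": _FLOAT % (e.precursor_mz * frac),
                    "Annotation": frag,
                    "ProteinId": ";".join(e.protein_ids),
                    "GeneName": ";".join(e.gene_ids),
                    "PeptideSequence": e.stripped_sequence,
                    "ModifiedPeptideSequence": e.modified_sequence,
                    "PrecursorCharge": e.charge,
                    "LibraryIntensity": _FLOAT % inten,
                    "NormalizedRetentionTime": _FLOAT % _stable_rt(e.stripped_sequence),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_maxquant_evidence(
    lib: SpectralLibrary, path: str | Path, *, n_decoys: int = 0
) -> None:
    """Write a MaxQuant ``evidence.txt``-style library.

    Contaminant entries get ``CON__``-prefixed accessions and a
    ``Potential contaminant`` flag (the MaxQuant convention; other dialects
    carry no contaminant marking).  ``n_decoys`` plants reversed-sequence
    rows flagged ``Reverse`` that a correct reader must drop.
    """
    _require_nonempty(len(lib.entries), "library")
    rows = []

    def _row(e: LibraryEntry, reverse: bool) -> dict:
        proteins = [
            p if p.startswith(("CON__", "REV__")) else (f"CON__{p}" if e.is_contaminant else p)
            for p in e.protein_ids
        ]
        return {
            "Sequence": e.stripped_sequence,
            "Length": len(e.stripped_sequence),
            "Modified sequence": e.modified_sequence,
            "Charge": e.charge,
            "m/z": _FLOAT % e.precursor_mz,
            "Proteins": ";".join(proteins),
            "Gene names": ";".join(e.gene_ids),
            "Raw file": "run01",
            "Reverse": "+" if reverse else "",
            "Potential contaminant": "+" if e.is_contaminant else "",
            "Intensity": _FLOAT % 1e6,
        }

    for e in lib.entries:
        rows.append(_row(e, reverse=False))
    for e in lib.entries[: max(0, n_decoys)]:
        rev = e.stripped_sequence[::-1]
        decoy = LibraryEntry(
            stripped_sequence=rev,
            modified_sequence=rev,
            charge=e.charge,
            precursor_mz=e.precursor_mz,
            protein_ids=tuple(f"REV__{p}" for p in e.protein_ids),
            gene_ids=(),
        )
        rows.append(_row(decoy, reverse=True))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_spectronaut_allpeptides(lib: SpectralLibrary, path: str | Path) -> None:
    """Write a Spectronaut ``AllPeptides.tsv``-style peptide list."""
    _require_nonempty(len(lib.entries), "library")
    rows = [
        {
            "PG.ProteinGroups": ";".join(e.protein_ids),
            "PG.Genes": ";".join(e.gene_ids),
            "PEP.StrippedSequence": e.stripped_sequence,
            "EG.ModifiedSequence": e.modified_sequence,
            "FG.Charge": e.charge,
            "FG.PrecMz": _FLOAT % e.precursor_mz,
        }
        for e in lib.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


LIBRARY_WRITERS = {
    "diann_lib": write_diann_library,
    "fragpipe_lib": write_fragpipe_library,
    "maxquant_evidence": write_maxquant_evidence,
    "spectronaut_allpeptides": write_spectronaut_allpeptides,
}

_ENGINE_LIB_DIALECT = {
    "DIANN": "diann_lib",
    "FragPipe": "fragpipe_lib",
    "MaxQuant": "maxquant_evidence",
    "Spectronaut": "spectronaut_allpeptides",
}

_LIB_FILENAME = {
    "diann_lib": "report-lib.tsv",
    "fragpipe_lib": "library.tsv",
    "maxquant_evidence": "evidence.txt",
    "spectronaut_allpeptides": "AllPeptides.tsv",
}


def _fmt_cell(v: float, missing: str) -> str:
    return missing if pd.isna(v) else _FLOAT % v


def write_pg_matrix(qm: QuantMatrix, path: str | Path) -> None:
    """Write a DIA-NN/FragPipe ``report.pg_matrix.tsv``; missing = blank."""
    _require_nonempty(len(qm.values), "quantity matrix")
    out = pd.DataFrame({"Protein.Group": qm.values.index})
    out["Genes"] = (
        qm.genes.reindex(qm.values.index).fillna("").values if qm.genes is not None else ""
    )
    for run in qm.values.columns:
        out[run] = [_fmt_cell(v, "") for v in qm.values[run]]
    out.to_csv(path, sep="\t", index=False)


def write_maxquant_protein_groups(
    qm: QuantMatrix, path: str | Path, *, n_decoys: int = 0, n_site_only: int = 0
) -> None:
    """Write a MaxQuant ``proteinGroups.txt``; missing = 0.

    ``n_decoys`` / ``n_site_only`` plant Reverse and "Only identified by
    site" rows that a correct reader must drop.
    """
    _require_nonempty(len(qm.values), "quantity matrix")
    contam = qm.contaminant.reindex(qm.values.index).fillna(False)
    rows = []
    for pid in qm.values.index:
        rows.append(
            {
                "Protein IDs": f"CON__{pid}" if contam[pid] and not str(pid).startswith("CON__") else pid,
                "Gene names": "" if qm.genes is None else str(qm.genes.get(pid, "") or ""),
                "Reverse": "",
                "Only identified by site": "",
                "Potential contaminant": "+" if contam[pid] else "",
                **{
                    f"Intensity {run}": _fmt_cell(qm.values.at[pid, run], "0")
                    for run in qm.values.columns
                },
            }
        )
    for i in range(n_decoys):
        rows.append(
            {
                "Protein IDs": f"REV__DECOY{i:03d}",
                "Gene names": "",
                "Reverse": "+",
                "Only identified by site": "",
                "Potential contaminant": "",
                **{f"Intensity {run}": "1000.0" for run in qm.values.columns},
            }
        )
    for i in range(n_site_only):
        rows.append(
            {
                "Protein IDs": f"SITEONLY{i:03d}",
                "Gene names": "",
                "Reverse": "",
                "Only identified by site": "+",
                "Potential contaminant": "",
                **{f"Intensity {run}": "1000.0" for run in qm.values.columns},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_spectronaut_report(qm: QuantMatrix, path: str | Path) -> None:
    """Write a Spectronaut long-format ``Report.tsv``; absent pair = missing."""
    _require_nonempty(len(qm.values), "quantity matrix")
    rows = []
    for pid in qm.values.index:
        for run in qm.values.columns:
            v = qm.values.at[pid, run]
            if pd.isna(v):
                continue
            rows.append(
                {
                    "R.FileName": run,
                    "PG.ProteinGroups": pid,
                    "PG.Genes": "" if qm.genes is None else str(qm.genes.get(pid, "") or ""),
                    "PG.Quantity": _FLOAT % v,
                }
            )
    if not rows:
        raise ValueError("refusing to write a quantity report with no observed values")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fragpipe_combined_protein(
    qm: QuantMatrix,
    path: str | Path,
    *,
    maxlfq: Optional[pd.DataFrame] = None,
    extra_maxlfq_missing_every: int = 7,
) -> None:
    """Write a FragPipe ``combined_protein.tsv`` with both column families.

    When ``maxlfq`` is not given, the MaxLFQ family copies the Intensity
    values but blanks every ``extra_maxlfq_missing_every``-th observed cell
    — mirroring the empirically sparser MaxLFQ columns.
    """
    _require_nonempty(len(qm.values), "quantity matrix")
    if maxlfq is None:
        maxlfq = qm.values.copy()
        flat = np.flatnonzero(maxlfq.notna().to_numpy().ravel())
        kill = flat[::extra_maxlfq_missing_every] if extra_maxlfq_missing_every > 0 else []
        arr = maxlfq.to_numpy().ravel()
        arr[kill] = np.nan
        maxlfq = pd.DataFrame(
            arr.reshape(maxlfq.shape), index=maxlfq.index, columns=maxlfq.columns
        )
    out = pd.DataFrame({"Protein": qm.values.index})
    out["Protein ID"] = qm.values.index
    out["Gene"] = (
        qm.genes.reindex(qm.values.index).fillna("").values if qm.genes is not None else ""
    )
    for run in qm.values.columns:
        out[f"{run} Intensity"] = [_fmt_cell(v, "0") for v in qm.values[run]]
    for run in qm.values.columns:
        out[f"{run} MaxLFQ Intensity"] = [_fmt_cell(v, "0") for v in maxlfq[run]]
    out.to_csv(path, sep="\t", index=False)


QUANT_WRITERS = {
    "pg_matrix": write_pg_matrix,
    "maxquant": write_maxquant_protein_groups,
    "spectronaut": write_spectronaut_report,
    "fragpipe_combined": write_fragpipe_combined_protein,
}

_ENGINE_QUANT_DIALECT = {
    "DIANN": "pg_matrix",
    "FragPipe": "fragpipe_combined",
    "MaxQuant": "maxquant",
    "Spectronaut": "spectronaut",
}

_QUANT_FILENAME = {
    "pg_matrix": "report.pg_matrix.tsv",
    "maxquant": "proteinGroups.txt",
    "spectronaut": "Report.tsv",
    "fragpipe_combined": "combined_protein.tsv",
}


def write_fixtures(
    libraries: Mapping[str, SpectralLibrary],
    matrices: Mapping[str, QuantMatrix],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write every library and matrix in its engine's native dialect.

    Returns a map from a short key (``lib:<name>`` / ``quant:<engine>``) to
    the written path.  File names follow each workflow's conventions
    (``report-lib.tsv``, ``library.tsv``, ``evidence.txt``,
    ``AllPeptides.tsv``; ``report.pg_matrix.tsv``, ``combined_protein.tsv``,
    ``proteinGroups.txt``, ``Report.tsv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in sorted(libraries):
        lib = libraries[name]
        dialect = _ENGINE_LIB_DIALECT[lib.provenance.engine]
        path = out_dir / f"{name}.{_LIB_FILENAME[dialect]}"
        LIBRARY_WRITERS[dialect](lib, path)
        written[f"lib:{name}"] = path
    for engine in sorted(matrices):
        dialect = _ENGINE_QUANT_DIALECT[engine]
        path = out_dir / f"{engine}.{_QUANT_FILENAME[dialect]}"
        QUANT_WRITERS[dialect](matrices[engine], path)
        written[f"quant:{engine}"] = path
    return written
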
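"""Readers and writers for spectral-library exports of DIA software.

Each DIA workflow exports its spectral library as a tab-separated text table
with its own column vocabulary:

========================  =========================  ======================
workflow                  export file                dialect identifier
========================  =========================  ======================
DIA-NN                    ``report-lib.tsv``         ``diann_lib``
FragPipe (MSFragger)      ``library.tsv``            ``fragpipe_lib``
MaxQuant                  ``evidence.txt``           ``maxquant_evidence``
Spectronaut               ``AllPeptides.tsv/.txt``   ``spectronaut_allpeptides``
========================  =========================  ======================

All four are reduced to one harmonized representation: one
:class:`LibraryEntry` per distinct (modified sequence, charge) precursor,
carrying the stripped peptide sequence, precursor m/z and protein / gene
annotations.  Transition-level rows (DIA-NN and FragPipe libraries list one
row per fragment ion) are collapsed to precursor level on read; fragment
content is not modelled.  Modification notation is preserved verbatim in the
source workflow's own syntax — cross-workflow comparisons key on the
stripped sequence (see :mod:`diakit.diversity`).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = (
    "diann_lib",
    "fragpipe_lib",
    "maxquant_evidence",
    "spectronaut_allpeptides",
)

ENGINES = ("DIANN", "FragPipe", "MaxQuant", "Spectronaut")
ACQUISITIONS = ("DDA", "DIA")

#: Feasible (engine, acquisition) pairs.  MaxQuant builds libraries only from
#: DDA identifications; the DIA-NN search engine only reads DIA data;
#: FragPipe (MSFragger) and Spectronaut (Pulsar) identify either mode.
FEASIBLE_PAIRS = frozenset(
    [
        ("DIANN", "DIA"),
        ("FragPipe", "DDA"),
        ("FragPipe", "DIA"),
        ("MaxQuant", "DDA"),
        ("Spectronaut", "DDA"),
        ("Spectronaut", "DIA"),
    ]
)

MIN_PEPTIDE_LENGTH = 5

DECOY_PREFIX = "REV__"
DEFAULT_CONTAMINANT_PREFIXES = ("CON__", "contam_")


class DialectError(ValueError):
    """Raised when a file matches zero or more than one library dialect."""


class ParseError(ValueError):
    """Raised when a library file cannot be parsed under its dialect."""


def _norm_header(token: str) -> str:
    """Collapse a header token to a canonical lowercase alphanumeric form.

    Real exports vary in case and in the separator used inside column names
    (``Modified.Sequence`` vs ``Modified sequence``); comparing normalized
    tokens makes detection robust to those variants.
    """
    return re.sub(r"[^0-9a-z]", "", token.strip().lower())


# Required column signature per dialect.  Each element is a tuple of accepted
# alternative (normalized) names for one required column.
_SIGNATURES: dict[str, tuple[tuple[str, ...], ...]] = {
    "diann_lib": (
        ("peptidesequence", "strippedsequence"),
        ("modifiedpeptide", "modifiedsequence"),
        ("precursorcharge",),
        ("precursormz",),
        ("proteingroup", "proteinid"),
        ("genes",),
    ),
    "fragpipe_lib": (
        ("peptidesequence",),
        ("modifiedpeptidesequence",),
        ("precursorcharge",),
        ("precursormz",),
        ("proteinid",),
    ),
    "maxquant_evidence": (
        ("sequence",),
        ("modifiedsequence",),
        ("charge",),
        ("mz",),
        ("proteins",),
    ),
    "spectronaut_allpeptides": (
        ("pepstrippedsequence", "strippedsequence"),
        ("egmodifiedsequence", "egmodifiedpeptide"),
        ("fgcharge",),
        ("fgprecmz", "fgprecursormz"),
    ),
}

# Optional columns harvested when present: genes / secondary annotations.
_OPTIONAL: dict[str, dict[str, tuple[str, ...]]] = {
    "diann_lib": {},
    "fragpipe_lib": {"genes": ("genename", "genes")},
    "maxquant_evidence": {
        "genes": ("genenames",),
        "reverse": ("reverse",),
        "contaminant": ("potentialcontaminant", "contaminant"),
    },
    "spectronaut_allpeptides": {
        "proteins": ("pgproteingroups", "proteingroups"),
        "genes": ("pggenes", "genes"),
    },
}


@dataclass(frozen=True)
class LibraryEntry:
    """One identified precursor of a spectral library.

    ``modified_sequence`` keeps the source workflow's own modification
    notation; ``stripped_sequence`` is the plain uppercase amino-acid string
    obtained by removing every modification annotation from it.
    """

    stripped_sequence: str
    modified_sequence: str
    charge: int
    precursor_mz: float
    protein_ids: tuple[str, ...] = ()
    gene_ids: tuple[str, ...] = ()
    is_contaminant: bool = False
    source_row: int = -1


@dataclass(frozen=True)
class LibraryProvenance:
    """Where a library came from: workflow, acquisition mode, dataset, cohort."""

    engine: str
    acquisition: str
    dataset: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}; expected one of {ENGINES}")
        if self.acquisition not in ACQUISITIONS:
            raise ValueError(
                f"unknown acquisition {self.acquisition!r}; expected one of {ACQUISITIONS}"
            )
        if (self.engine, self.acquisition) not in FEASIBLE_PAIRS:
            raise ValueError(
                f"({self.engine}, {self.acquisition}) is not a feasible workflow: "
                "MaxQuant identifies only DDA and the DIA-NN search engine only DIA"
            )


@dataclass
class ReadStats:
    """Row-accounting from one :func:`read_library` call."""

    n_rows: int = 0
    n_invalid: int = 0
    n_decoys: int = 0
    n_duplicates: int = 0
    n_mz_conflicts: int = 0


@dataclass
class SpectralLibrary:
    """A harmonized spectral library: unique precursors plus provenance."""

    entries: list[LibraryEntry]
    provenance: LibraryProvenance
    name: str
    read_stats: ReadStats = field(default_factory=ReadStats)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def stripped_sequences(self) -> set[str]:
        return {e.stripped_sequence for e in self.entries}

    def precursor_mzs(self) -> list[float]:
        return [e.precursor_mz for e in self.entries]


_DEPTH_OPEN = {"(": ")", "[": "]", "{": "}"}
_DEPTH_CLOSE = set(_DEPTH_OPEN.values())


def strip_modifications(modified_sequence: str) -> str:
    """Remove modification annotations, returning the bare peptide sequence.

    Handles the notations of all four workflows: bracketed or parenthesized
    (possibly nested, e.g. MaxQuant's ``(Oxidation (M))``) annotation groups,
    MaxQuant's flanking underscores, and inline mass tags.
    """
    out = []
    depth = 0
    for ch in modified_sequence:
        if ch in _DEPTH_OPEN:
            depth += 1
        elif ch in _DEPTH_CLOSE:
            depth = max(0, depth - 1)
        elif depth == 0 and "A" <= ch <= "Z":
            out.append(ch)
    return "".join(out)


def _read_header(path: Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n")
    if not header or "\t" not in header:
        raise DialectError(f"{path}: no tab-separated header line found")
    return header.split("\t")


def detect_dialect(path: str | Path) -> str:
    """Identify which library dialect a file is, from its header alone.

    Returns the unique dialect whose required columns are all present.
    Raises :class:`DialectError` if no dialect matches or several do,
    naming the missing or conflicting columns.
    """
    path = Path(path)
    tokens = {_norm_header(t) for t in _read_header(path)}
    matches = []
    missing: dict[str, list[str]] = {}
    for dialect, signature in _SIGNATURES.items():
        absent = ["|".join(alts) for alts in signature if not tokens.intersection(alts)]
        if absent:
            missing[dialect] = absent
        else:
            matches.append(dialect)
    if len(matches) == 1:
        return matches[0]
    if not matches:
        detail = "; ".join(f"{d}: missing {m}" for d, m in missing.items())
        raise DialectError(f"{path}: header matches no known library dialect ({detail})")
    raise DialectError(
        f"{path}: header ambiguously matches several dialects: {', '.join(sorted(matches))}"
    )


def _pick(columns: Sequence[str], alternatives: Iterable[str]) -> Optional[str]:
    by_norm = {_norm_header(c): c for c in columns}
    for alt in alternatives:
        if alt in by_norm:
            return by_norm[alt]
    return None


def _split_ids(value: object, seps: str = ";,") -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return ()
    for sep in seps[1:]:
        text = text.replace(sep, seps[0])
    return tuple(p.strip() for p in text.split(seps[0]) if p.strip())


def read_library(
    path: str | Path,
    dialect: str | None = None,
    provenance: LibraryProvenance | None = None,
    name: str | None = None,
    *,
    min_length: int = MIN_PEPTIDE_LENGTH,
    drop_contaminants: bool = False,
    contaminant_prefixes: Sequence[str] = DEFAULT_CONTAMINANT_PREFIXES,
    mz_conflict_tol: float = 0.01,
) -> SpectralLibrary:
    """Parse a spectral-library export into a :class:`SpectralLibrary`.

    Parameters
    ----------
    path:
        Tab-separated library export.
    dialect:
        One of :data:`DIALECTS`, or ``None`` to auto-detect from the header.
    provenance:
        Workflow / acquisition / dataset labels for the library.  Required
        because no dialect records its own acquisition mode.
    name:
        Unique label; defaults to ``"{engine}-{acquisition}"``.
    min_length:
        Peptides with a stripped sequence shorter than this are dropped.
    drop_contaminants:
        When True, contaminant-flagged entries are removed instead of being
        retained with ``is_contaminant=True`` (the default; contaminant
        prominence is itself informative in affinity experiments).
    mz_conflict_tol:
        Duplicate (modified sequence, charge) rows keep the first precursor
        m/z; later rows disagreeing by more than this (Th) are logged.

    Notes
    -----
    Decoy rows (MaxQuant ``Reverse == '+'`` or ``REV__`` protein prefixes)
    are always dropped.  Rows violating entry invariants (non-positive
    charge or m/z, sequence/annotation mismatch, short peptide) are dropped
    and counted in ``read_stats``.
    """
    path = Path(path)
    if dialect is None or dialect == "auto":
        dialect = detect_dialect(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if provenance is None:
        raise ValueError("provenance must be supplied (engine + acquisition at minimum)")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    cols = list(df.columns)
    sig = _SIGNATURES[dialect]
    picked = [_pick(cols, alts) for alts in sig]
    for alts, col in zip(sig, picked):
        if col is None:
            raise ParseError(f"{path}: required column {'|'.join(alts)} absent for {dialect}")

    opt = {key: _pick(cols, alts) for key, alts in _OPTIONAL[dialect].items()}

    if dialect == "diann_lib":
        stripped_c, modified_c, charge_c, mz_c, protein_c, genes_c = picked
    elif dialect == "fragpipe_lib":
        stripped_c, modified_c, charge_c, mz_c, protein_c = picked
        genes_c = opt.get("genes")
    elif dialect == "maxquant_evidence":
        stripped_c, modified_c, charge_c, mz_c, protein_c = picked
        genes_c = opt.get("genes")
    else:  # spectronaut_allpeptides
        stripped_c, modified_c, charge_c, mz_c = picked
        protein_c = opt.get("proteins")
        genes_c = opt.get("genes")

    stats = ReadStats(n_rows=len(df))
    seen: dict[tuple[str, int], LibraryEntry] = {}

    reverse_c = opt.get("reverse")
    contam_c = opt.get("contaminant")

    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rec = dict(zip(cols, row))
        proteins = _split_ids(rec.get(protein_c)) if protein_c else ()

        # decoys: explicit Reverse flag or REV__-prefixed accessions
        if reverse_c and str(rec.get(reverse_c, "")).strip() == "+":
            stats.n_decoys += 1
            continue
        if proteins and all(p.startswith(DECOY_PREFIX) for p in proteins):
            stats.n_decoys += 1
            continue

        contaminant = bool(contam_c and str(rec.get(contam_c, "")).strip() == "+") or any(
            p.startswith(tuple(contaminant_prefixes)) for p in proteins
        )
        if contaminant and drop_contaminants:
            stats.n_invalid += 1
            continue

        modified = str(rec.get(modified_c, "") or "")
        stripped_claim = str(rec.get(stripped_c, "") or "").strip().upper()
        stripped = strip_modifications(modified) if modified else stripped_claim
        if stripped_claim and stripped and stripped_claim != stripped:
            stats.n_invalid += 1
            continue
        stripped = stripped or stripped_claim
        try:
            charge = int(float(rec.get(charge_c)))
            mz = float(rec.get(mz_c))
        except (TypeError, ValueError):
            stats.n_invalid += 1
            continue
        if (
            not stripped
            or not re.fullmatch(r"[A-Z]+", stripped)
            or len(stripped) < min_length
            or charge < 1
            or mz <= 0
        ):
            stats.n_invalid += 1
            continue

        key = (modified or stripped, charge)
        if key in seen:
            stats.n_duplicates += 1
            if abs(seen[key].precursor_mz - mz) > mz_conflict_tol:
                stats.n_mz_conflicts += 1
                logger.warning(
                    "%s: duplicate precursor %s/%d with conflicting m/z (%.4f vs %.4f)",
                    path.name, key[0], charge, seen[key].precursor_mz, mz,
                )
            continue
        seen[key] = LibraryEntry(
            stripped_sequence=stripped,
            modified_sequence=modified or stripped,
            charge=charge,
            precursor_mz=mz,
            protein_ids=proteins,
            gene_ids=_split_ids(rec.get(genes_c)) if genes_c else (),
            is_contaminant=contaminant,
            source_row=i,
        )

    if not seen:
        raise ParseError(f"{path}: empty library after filtering")
    if stats.n_duplicates:
        logger.info("%s: collapsed %d duplicate precursor rows", path.name, stats.n_duplicates)

    lib_name = name or f"{provenance.engine}-{provenance.acquisition}"
    return SpectralLibrary(
        entries=list(seen.values()), provenance=provenance, name=lib_name, read_stats=stats
    )


HARMONIZED_COLUMNS = [
    "name",
    "engine",
    "acquisition",
    "stripped_sequence",
    "modified_sequence",
    "charge",
    "precursor_mz",
    "protein_ids",
    "gene_ids",
    "contaminant",
]


def write_harmonized_library(lib: SpectralLibrary, path: str | Path, *, fmt: str = "tsv") -> None:
    """Write a library in the harmonized TSV (or JSON-lines) layout."""
    path = Path(path)
    rows = [
        {
            "name": lib.name,
            "engine": lib.provenance.engine,
            "acquisition": lib.provenance.acquisition,
            "stripped_sequence": e.stripped_sequence,
            "modified_sequence": e.modified_sequence,
            "charge": e.charge,
            "precursor_mz": e.precursor_mz,
            "protein_ids": ";".join(e.protein_ids),
            "gene_ids": ";".join(e.gene_ids),
            "contaminant": int(e.is_contaminant),
        }
        for e in lib.entries
    ]
    if fmt == "tsv":
        pd.DataFrame(rows, columns=HARMONIZED_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in rows:
                fh.write(json.dumps(r) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'jsonl'")


def read_harmonized_library(path: str | Path, *, fmt: str = "tsv") -> SpectralLibrary:
    """Read a harmonized library written by :func:`write_harmonized_library`."""
    path = Path(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        rows = df.to_dict("records")
    elif fmt == "jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not rows:
        raise ParseError(f"{path}: empty harmonized library")
    first = rows[0]
    prov = LibraryProvenance(engine=str(first["engine"]), acquisition=str(first["acquisition"]))
    entries = [
        LibraryEntry(
            stripped_sequence=str(r["stripped_sequence"]),
            modified_sequence=str(r["modified_sequence"]),
            charge=int(r["charge"]),
            precursor_mz=float(r["precursor_mz"]),
            protein_ids=_split_ids(r.get("protein_ids", "")),
            gene_ids=_split_ids(r.get("gene_ids", "")),
            is_contaminant=bool(int(r.get("contaminant", 0) or 0)),
            source_row=i,
        )
        for i, r in enumerate(rows, start=2)
    ]
    return SpectralLibrary(entries=entries, provenance=prov, name=str(first["name"]))
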
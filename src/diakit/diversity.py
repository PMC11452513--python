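"""Peptide diversity summaries and exact-intersection (UpSet) statistics.

A library's *diversity* is counted at five nested granularities: distinct
genes, protein accessions, peptide sequences, modified peptide forms, and
"MPZs" — (modified peptide, charge) pairs, the finest unit a spectral
library stores.  Intersections across a named set of libraries follow UpSet
semantics: every peptide key is assigned to exactly one exact-membership
pattern over the libraries, and patterns are counted.

The cross-library peptide key defaults to the stripped sequence, because
modification notation differs between workflows; modified-sequence keying
is available when the caller supplies a normalizer that maps each
workflow's notation to a common canonical form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .library_io import SpectralLibrary


@dataclass(frozen=True)
class DiversitySummary:
    """Distinct-element counts for one spectral library.

    ``n_genes`` is None when the library carries no gene annotation at all
    (reported as absent, not as zero).
    """

    name: str
    n_proteins: int
    n_peptides: int
    n_modified_peptides: int
    n_mpz: int
    n_genes: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.n_peptides <= self.n_modified_peptides <= self.n_mpz):
            raise ValueError(
                "diversity counts must nest: peptides <= modified peptides <= MPZs "
                f"(got {self.n_peptides}, {self.n_modified_peptides}, {self.n_mpz})"
            )


def diversity_stats(lib: SpectralLibrary) -> DiversitySummary:
    """Count distinct genes, proteins, peptides, modified peptides and MPZs."""
    if not lib.entries:
        raise ValueError(f"library {lib.name!r} is empty")
    peptides = {e.stripped_sequence for e in lib.entries}
    modified = {e.modified_sequence for e in lib.entries}
    mpz = {(e.modified_sequence, e.charge) for e in lib.entries}
    proteins = set()
    genes = set()
    any_gene_annotation = False
    for e in lib.entries:
        proteins.update(e.protein_ids)
        if e.gene_ids:
            any_gene_annotation = True
            genes.update(g for g in e.gene_ids if g)
    return DiversitySummary(
        name=lib.name,
        n_proteins=len(proteins),
        n_peptides=len(peptides),
        n_modified_peptides=len(modified),
        n_mpz=len(mpz),
        n_genes=len(genes) if any_gene_annotation else None,
    )


def diversity_ratio(after: DiversitySummary, before: DiversitySummary) -> float:
    """Peptide-diversity growth factor between two libraries (after / before).

    A thin reporting helper, e.g. for batch-to-batch library growth.
    """
    if before.n_peptides == 0:
        raise ValueError("reference library has zero peptides")
    return after.n_peptides / before.n_peptides


@dataclass
class IntersectionTable:
    """Exact-membership pattern -> peptide count over N named libraries.

    Patterns are integer bitmasks; bit i (1 << i) marks membership in
    ``library_names[i]``.  Zero-count patterns are omitted.
    """

    library_names: tuple[str, ...]
    rows: dict[int, int]
    key_kind: str = "stripped"

    def union_size(self) -> int:
        return sum(self.rows.values())

    def marginal(self, name: str) -> int:
        """Distinct-key count of one library (sum over patterns containing it)."""
        i = self.library_names.index(name)
        return sum(c for pat, c in self.rows.items() if pat >> i & 1)

    def pattern_members(self, pattern: int) -> tuple[str, ...]:
        return tuple(n for i, n in enumerate(self.library_names) if pattern >> i & 1)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: bitstring (library 0 leftmost), member names, count."""
        n = len(self.library_names)
        recs = [
            {
                "pattern": format(pat, f"0{n}b")[::-1],
                "members": ";".join(self.pattern_members(pat)),
                "count": cnt,
            }
            for pat, cnt in self.rows.items()
        ]
        df = pd.DataFrame(recs, columns=["pattern", "members", "count"])
        return df.sort_values(["count", "pattern"], ascending=[False, True]).reset_index(drop=True)


def _library_keys(
    lib: SpectralLibrary,
    key_kind: str,
    normalizer: Optional[Callable[[str], str]],
) -> set[str]:
    if key_kind == "stripped":
        return {e.stripped_sequence for e in lib.entries}
    if key_kind == "modified":
        norm = normalizer or (lambda s: s)
        return {norm(e.modified_sequence) for e in lib.entries}
    raise ValueError(f"key_kind must be 'stripped' or 'modified', got {key_kind!r}")


def intersection_counts(
    libs: Sequence[SpectralLibrary],
    key_kind: str = "stripped",
    *,
    normalizer: Optional[Callable[[str], str]] = None,
) -> IntersectionTable:
    """Count peptide keys per exact-membership pattern across libraries.

    Parameters
    ----------
    libs:
        2..16 libraries with unique names.
    key_kind:
        ``"stripped"`` (default) keys on the bare peptide sequence;
        ``"modified"`` keys on the modified sequence, normalized by
        ``normalizer`` when workflows use different notations.
    """
    if not (2 <= len(libs) <= 16):
        raise ValueError(f"need between 2 and 16 libraries, got {len(libs)}")
    names = tuple(lib.name for lib in libs)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate library names: {sorted(names)}")

    mask: dict[str, int] = {}
    for i, lib in enumerate(libs):
        bit = 1 << i
        for key in _library_keys(lib, key_kind, normalizer):
            mask[key] = mask.get(key, 0) | bit
    rows: dict[int, int] = {}
    for pat in mask.values():
        rows[pat] = rows.get(pat, 0) + 1
    return IntersectionTable(library_names=names, rows=rows, key_kind=key_kind)


def mode_only_counts(
    table: IntersectionTable, mode_of: Mapping[str, str]
) -> tuple[int, int]:
    """Peptides confined to DDA-derived or to DIA-derived libraries.

    Returns ``(dda_only, dia_only)``: the summed counts over patterns whose
    member libraries are exclusively DDA (respectively DIA).  Patterns
    mixing both acquisition modes contribute to neither.
    """
    unmapped = [n for n in table.library_names if n not in mode_of]
    if unmapped:
        raise ValueError(f"libraries without an acquisition mode: {unmapped}")
    bad = {n: m for n, m in mode_of.items() if n in table.library_names and m not in ("DDA", "DIA")}
    if bad:
        raise ValueError(f"acquisition mode must be DDA or DIA: {bad}")

    dda_only = dia_only = 0
    for pat, cnt in table.rows.items():
        modes = {mode_of[n] for n in table.pattern_members(pat)}
        if modes == {"DDA"}:
            dda_only += cnt
        elif modes == {"DIA"}:
            dia_only += cnt
    return dda_only, dia_only


# ---------------------------------------------------------------------------
# tabular / graphical output


def write_diversity_tsv(summaries: Iterable[DiversitySummary], path: str | Path) -> None:
    """One row per library: name and the five diversity counts."""
    recs = [
        {
            "name": s.name,
            "n_genes": "" if s.n_genes is None else s.n_genes,
            "n_proteins": s.n_proteins,
            "n_peptides": s.n_peptides,
            "n_modified_peptides": s.n_modified_peptides,
            "n_mpz": s.n_mpz,
        }
        for s in sorted(summaries, key=lambda s: s.name)
    ]
    pd.DataFrame(
        recs,
        columns=["name", "n_genes", "n_proteins", "n_peptides", "n_modified_peptides", "n_mpz"],
    ).to_csv(path, sep="\t", index=False)


def write_intersection_tsv(table: IntersectionTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def plot_intersections(
    table: IntersectionTable,
    path: str | Path,
    *,
    max_patterns: int = 25,
) -> None:
    """UpSet-style figure: intersection bars over a membership dot matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.to_frame().head(max_patterns)
    n_libs = len(table.library_names)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2,
        1,
        figsize=(max(6, 0.45 * len(df)), 4 + 0.3 * n_libs),
        sharex=True,
        gridspec_kw={"height_ratios": [3, 1.2]},
    )
    x = range(len(df))
    ax_bar.bar(x, df["count"], color="0.25")
    for xi, cnt in zip(x, df["count"]):
        ax_bar.text(xi, cnt, str(cnt), ha="center", va="bottom", fontsize=7)
    ax_bar.set_ylabel("peptide keys")
    ax_bar.set_title(f"exact intersections ({table.key_kind} keys)")

    for xi, pattern in enumerate(df["pattern"]):
        member = [i for i, b in enumerate(pattern) if b == "1"]
        ax_dot.scatter([xi] * n_libs, range(n_libs), s=12, color="0.85")
        if member:
            ax_dot.scatter([xi] * len(member), member, s=18, color="0.15")
            ax_dot.plot([xi, xi], [min(member), max(member)], color="0.15", lw=1)
    ax_dot.set_yticks(range(n_libs))
    ax_dot.set_yticklabels(table.library_names, fontsize=7)
    ax_dot.set_ylim(-0.5, n_libs - 0.5)
    ax_dot.invert_yaxis()
    ax_dot.set_xticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
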
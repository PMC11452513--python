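# Methods

## Harmonized parsing

Four spectral-library dialects are supported: DIA-NN `report-lib.tsv`,
FragPipe/OpenSWATH `library.tsv`, MaxQuant `evidence.txt`, and Spectronaut
`AllPeptides.tsv`/`.txt`. Dialect detection works from the header alone:
each dialect has a required column signature (with accepted alternatives,
e.g. `PeptideSequence` or `Stripped.Sequence` for DIA-NN), compared after
normalizing tokens to lowercase alphanumerics so that case and
dot/space/underscore separator variants across software versions all
match. A file must match exactly one signature; zero or several matches
raise an error naming the missing or conflicting columns.

Parsing reduces every dialect to one entry per distinct
(modified sequence, charge) precursor. Decisions baked into the readers:

* **Transitions collapse.** DIA-NN and FragPipe libraries list one row per
  fragment ion; they are collapsed to precursor level because no
  downstream statistic here consumes fragment content.
* **Duplicates keep the first precursor m/z**; a later duplicate
  disagreeing by more than 0.01 Th is logged as a conflict. Duplicate and
  invalid-row counts are kept on the library (`read_stats`) so parses are
  auditable.
* **Decoys are always dropped** (MaxQuant `Reverse == '+'` rows, or
  accession lists consisting entirely of `REV__` prefixes). **Contaminants
  are retained and flagged** (`CON__` prefixes or MaxQuant's
  `Potential contaminant`), with a `drop_contaminants` switch: in affinity
  experiments contaminant prominence is itself a finding, so discarding
  them silently would hide signal. The prefix list is configurable for
  FragPipe-style contaminant naming.
* **Modification notation is preserved verbatim** in each workflow's own
  syntax. Cross-workflow peptide comparisons key on the stripped sequence
  (below); a notation normalizer can be supplied where modified-level
  comparison is wanted. Stripping handles all four notations with one
  depth-tracking scan (nested parentheses, brackets, flanking
  underscores).
* **Entry invariants** — stripped sequence `[A-Z]+` of length ≥ 5
  (configurable), charge ≥ 1, m/z > 0, stripped sequence equal to the
  annotation-stripped modified sequence — drop the row when violated,
  counted, never silently repaired.

Quantity tables: DIA-NN/FragPipe `report.pg_matrix.tsv` (wide), MaxQuant
`proteinGroups.txt` (wide; `Reverse` and `Only identified by site` rows
dropped, contaminants flagged; run columns are the `Intensity <run>`
family), Spectronaut `Report.tsv` (long, pivoted; the (run, protein,
quantity) column triple is configurable because report templates vary;
conflicting duplicate pairs are an error), and FragPipe
`combined_protein.tsv` (per-run `Intensity` vs `MaxLFQ Intensity`
families; `Intensity` is the default since the MaxLFQ family empirically
carries more missing values). **Zeros map to missing by default**: most
DIA software distinguishes "no viable chromatogram" (blank or reported 0)
from a detected chromatogram (positive intensity). The switch
`zeros_as_missing=False` restores the literal reading. Protein-group
labels are the dialect's primary group column verbatim — no re-grouping or
parsimony across engines, so counts stay attributable to the original
software. Runs are mapped to cohorts by an explicit run-name pattern map
(exact match first, then unique substring); unmatched run columns are an
error rather than a dropped column.

## Diversity and intersections

Per-library diversity counts five nested granularities: genes, proteins,
peptides (stripped sequences), modified peptides, MPZs. `n_genes` is
reported as absent (not 0) when a library carries no gene annotation.
Intersections follow UpSet semantics: each peptide key maps to one exact
membership bitmask over N ≤ 16 libraries; pattern counts therefore sum to
the union size, and each library's marginal equals its distinct-key count
— both asserted in tests against a brute-force per-key enumeration.
DDA-only / DIA-only totals sum patterns whose member libraries are all of
one acquisition mode; mixed patterns count toward neither. The default
key is the stripped sequence, the only unit comparable across engine
notations without a mapping.

## Missingness and the quintile CV vote

For one cohort: `n_quantified_any` counts proteins with ≥ 1 observed
value across the cohort's runs; `n_unanimous` counts proteins observed in
every run. Per-run missing counts are restricted to proteins quantified
somewhere in the cohort — a protein absent everywhere is not "missing" in
any particular run.

The CV uses the sample (n−1) standard deviation over the mean, on raw
intensities. Small cohorts (3–9 runs) make the n vs n−1 distinction
material; the sample estimator is the conventional choice. Unanimous
proteins are ranked by summed intensity descending (ties broken by
protein label for determinism), split into five contiguous quintiles with
sizes as equal as possible (remainder to the top quintiles), and the
cohort votes TRUE iff median CV(Q1) < median CV(Q3) < median CV(Q5),
strictly. Ties therefore vote FALSE; with continuous intensities ties
have probability zero, and under the null the three quintile medians are
exchangeable, giving the 1/6 chance-TRUE rate that the simulation tests
verify within binomial 99% bounds. Quintiles 2 and 4 are reported but do
not enter the vote. Fewer than 10 unanimous proteins (or fewer than 2
runs) raises an explicit error instead of returning an empty report —
sparse negative-control cohorts routinely hit this, and a loud failure is
the informative outcome.

## Variable-window design

Given the precursor m/z multiset of a representative library (optionally
clamped to [floor, ceiling]; values outside are ignored), interior
boundaries b₁…b₍ₙ₋₁₎ are type-1 empirical quantiles: bᵢ is the
⌈i·N/n⌉-th order statistic, deterministic and checkable against a plain
sort. Window i spans [⌊bᵢ₋₁⌋, ⌈bᵢ⌉]; an interior boundary landing exactly
on an integer has its stop bumped to bᵢ+1. Both rules guarantee every
consecutive pair overlaps by exactly 1 m/z, and integer boundaries make
manual entry into instrument software less error-prone.

Occupancy diagnostics attribute precursors by the *exact* stored
boundaries (value in (bᵢ₋₁, bᵢ] → window i, boundary values to the lower
window), under which the max−min occupancy spread is ≤ 2 regardless of
m/z density. Attribution by the rounded integer edges is also available
but is only a diagnostic: at realistic densities (tens of precursors per
Th) a 1-Th rounding shift moves many boundary-adjacent ions, so the
integer partition cannot bound the spread — the rounding serves the
instrument, not the statistics. Cycle arithmetic is exact by
construction: cycle = n/rate, points-per-peak = peak·rate/n.

## Synthetic data

The generator emulates the structure of a multi-workflow, multi-cohort
DIA study. Defaults (all overridable, all driven by one seed):

* **Universe**: 400 proteins × 4–20 tryptic-like peptides (length 7–24,
  C-terminal K/R), globally unique; charges drawn from {2: 0.6, 3: 0.3,
  4: 0.1} restricted to those keeping m/z in 350–1400 Th, a second charge
  with probability 0.3. Monoisotopic m/z comes from pyteomics residue
  masses plus modification masses and z protons. Fixed Cys chemistry is
  chosen from the shifts seen across real platforms (+45.987721 MMTS —
  the default, +57.021464 carbamidomethyl, +71.037114 propionamide, or
  none); Met oxidation with probability 0.2. The first 10 proteins form a
  keratin-like contaminant block, flagged via the `CON__` convention in
  MaxQuant-dialect output only, matching how the engines differ on
  contaminant handling.
* **Libraries**: six workflows (DIA-NN/DIA, FragPipe/DDA, FragPipe/DIA,
  MaxQuant/DDA, Spectronaut/DDA, Spectronaut/DIA — the feasible engine ×
  mode pairs). Each peptide is shared (76%), DDA-only (8%), DIA-only
  (8%), or engine-preferring (8%, contaminants always shared); within its
  eligible libraries each precursor is detected with rate 0.9. Setting
  the rate to 1 makes every planted count exact, which the recovery tests
  exploit.
* **Quantities**: protein truth intensity log-normal (log₁₀ mean 6,
  sd 1.2); run value I·(1+ε) with sd(ε) = a + b·I^(−1/2) (defaults
  a = 0.05, b = 25, floored at I/1000), so CV falls with intensity;
  missing with probability min(1, scale·logistic((mid − log₁₀I)/slope)),
  scale per run. The default nine-run cohort uses scales
  (0.9, 0.9, 0.9, 0.3, 0.3, 0.3, 0.1, 0.1, 0.1), three runs at each of
  three depths, emulating short/medium/long gradients with per-run
  missingness in roughly the 18% / 6% / 2% proportions a depth-graded
  enrichment series shows.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: fragment-level content and interference,
retention-time structure, charge-state-dependent detectability, shared
(razor) peptides across protein groups, correlated missingness between
runs beyond the per-run depth factor, and batch effects. Statistical
conclusions from the simulations (vote power and null rate, recovery
exactness) are claims about the model above, not about any instrument.

## Numerical and testing choices

Vote power and null rate are measured on 200 simulated cohorts of 500
proteins × 4 runs — sizes at which the binomial 99% band around 1/6 is
informative (±~7 percentage points) and the whole acceptance script still
runs in seconds. Intersection oracle checks enumerate 10 libraries ×
10⁴ keys. CV agreement with an independent two-pass oracle is required to
1e-12 relative. Determinism: every stochastic path takes a
`numpy.random.Generator` seeded from the configuration seed (sub-streams
keyed by fixed integers and, for cohorts, the cohort name), so identical
configs give byte-identical fixture files; pipeline outputs are sorted on
explicit keys (library name, pattern bitstring, protein id) so reruns
diff clean.

## Known limitations

Real-world exports deviate more than the tolerated header variants:
Spectronaut report templates can rename all three pivot columns (hence
the configurable triple), FragPipe summary columns differ across
versions, and MaxQuant site-level tables are out of scope. Modified-
sequence intersection requires a user-supplied notation normalizer; no
built-in UniMod mapping table ships with the package. The designer does
not schedule FAIMS compensation voltages or emit vendor method files —
its output is the instrument-entry table only.
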
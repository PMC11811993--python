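# Methods

## Scope and model

`diaquant` post-processes label-free DIA proteomics results that have
already been searched and quantified (DIA-NN-style precursor reports). The
unit of reporting is the *canonical protein*, identified with its parent
gene id ("one protein sequence per gene"), so "gene" and "protein" are used
interchangeably below. The pipeline assumes:

- each dataset was searched independently against the same target database
  (optionally augmented with entrapment and contaminant sequences), with a
  run-level q-value threshold already applied upstream (we re-apply 0.01 at
  ingest as a guard);
- precursor quantities are LFQ intensities on an arbitrary multiplicative
  scale, comparable within a run but subject to large batch effects between
  samples and datasets;
- evidence quality is adequately proxied by peptide support: a protein is
  trusted in a run only with ≥ 2 distinct stripped peptide sequences.

## Filtering

Filters run in a fixed order: contaminants → multi-mapped groups → minimum
unique peptides → sample-status selection. A record is contaminated if *any*
member of its protein group is a contaminant accession (conservative:
ambiguous evidence is removed). Multi-mapped means more than one protein or
gene identifier in the group. "Unique peptide" counts distinct stripped
(unmodified) sequences, not peptidoforms or precursors, per (run, gene).
The first two filters commute and all filters are idempotent; removal
counts are logged and recorded in the run manifest so input = survivors +
removals at every stage.

## Quantification

Per-run gene abundance is the median of the gene's precursor quantities in
that run; per-sample abundance is the median over the sample's runs,
ignoring runs where the gene is missing. Medians are used throughout for
robustness to peptide-specific response factors and occasional outlier
precursors.

iBAQ divides the LFQ value by the gene's count of theoretical tryptic
peptides. Digestion defaults: cleave after K or R, suppressed before P, no
missed cleavages, peptide length 7–30 — the usual identifiable range and
the defaults of the search engine family these reports come from. All of
this is configurable (`DigestionRules`). Genes whose sequence yields no
in-range peptide cannot receive an iBAQ value and are dropped with a
warning. The digestion is implemented directly (it determines every iBAQ
value) and is verified in the tests against a brute-force
enumerate-all-substrings oracle and against an independent
regex-rule implementation from pyteomics.

Binning sorts each sample's present iBAQ values ascending and assigns bins
1..5 whose sizes differ by at most one. Binning is per column by default
(per-sample quantiles remove between-sample scale effects; a `global` scope
is available). Ties are broken by stable input order; when the count is not
a multiple of the bin number, the lowest bins absorb the remainder. Bins
are invariant to positive rescaling of a column, and larger abundance never
gets a smaller bin.

## Entrapment FDR

Protein groups whose gene identifiers are *exclusively* from the entrapment
species are decoys; mixed groups are targets. Group identity across
datasets is the sorted gene-id tuple. For each `k`, `D(≥k)` and `T(≥k)`
count decoy/target groups present in at least `k` datasets and

    FDR(k) = Dn · D(≥k) / T(≥k),   Dn = |target db| / |entrapment db|.

`Dn` defaults to the exact size ratio; a `rounded` mode (one decimal) is
available since the factor is conventionally quoted rounded. The estimate
is reported unclamped alongside a value clamped to [0, 1]: on small inputs
an entrapment estimator can exceed 1. `FDR(k)` is undefined (flagged NaN)
when no target reaches `k` datasets. The cumulative counts are
non-increasing in `k`, and the table is exactly consistent with the
exact-`k` presence histogram's reverse cumulative sums (a test asserts
this).

## Missingness, correlation, coverage

`Fm = NA / (n · g)` is computed per (dataset, tissue) block with `g` the
genes having ≥ 1 present value *within that block* (not the global gene
universe — the normalization is by observations actually possible in the
block; a dataset-wide alternative would only rescale all blocks of a
dataset identically). The dataset summary is the median over its tissue
blocks. By construction 0 ≤ Fm < 1 whenever g > 0.

Pairwise sample correlations use binned values restricted to proteins
present in both samples ("commonly identified", read literally as
non-missing in both). Cells with < 3 common proteins or zero variance are
undefined. R² (squared Pearson) is reported with the signed r kept as a
companion field — squaring hides anticorrelation, which matters for
diagnostics. Group medians (per tissue, and per tissue × dataset, since a
multi-dataset tissue can be summarized either way) take the median of
defined off-diagonal cells.

Cross-study comparison joins two gene × tissue tables on shared genes per
common tissue, optionally log2-transforms, and reports per-tissue R² with
the joined gene count n. Coverage counts a gene as identified in a tissue
if present in ≥ 1 of its samples; percentages are of the overall distinct
gene total, rounded to one decimal (the same one-decimal convention used by
the overlap summary, whose percentages are computed against |a| for common
and a-only and |b| for b-only).

## Synthetic data generator

The generator emulates the structure of a multi-dataset human tissue DIA
reanalysis; it is the ground truth for all statistical tests.

- **Design.** Default: 3 datasets × 3 tissues × 4 samples/tissue × 2
  runs/sample (72 runs) — small enough for fast tests, large enough for
  stable rate estimates. `design_from_counts()` instead reproduces an
  explicit per-dataset table; its default is the 15-dataset / 12-tissue /
  356-run / 178-sample human tissue study design with runs split as evenly
  as possible across samples.
- **Databases.** 300 target and 600 entrapment genes by default — the 2:1
  entrapment:target ratio mirrors the Arabidopsis:human one-per-gene
  database sizes (41,621 : 20,838, Dn ≈ 0.5). Sequences are concatenations
  of 3–12 tryptic segments of 7–30 residues (never starting with P), so
  every protein digests to at least one — typically several — in-range
  peptides.
- **Abundances.** Gene base abundance is log-normal, log10 mean 6, sd 1
  (LFQ-like intensities 1e4–1e8). A core fraction (default 0.15) of genes
  is expressed in every tissue; the rest are present per tissue with
  probability 0.5 (at least one tissue). Tissue effects add sd 0.6 and
  samples scatter around their tissue profile with sd 0.25 (log10) — noise
  levels that make within-tissue correlation clearly exceed between-tissue
  correlation without making recovery trivial.
- **Reports.** Observed peptides per protein: 1 + Poisson(3), capped at the
  digest size, so a realistic minority of observations fail the ≥ 2-peptide
  filter. Peptide response factors are log-normal (sd 0.5 decades, fixed
  per peptide across runs); row quantities add log-normal noise (sd 0.25).
  Dropout is logistic in log10 abundance (max 0.6, midpoint 1e4.5,
  steepness 1.5 per decade): low-abundance proteins go missing more often,
  the abundance-dependent missingness DDA/DIA comparisons assume.
- **Injections.** Decoy (entrapment-only) groups are emitted with odds
  r/(1−r) per emitted target group (default r = 0.02), so the expected
  decoy share of emitted groups is exactly r; decoys carry ≥ 2 peptides so
  they survive the peptide filter and are visible to the FDR stage.
  Multi-gene groups (rate 0.02 per emitted group) pair the gene with a
  random second target gene. Contaminants appear per run with probability
  0.3 each. Every injection is logged per dataset, which is how tests
  compare filter removals and FDR counts against ground truth.
- **Determinism.** All draws flow from one integer seed through named
  streams; regenerating a study is byte-identical, and report files
  round-trip losslessly (floats written via `repr`).

What the generator does *not* emulate: spectra, retention times,
chromatogram-level interference, match-between-runs artifacts, shared
peptides between homologous proteins, fractionation, or realistic
contaminant dynamics. Passing tests therefore demonstrate correctness of
the post-processing arithmetic and its statistical behaviour under the
stated generative model — not search-engine-level identification quality on
real data.

## Numerical and design choices

- Medians of even-sized sets are the mean of the middle two (standard).
- `pd.to_numeric`'s fast float path is used only to locate unparseable
  rows; actual conversion uses exact correctly-rounded parsing so written
  reports round-trip bit-exactly.
- Binning tie-break and remainder placement are fixed (stable order, lowest
  bins first) purely for determinism; any consistent choice would do.
- Abundance matrices exclude entrapment genes (decoys are an FDR device,
  not biology); the FDR stage sees all filtered groups.
- Problem sizes in the test suite (hundreds of genes, tens of runs; 60
  genes for the 356-run design check) keep the full suite under a minute
  while leaving ≥ 3σ headroom on every rate assertion.

## Known limitations

- The ≥ 2-peptide filter is applied per run before median aggregation;
  alternative orderings (e.g. per dataset) would retain slightly different
  evidence and are not exposed.
- `Fm` with very aggressive dropout underestimates the model dropout rate
  because fully-missing genes drop out of `g`; the generator-level test
  therefore checks dropout at the report level.
- The entrapment FDR estimator assumes decoy observations are exchangeable
  with false target observations up to the Dn factor; with structured decoy
  injection (as in reality with homologous sequences) it is only an
  approximation.
- Correlation cells are computed pairwise-complete; the per-cell gene sets
  differ, so the matrix need not be positive semi-definite.
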
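"""Missingness, coverage, overlap and correlation analytics.

These operate on sample-level abundance matrices: the fraction of
missingness Fm = NA / (n x g) per tissue block (g counts only genes seen at
least once within the block), pairwise squared Pearson correlations of
binned abundances restricted to commonly identified proteins, per-group
median correlations, cross-study per-tissue correlations of log2 median
abundances, and identification-overlap / coverage summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .quantify import AbundanceMatrix


def percentage(part: float, total: float) -> float:
    """Percentage rounded to one decimal, the reporting convention used throughout."""
    if total == 0:
        raise InvalidParameterError("percentage of an empty total is undefined")
    return round(100.0 * part / total, 1)


# ---------------------------------------------------------------------------
# missingness


@dataclass
class MissingnessResult:
    """Per-tissue Fm values and their per-dataset medians."""

    per_tissue: pd.DataFrame   # dataset_id, tissue, n, g, na_count, fm
    per_dataset: pd.DataFrame  # dataset_id, fm_median


def missingness_fm(matrix: AbundanceMatrix, metadata: pd.DataFrame | None = None) -> MissingnessResult:
    """Fraction of missingness per (dataset, tissue) block.

    For each tissue within a dataset: ``n`` = number of samples, ``g`` =
    genes with at least one present value among those samples, ``fm`` =
    missing cells within the n x g block divided by n x g.  A dataset's
    summary is the median of its tissue fm values.  A tissue block with no
    identified genes has undefined fm (NaN, flagged).
    """
    meta = matrix.column_meta
    rows = []
    for (ds, tissue), cols in meta.groupby(["dataset_id", "tissue"]).groups.items():
        block = matrix.values[list(cols)]
        present = block.notna()
        identified = present.any(axis=1)
        g = int(identified.sum())
        n = len(cols)
        if g == 0:
            rows.append({"dataset_id": ds, "tissue": tissue, "n": n, "g": 0,
                         "na_count": 0, "fm": np.nan})
            continue
        sub = present.loc[identified]
        na = int((~sub).to_numpy().sum())
        rows.append({"dataset_id": ds, "tissue": tissue, "n": n, "g": g,
                     "na_count": na, "fm": na / (n * g)})
    per_tissue = pd.DataFrame(rows).sort_values(["dataset_id", "tissue"]).reset_index(drop=True)
    per_dataset = (
        per_tissue.groupby("dataset_id")["fm"].median().rename("fm_median").reset_index()
    )
    return MissingnessResult(per_tissue=per_tissue, per_dataset=per_dataset)


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationMatrix:
    """Pairwise sample correlations on commonly identified proteins.

    ``r2`` is the squared Pearson correlation; the signed ``r`` is kept as a
    companion for diagnostics (binned anticorrelation squares to the same
    r2).  ``n_common`` counts the genes present in both samples of a pair.
    Cells with fewer than ``min_common`` shared genes or zero variance in
    either sub-vector are undefined (NaN).
    """

    r2: pd.DataFrame
    r: pd.DataFrame
    n_common: pd.DataFrame
    column_meta: pd.DataFrame


def pairwise_binned_correlation(
    matrix: AbundanceMatrix, min_common: int = 3
) -> CorrelationMatrix:
    """Pearson correlation of binned abundances for every sample pair.

    For each pair only the proteins identified (present) in both samples are
    used, so each cell is computed on its own sub-vector.
    """
    if matrix.stage != "binned":
        raise InvalidParameterError("pairwise correlation expects a binned matrix")
    arr = matrix.values.to_numpy(dtype=float)
    cols = list(matrix.values.columns)
    m = len(cols)
    mask = ~np.isnan(arr)
    r = np.full((m, m), np.nan)
    n_common = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i, m):
            both = mask[:, i] & mask[:, j]
            n = int(both.sum())
            n_common[i, j] = n_common[j, i] = n
            if n < min_common:
                continue
            x, y = arr[both, i], arr[both, j]
            if x.std() == 0 or y.std() == 0:
                continue
            rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = rij
    idx = pd.Index(cols, name="sample")
    return CorrelationMatrix(
        r2=pd.DataFrame(r**2, index=idx, columns=idx),
        r=pd.DataFrame(r, index=idx, columns=idx),
        n_common=pd.DataFrame(n_common, index=idx, columns=idx),
        column_meta=matrix.column_meta,
    )


def median_group_correlation(corr: CorrelationMatrix, group_by: str | list[str]) -> pd.Series:
    """Median off-diagonal r2 over sample pairs sharing a group label.

    ``group_by`` is a column (or list of columns) of the correlation's sample
    metadata, e.g. ``"tissue"`` or ``["tissue", "dataset_id"]``.  Groups with
    fewer than two samples have an undefined median (NaN).
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    labels = corr.column_meta[group_by].astype(str).agg("|".join, axis=1)
    out = {}
    for group, samples in labels.groupby(labels).groups.items():
        samples = list(samples)
        if len(samples) < 2:
            out[group] = np.nan
            continue
        sub = corr.r2.loc[samples, samples].to_numpy()
        off = sub[np.triu_indices(len(samples), k=1)]
        off = off[~np.isnan(off)]
        out[group] = float(np.median(off)) if off.size else np.nan
    return pd.Series(out, name="median_r2").sort_index()


def cross_study_compare(
    a: pd.DataFrame,
    b: pd.DataFrame,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-tissue correlation between two gene x tissue abundance tables.

    Tables from different studies are joined on their shared gene-identifier
    namespace per common tissue; values are optionally log2-transformed
    before the Pearson correlation.  Reports r2 and the joined gene count n
    per tissue; tissues with fewer than 3 shared genes (or zero variance)
    are undefined.
    """
    tissues = sorted(set(a.columns) & set(b.columns))
    if not tissues:
        raise InvalidParameterError("no common tissues between the two tables")
    rows = []
    for tissue in tissues:
        joined = pd.concat(
            [a[tissue].rename("a"), b[tissue].rename("b")], axis=1, join="inner"
        ).dropna()
        n = len(joined)
        if n < 3 or joined["a"].std() == 0 or joined["b"].std() == 0:
            rows.append({"tissue": tissue, "r2": np.nan, "r": np.nan, "n": n})
            continue
        x, y = joined["a"].to_numpy(float), joined["b"].to_numpy(float)
        if log_transform:
            if np.any(x <= 0) or np.any(y <= 0):
                raise InvalidParameterError("log2 transform requires positive abundances")
            x, y = np.log2(x), np.log2(y)
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append({"tissue": tissue, "r2": r**2, "r": r, "n": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap and coverage


@dataclass
class OverlapSummary:
    n_a: int
    n_b: int
    n_common: int
    n_a_only: int
    n_b_only: int
    pct_common_of_a: float
    pct_a_only_of_a: float
    pct_b_only_of_b: float


def overlap_summary(set_a: set, set_b: set) -> OverlapSummary:
    """Identification overlap between two gene sets.

    Percentages follow the convention of reporting common and a-only
    identifications against |a| and b-only against |b|, rounded to one
    decimal.  Conservation holds exactly: common + a-only = |a| and
    common + b-only = |b|.
    """
    set_a, set_b = set(set_a), set(set_b)
    if not set_a and not set_b:
        raise InvalidParameterError("overlap of two empty sets is undefined")
    common = len(set_a & set_b)
    return OverlapSummary(
        n_a=len(set_a),
        n_b=len(set_b),
        n_common=common,
        n_a_only=len(set_a) - common,
        n_b_only=len(set_b) - common,
        pct_common_of_a=percentage(common, len(set_a)) if set_a else np.nan,
        pct_a_only_of_a=percentage(len(set_a) - common, len(set_a)) if set_a else np.nan,
        pct_b_only_of_b=percentage(len(set_b) - common, len(set_b)) if set_b else np.nan,
    )


@dataclass
class CoverageSummary:
    """Identified-gene tallies per tissue and dataset.

    A gene counts as identified in a tissue (or dataset) if present in at
    least one of its samples; percentages are of the overall distinct-gene
    total.  ``n_all_tissues`` / ``n_single_tissue`` count genes observed in
    every tissue and in exactly one tissue.
    """

    total_genes: int
    per_tissue: pd.DataFrame   # tissue, n_genes, pct
    per_dataset: pd.DataFrame  # dataset_id, n_genes, pct
    n_all_tissues: int
    n_single_tissue: int


def coverage_summary(matrix: AbundanceMatrix) -> CoverageSummary:
    present = matrix.values.notna()
    identified_any = present.any(axis=1)
    total = int(identified_any.sum())
    meta = matrix.column_meta

    def _per(label: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        blocks = {}
        for value, cols in meta.groupby(label).groups.items():
            blocks[value] = present[list(cols)].any(axis=1)
        return pd.DataFrame(blocks)

    tissue_presence = _per("tissue")
    per_tissue = pd.DataFrame(
        {
            "tissue": tissue_presence.columns,
            "n_genes": tissue_presence.sum().to_numpy(),
        }
    )
    per_tissue["pct"] = [percentage(n, total) for n in per_tissue["n_genes"]]
    ds_presence = _per("dataset_id")
    per_dataset = pd.DataFrame(
        {
            "dataset_id": ds_presence.columns,
            "n_genes": ds_presence.sum().to_numpy(),
        }
    )
    per_dataset["pct"] = [percentage(n, total) for n in per_dataset["n_genes"]]

    tissues_per_gene = tissue_presence.sum(axis=1)
    n_tissues = tissue_presence.shape[1]
    return CoverageSummary(
        total_genes=total,
        per_tissue=per_tissue.sort_values("tissue").reset_index(drop=True),
        per_dataset=per_dataset.sort_values("dataset_id").reset_index(drop=True),
        n_all_tissues=int((tissues_per_gene == n_tissues).sum()),
        n_single_tissue=int((tissues_per_gene == 1).sum()),
    )
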
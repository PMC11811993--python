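"""From filtered peptide evidence to per-run / per-sample iBAQ abundances
and ranked quintile bins.

All aggregation uses medians: peptide quantities -> per-run gene abundance,
run abundances -> per-sample abundance.  LFQ values become iBAQ by dividing
by the gene's theoretical tryptic peptide count, and iBAQ values are ranked
into bins of (near) equal size per sample — bin 1 lowest, bin ``n_bins``
highest — which removes between-sample scale effects before correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digestion import PeptideCounts
from .errors import (
    BinningError,
    ConsistencyError,
    InvalidParameterError,
    MappingError,
)

logger = logging.getLogger(__name__)

STAGES = ("lfq", "ibaq", "binned")


@dataclass
class AbundanceMatrix:
    """Gene x column abundance grid with explicit missing cells (NaN).

    ``columns`` are MS runs or samples; ``column_meta`` (indexed by column)
    carries tissue and dataset labels and, for run matrices, the sample id.
    ``stage`` is one of ``lfq`` / ``ibaq`` (positive reals) or ``binned``
    (integers 1..n_bins).
    """

    values: pd.DataFrame
    stage: str
    column_meta: pd.DataFrame

    def __post_init__(self):
        if self.stage not in STAGES:
            raise InvalidParameterError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if set(self.values.columns) != set(self.column_meta.index):
            raise ConsistencyError("column metadata does not match matrix columns")
        self.column_meta = self.column_meta.loc[self.values.columns]
        arr = self.values.to_numpy(dtype=float)
        present = arr[~np.isnan(arr)]
        if self.stage in ("lfq", "ibaq") and np.any(present <= 0):
            raise ConsistencyError(f"{self.stage} values must be strictly positive")
        if self.stage == "binned" and present.size and np.any(present != np.round(present)):
            raise ConsistencyError("binned values must be integers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _single_gene(records: pd.DataFrame) -> pd.Series:
    if records["gene_group"].map(len).gt(1).any():
        raise InvalidParameterError(
            "records must be single-gene; apply filter_multimapped first"
        )
    return records["gene_group"].str[0]


def aggregate_run_abundance(records: pd.DataFrame, metadata: pd.DataFrame) -> AbundanceMatrix:
    """Median of each gene's precursor quantities within each MS run (stage=lfq)."""
    gene = _single_gene(records)
    matrix = records.assign(gene=gene).pivot_table(
        index="gene", columns="run_id", values="quantity", aggfunc="median"
    )
    matrix.index.name = "gene"
    meta = metadata.set_index("run_id")[["sample_id", "tissue", "dataset_id"]]
    unknown = set(matrix.columns) - set(meta.index)
    if unknown:
        raise MappingError(f"runs absent from metadata: {sorted(unknown)[:5]}")
    return AbundanceMatrix(values=matrix.sort_index(), stage="lfq",
                           column_meta=meta.loc[matrix.columns])


def aggregate_sample_abundance(run_matrix: AbundanceMatrix, metadata: pd.DataFrame) -> AbundanceMatrix:
    """Collapse run columns to samples by median, ignoring missing runs.

    A (gene, sample) cell is missing only if the gene is missing in every run
    of the sample.
    """
    if "sample_id" not in run_matrix.column_meta:
        raise MappingError("run matrix carries no sample mapping")
    sample_of_run = run_matrix.column_meta["sample_id"]
    if sample_of_run.isna().any():
        raise MappingError("unmapped run column")
    values = run_matrix.values.T.groupby(sample_of_run).median().T
    meta = (
        metadata.drop_duplicates("sample_id")
        .set_index("sample_id")[["tissue", "dataset_id", "disease_status"]]
    )
    unknown = set(values.columns) - set(meta.index)
    if unknown:
        raise MappingError(f"samples absent from metadata: {sorted(unknown)[:5]}")
    return AbundanceMatrix(values=values, stage=run_matrix.stage,
                           column_meta=meta.loc[values.columns])


def lfq_to_ibaq(matrix: AbundanceMatrix, counts: PeptideCounts) -> AbundanceMatrix:
    """iBAQ(gene, col) = LFQ(gene, col) / theoretical peptide count of the gene.

    Genes whose count is zero cannot be normalized and are dropped with a
    warning; a gene missing from ``counts`` altogether is an inconsistency
    between the matrix and the sequence database.
    """
    if matrix.stage != "lfq":
        raise InvalidParameterError("lfq_to_ibaq expects a stage='lfq' matrix")
    absent = set(matrix.values.index) - set(counts.counts.index)
    if absent:
        raise ConsistencyError(
            f"{len(absent)} genes have no theoretical peptide count: {sorted(absent)[:5]}"
        )
    zero = [g for g in matrix.values.index if g in counts.zero_count_genes]
    if zero:
        logger.warning("dropping %d genes with zero theoretical peptides", len(zero))
    kept = matrix.values.drop(index=zero)
    ibaq = kept.div(counts.counts.reindex(kept.index), axis=0)
    return AbundanceMatrix(values=ibaq, stage="ibaq", column_meta=matrix.column_meta)


def _bin_column(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign sorted-rank bins 1..n_bins of sizes differing by at most one.

    The stable argsort breaks ties by input order; when the count is not a
    multiple of ``n_bins`` the lowest bins absorb the remainder.
    """
    present = ~np.isnan(values)
    n = int(present.sum())
    out = np.full(values.shape, np.nan)
    order = np.argsort(values[present], kind="stable")
    sizes = [n // n_bins + (1 if i < n % n_bins else 0) for i in range(n_bins)]
    labels = np.repeat(np.arange(1, n_bins + 1), sizes)
    binned = np.empty(n)
    binned[order] = labels
    out[present] = binned
    return out


def bin_abundances(
    matrix: AbundanceMatrix, n_bins: int = 5, scope: str = "column"
) -> AbundanceMatrix:
    """Rank present values into ``n_bins`` near-equal bins (stage=binned).

    ``scope='column'`` (default) bins each sample independently — per-sample
    quantiles remove between-sample scale differences; ``scope='global'``
    pools all present cells into one ranking.
    """
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    if matrix.stage == "binned":
        raise InvalidParameterError("matrix is already binned")
    if scope not in ("column", "global"):
        raise InvalidParameterError("scope must be 'column' or 'global'")
    arr = matrix.values.to_numpy(dtype=float)
    if scope == "global":
        flat = arr.ravel()
        if int((~np.isnan(flat)).sum()) < n_bins:
            raise BinningError(f"fewer than {n_bins} present values overall")
        binned = _bin_column(flat, n_bins).reshape(arr.shape)
    else:
        binned = np.empty_like(arr)
        for j, col in enumerate(matrix.values.columns):
            n_present = int((~np.isnan(arr[:, j])).sum())
            if n_present < n_bins:
                raise BinningError(
                    f"column {col!r} has {n_present} present values, fewer than {n_bins} bins"
                )
            binned[:, j] = _bin_column(arr[:, j], n_bins)
    values = pd.DataFrame(binned, index=matrix.values.index, columns=matrix.values.columns)
    return AbundanceMatrix(values=values, stage="binned", column_meta=matrix.column_meta)
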
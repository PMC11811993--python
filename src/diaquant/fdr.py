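"""Entrapment-based protein FDR across datasets.

Each dataset is searched against a target database augmented with sequences
from a foreign species (the entrapment database).  Protein groups whose gene
identifiers belong exclusively to the entrapment species are decoys; all
other groups are targets.  Because the two databases differ in size, decoy
counts are rescaled by the database normalizing factor
``Dn = target_db_size / entrapment_db_size`` and the combined FDR for
proteins observed in at least ``k`` datasets is estimated as

    FDR(k) = Dn * D(>=k) / T(>=k)

where D(>=k) and T(>=k) count decoy and target groups present in >= k
datasets.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import IntegrityError, InvalidParameterError


def compute_dn(target_db_size: int, entrapment_db_size: int) -> float:
    """Database normalizing factor: target size over entrapment size."""
    if target_db_size < 1 or entrapment_db_size < 1:
        raise InvalidParameterError("database sizes must be >= 1")
    return target_db_size / entrapment_db_size


def extract_protein_groups(records: pd.DataFrame) -> dict[str, set[tuple[str, ...]]]:
    """Distinct gene-level protein groups per dataset from filtered evidence."""
    out: dict[str, set[tuple[str, ...]]] = {}
    for ds, grp in records.groupby("dataset_id"):
        out[str(ds)] = set(grp["gene_group"])
    return out


def classify_protein_groups(
    groups_by_dataset: Mapping[str, Iterable[tuple[str, ...]]],
    entrapment_genes: set[str],
) -> pd.DataFrame:
    """Build the presence table: one row per distinct group identity.

    Group identity across datasets is the sorted gene-id tuple.  A group is a
    decoy iff *every* gene it contains carries the entrapment tag — a mixed
    target/entrapment group counts as a target.  ``datasets_present`` is the
    number of datasets in which the group was observed.
    """
    presence: dict[tuple[str, ...], set[str]] = {}
    for ds, groups in groups_by_dataset.items():
        for genes in groups:
            genes = tuple(sorted(genes))
            if not genes or any(not g for g in genes):
                raise IntegrityError(f"protein group with empty gene list in dataset {ds!r}")
            presence.setdefault(genes, set()).add(ds)
    rows = [
        {
            "group_id": ";".join(genes),
            "genes": genes,
            "is_decoy": all(g in entrapment_genes for g in genes),
            "datasets_present": len(ds_set),
        }
        for genes, ds_set in sorted(presence.items())
    ]
    return pd.DataFrame(rows, columns=["group_id", "genes", "is_decoy", "datasets_present"])


def fdr_at_k(presence: pd.DataFrame, dn: float) -> pd.DataFrame:
    """Cumulative FDR table for k = 1 .. max observed dataset count.

    ``fdr`` is Dn * decoys_at_k / targets_at_k, left NaN (undefined) where no
    target reaches k datasets; ``fdr_clamped`` caps the estimate at 1 (an
    entrapment estimator can exceed 1 on tiny inputs).
    """
    if presence.empty:
        raise InvalidParameterError("empty presence table")
    if dn <= 0:
        raise InvalidParameterError("dn must be > 0")
    kmax = int(presence["datasets_present"].max())
    rows = []
    for k in range(1, kmax + 1):
        at_k = presence["datasets_present"] >= k
        d = int((at_k & presence["is_decoy"]).sum())
        t = int((at_k & ~presence["is_decoy"]).sum())
        fdr = dn * d / t if t > 0 else np.nan
        rows.append(
            {
                "k": k,
                "decoys_at_k": d,
                "targets_at_k": t,
                "fdr": fdr,
                "fdr_clamped": min(fdr, 1.0) if t > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def decoy_presence_histogram(presence: pd.DataFrame) -> pd.DataFrame:
    """Counts of decoy and target groups present in *exactly* k datasets.

    Column sums recover the total number of distinct decoy and target groups.
    """
    if presence.empty:
        raise InvalidParameterError("empty presence table")
    kmax = int(presence["datasets_present"].max())
    ks = pd.RangeIndex(1, kmax + 1, name="k")
    decoy = (
        presence.loc[presence["is_decoy"], "datasets_present"]
        .value_counts().reindex(ks, fill_value=0)
    )
    target = (
        presence.loc[~presence["is_decoy"], "datasets_present"]
        .value_counts().reindex(ks, fill_value=0)
    )
    return pd.DataFrame(
        {"k": ks, "decoy_count": decoy.to_numpy(), "target_count": target.to_numpy()}
    )
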
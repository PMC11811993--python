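"""Reading DIA-NN-style reports, FASTA databases and SDRF metadata, and the
row/protein-level evidence filters applied before quantification.

Filter order is fixed: contaminants -> multi-mapped groups -> minimum unique
peptides per (run, gene).  The last filter must see only single-gene records,
which the multi-map filter guarantees.  Each filter logs how many records it
removed; input count always equals survivors plus removals.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, IntegrityError, InvalidParameterError, MappingError
from .seqdb import DBEntry, ProteinSequenceDB

logger = logging.getLogger(__name__)

#: Default column-name map for DIA-NN 1.8.x report files.  Override for other
#: report dialects whose column names drift.
DIANN_DIALECT: dict[str, str] = {
    "run_id": "Run",
    "protein_group": "Protein.Group",
    "gene_group": "Genes",
    "stripped_peptide": "Stripped.Sequence",
    "quantity": "Precursor.Quantity",
    "q_value": "Q.Value",
}

RECORD_COLUMNS = [
    "run_id",
    "dataset_id",
    "protein_group",
    "gene_group",
    "stripped_peptide",
    "quantity",
    "q_value",
]


def read_report(
    path: str | Path,
    dataset_id: str,
    dialect: dict[str, str] = DIANN_DIALECT,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Parse a precursor report into one record per row.

    Multi-member protein/gene groups are split on ``;`` into tuples.  Rows
    with q-value above ``q_threshold`` (default 0.01, the run-level threshold
    used at search time) are dropped and the drop count logged.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [col for col in dialect.values() if col not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")

    out = pd.DataFrame(index=raw.index)
    out["run_id"] = raw[dialect["run_id"]]
    out["dataset_id"] = dataset_id
    for field in ("quantity", "q_value"):
        probe = pd.to_numeric(raw[dialect[field]], errors="coerce")
        bad = probe.isna() | (raw[dialect[field]].str.strip() == "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path.name}: unparseable {field} "
                f"{raw[dialect[field]][bad.idxmax()]!r} at line {line}"
            )
        # exact (correctly rounded) parse; pandas' fast path is only a probe
        out[field] = raw[dialect[field]].map(float)
    if ((out["q_value"] < 0) | (out["q_value"] > 1)).any():
        raise FormatError(f"{path.name}: q_value outside [0, 1]")
    if (out["quantity"] < 0).any():
        raise FormatError(f"{path.name}: negative quantity")

    for field in ("protein_group", "gene_group"):
        col = raw[dialect[field]]
        if (col.str.strip() == "").any():
            line = int((col.str.strip() == "").idxmax()) + 2
            raise FormatError(f"{path.name}: empty {field} at line {line}")
        out[field] = col.map(lambda s: tuple(s.split(";")))
    out["stripped_peptide"] = raw[dialect["stripped_peptide"]]

    keep = out["q_value"] <= q_threshold
    if (~keep).any():
        logger.info(
            "%s: dropped %d/%d rows above q-value threshold %g",
            path.name, int((~keep).sum()), len(out), q_threshold,
        )
    return out.loc[keep, RECORD_COLUMNS].reset_index(drop=True)


_GN_RE = re.compile(r"\bGN=(\S+)")
_OS_RE = re.compile(r"\bOS=(.+?)(?:\s+\w\w=|$)")


def read_fasta(
    path: str | Path,
    organism_tag: str,
    contaminant: bool = False,
) -> ProteinSequenceDB:
    """Load a FASTA database, taking the gene id from ``GN=`` (accession if absent)."""
    db = ProteinSequenceDB()
    for record in SeqIO.parse(str(path), "fasta"):
        gn = _GN_RE.search(record.description)
        db.add(
            DBEntry(
                accession=record.id,
                gene=gn.group(1) if gn else record.id,
                sequence=str(record.seq),
                organism=organism_tag,
                is_contaminant=contaminant,
            )
        )
    return db


SDRF_COLUMNS = {
    "sample_id": "source name",
    "tissue": "characteristics[organism part]",
    "disease_status": "characteristics[disease]",
    "run_id": "comment[data file]",
    "dataset_id": "comment[dataset id]",
}


def read_sdrf(path: str | Path) -> pd.DataFrame:
    """Read SDRF-like metadata into one row per MS run.

    Enforces that each run file is listed under exactly one sample and that a
    sample carries exactly one tissue / dataset / disease status.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in raw.columns}
    missing = [col for col in SDRF_COLUMNS.values() if col not in lower]
    if missing:
        raise FormatError(f"SDRF missing required column(s) {missing}")
    meta = pd.DataFrame({k: raw[lower[v]] for k, v in SDRF_COLUMNS.items()})
    dup = meta["run_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"run file {meta['run_id'][dup.idxmax()]!r} listed under more than one row"
        )
    per_sample = meta.groupby("sample_id")[["tissue", "dataset_id", "disease_status"]].nunique()
    if (per_sample > 1).any().any():
        raise IntegrityError("a sample maps to more than one tissue/dataset/status")
    return meta


# ---------------------------------------------------------------------------
# evidence filters


def filter_contaminants(records: pd.DataFrame, db: ProteinSequenceDB) -> pd.DataFrame:
    """Remove every record whose protein group contains a contaminant accession."""
    crap = db.contaminant_accessions
    if not crap:
        return records.copy()
    hit = records["protein_group"].map(lambda g: any(a in crap for a in g))
    logger.info("contaminant filter removed %d/%d records", int(hit.sum()), len(records))
    return records.loc[~hit].reset_index(drop=True)


def filter_multimapped(records: pd.DataFrame) -> pd.DataFrame:
    """Remove records mapping to more than one protein or gene identifier."""
    multi = records["protein_group"].map(len).gt(1) | records["gene_group"].map(len).gt(1)
    logger.info("multi-mapping filter removed %d/%d records", int(multi.sum()), len(records))
    return records.loc[~multi].reset_index(drop=True)


def filter_min_unique_peptides(records: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Within each MS run, drop genes backed by fewer than ``min_peptides``
    distinct stripped peptide sequences.

    Scope is per run: a gene with one peptide in run A but three in run B is
    removed from A only.  Records must be single-gene (apply after
    :func:`filter_multimapped`).
    """
    if min_peptides < 1:
        raise InvalidParameterError("min_peptides must be >= 1")
    if records.empty:
        return records.copy()
    if records["gene_group"].map(len).gt(1).any():
        raise InvalidParameterError(
            "filter_min_unique_peptides requires single-gene records; "
            "apply filter_multimapped first"
        )
    gene = records["gene_group"].str[0]
    n_unique = records.groupby([records["run_id"], gene])["stripped_peptide"].transform("nunique")
    keep = n_unique >= min_peptides
    logger.info(
        "min-unique-peptides filter (>=%d) removed %d/%d records",
        min_peptides, int((~keep).sum()), len(records),
    )
    return records.loc[keep].reset_index(drop=True)


def select_samples(
    records: pd.DataFrame, metadata: pd.DataFrame, status: str = "normal"
) -> pd.DataFrame:
    """Keep records whose run belongs to a sample with the requested disease status."""
    run_status = metadata.set_index("run_id")["disease_status"]
    unknown = set(records["run_id"]) - set(run_status.index)
    if unknown:
        raise MappingError(f"runs absent from metadata: {sorted(unknown)[:5]}")
    keep = records["run_id"].map(run_status) == status
    logger.info(
        "sample-status filter (%s) removed %d/%d records",
        status, int((~keep).sum()), len(records),
    )
    return records.loc[keep].reset_index(drop=True)
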
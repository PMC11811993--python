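"""End-to-end orchestration: ingest -> filter -> quantify -> FDR -> compare.

Each dataset is processed individually (its own report file); cross-dataset
steps — entrapment FDR and the sample-level comparison analytics — run on
the collated results.  A machine-readable manifest records per-stage record
counts, parameter echoes and content hashes of every output, so identical
configuration and inputs yield an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import compare, fdr, ingest, quantify
from .digestion import DigestionRules, count_theoretical_peptides
from .errors import InvalidParameterError, PipelineStageError
from .quantify import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated run configuration (see ``from_yaml`` for the file schema)."""

    reports: dict[str, Path]
    target_fasta: Path
    sdrf: Path
    output_dir: Path
    entrapment_fasta: Path | None = None
    contaminant_fasta: Path | None = None
    dialect: dict[str, str] = field(default_factory=lambda: dict(ingest.DIANN_DIALECT))
    q_value_threshold: float = 0.01
    min_unique_peptides: int = 2
    disease_status: str = "normal"
    digestion: DigestionRules = field(default_factory=DigestionRules)
    n_bins: int = 5
    bin_scope: str = "column"
    dn_mode: str = "exact"
    seed: int = 0

    def validate(self) -> None:
        if not self.reports:
            raise InvalidParameterError("no report files configured")
        paths = [self.target_fasta, self.sdrf, *self.reports.values()]
        for p in (self.entrapment_fasta, self.contaminant_fasta):
            if p is not None:
                paths.append(p)
        for p in paths:
            if not Path(p).exists():
                raise InvalidParameterError(f"input path does not exist: {p}")
        if not 0 < self.q_value_threshold <= 1:
            raise InvalidParameterError("q_value_threshold must be in (0, 1]")
        if self.min_unique_peptides < 1:
            raise InvalidParameterError("min_unique_peptides must be >= 1")
        if self.n_bins < 2:
            raise InvalidParameterError("n_bins must be >= 2")
        if self.dn_mode not in ("exact", "rounded"):
            raise InvalidParameterError("dn_mode must be 'exact' or 'rounded'")
        if self.bin_scope not in ("column", "global"):
            raise InvalidParameterError("bin_scope must be 'column' or 'global'")

    @classmethod
    def from_dict(cls, cfg: dict, base: Path | None = None) -> "PipelineConfig":
        base = base or Path(".")

        def _p(x):
            return (base / x).resolve() if x else None

        inputs = cfg.get("inputs", {})
        filters = cfg.get("filters", {})
        dig = cfg.get("digestion", {})
        binning = cfg.get("binning", {})
        return cls(
            reports={k: _p(v) for k, v in inputs.get("reports", {}).items()},
            target_fasta=_p(inputs.get("target_fasta")),
            entrapment_fasta=_p(inputs.get("entrapment_fasta")),
            contaminant_fasta=_p(inputs.get("contaminant_fasta")),
            sdrf=_p(inputs.get("sdrf")),
            output_dir=Path(cfg.get("output_dir", "out")),
            dialect=cfg.get("dialect", dict(ingest.DIANN_DIALECT)),
            q_value_threshold=filters.get("q_value_threshold", 0.01),
            min_unique_peptides=filters.get("min_unique_peptides", 2),
            disease_status=filters.get("disease_status", "normal"),
            digestion=DigestionRules(
                min_length=dig.get("min_length", 7),
                max_length=dig.get("max_length", 30),
                missed_cleavages=dig.get("missed_cleavages", 0),
            ),
            n_bins=binning.get("n_bins", 5),
            bin_scope=binning.get("scope", "column"),
            dn_mode=cfg.get("fdr", {}).get("dn_mode", "exact"),
            seed=cfg.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg, base=path.parent)


@dataclass
class PipelineResult:
    manifest: dict
    sample_lfq: AbundanceMatrix
    sample_ibaq: AbundanceMatrix
    sample_binned: AbundanceMatrix
    fdr_table: pd.DataFrame | None
    histogram: pd.DataFrame | None
    missingness: compare.MissingnessResult
    correlations: compare.CorrelationMatrix
    coverage: compare.CoverageSummary


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str, context: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineStageError(name, context, exc) from exc


def _write_matrix(matrix: AbundanceMatrix, path: Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_atlas_export(matrix: AbundanceMatrix, path: Path) -> None:
    """Expression-Atlas-style export: gene x sample values plus SDRF-named
    sample annotation columns in a companion ``*.coldata.tsv`` file."""
    matrix.values.to_csv(path, sep="\t")
    coldata = matrix.column_meta.rename(
        columns={"tissue": "characteristics[organism part]",
                 "disease_status": "characteristics[disease]",
                 "dataset_id": "comment[dataset id]"}
    )
    coldata.index.name = "source name"
    coldata.to_csv(Path(str(path).replace(".tsv", "")).with_suffix(".coldata.tsv"), sep="\t")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all outputs plus ``manifest.json``.

    Stage failures abort with the stage name and the offending input in the
    error message.  Reruns of the same configuration on the same inputs
    produce byte-identical outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    target_db = _stage("read_fasta", str(config.target_fasta),
                       ingest.read_fasta, config.target_fasta, "target")
    db = target_db
    target_size = len(db)
    entrapment_genes: set[str] = set()
    entrapment_size = 0
    if config.entrapment_fasta:
        ent = _stage("read_fasta", str(config.entrapment_fasta),
                     ingest.read_fasta, config.entrapment_fasta, "entrapment")
        entrapment_genes = ent.genes
        entrapment_size = len(ent)
        db = db.merge(ent)
    if config.contaminant_fasta:
        con = _stage("read_fasta", str(config.contaminant_fasta),
                     ingest.read_fasta, config.contaminant_fasta,
                     "contaminant", contaminant=True)
        db = db.merge(con)

    metadata = _stage("read_sdrf", str(config.sdrf), ingest.read_sdrf, config.sdrf)

    dataset_counts: dict[str, dict] = {}
    filtered_frames = []
    for ds in sorted(config.reports):
        path = config.reports[ds]
        records = _stage("read_report", f"dataset {ds} ({path})",
                         ingest.read_report, path, ds, config.dialect,
                         config.q_value_threshold)
        counts = {"rows_read": len(records)}
        records = _stage("filter_contaminants", f"dataset {ds}",
                         ingest.filter_contaminants, records, db)
        counts["after_contaminants"] = len(records)
        records = _stage("filter_multimapped", f"dataset {ds}",
                         ingest.filter_multimapped, records)
        counts["after_multimapped"] = len(records)
        records = _stage("filter_min_unique_peptides", f"dataset {ds}",
                         ingest.filter_min_unique_peptides, records,
                         config.min_unique_peptides)
        counts["after_min_unique_peptides"] = len(records)
        records = _stage("select_samples", f"dataset {ds}",
                         ingest.select_samples, records, metadata,
                         config.disease_status)
        counts["after_sample_selection"] = len(records)
        counts["unique_peptides"] = int(records["stripped_peptide"].nunique())
        dataset_counts[ds] = counts
        filtered_frames.append(records)

    evidence = pd.concat(filtered_frames, ignore_index=True)

    # cross-dataset entrapment FDR on the filtered protein groups
    fdr_table = histogram = None
    dn = None
    if entrapment_genes:
        groups = fdr.extract_protein_groups(evidence)
        presence = _stage("classify_protein_groups", "all datasets",
                          fdr.classify_protein_groups, groups, entrapment_genes)
        dn = fdr.compute_dn(target_size, entrapment_size)
        if config.dn_mode == "rounded":
            dn = round(dn, 1)
        fdr_table = _stage("fdr_at_k", "all datasets", fdr.fdr_at_k, presence, dn)
        histogram = _stage("decoy_presence_histogram", "all datasets",
                           fdr.decoy_presence_histogram, presence)

    # abundance matrices on target genes only
    is_target = evidence["gene_group"].map(
        lambda g: all(gene not in entrapment_genes for gene in g)
    )
    target_evidence = evidence.loc[is_target].reset_index(drop=True)
    for ds in dataset_counts:
        n = int((target_evidence["dataset_id"] == ds).sum())
        dataset_counts[ds]["target_rows"] = n

    run_lfq = _stage("aggregate_run_abundance", "all datasets",
                     quantify.aggregate_run_abundance, target_evidence, metadata)
    sample_lfq = _stage("aggregate_sample_abundance", "all datasets",
                        quantify.aggregate_sample_abundance, run_lfq, metadata)
    pep_counts = _stage("count_theoretical_peptides", str(config.target_fasta),
                        count_theoretical_peptides, target_db, config.digestion)
    sample_ibaq = _stage("lfq_to_ibaq", "sample matrix",
                         quantify.lfq_to_ibaq, sample_lfq, pep_counts)
    sample_binned = _stage("bin_abundances", "sample matrix",
                           quantify.bin_abundances, sample_ibaq,
                           config.n_bins, config.bin_scope)

    missing = _stage("missingness_fm", "sample matrix",
                     compare.missingness_fm, sample_ibaq)
    corr = _stage("pairwise_binned_correlation", "sample matrix",
                  compare.pairwise_binned_correlation, sample_binned)
    coverage = _stage("coverage_summary", "sample matrix",
                      compare.coverage_summary, sample_ibaq)
    median_by_tissue = compare.median_group_correlation(corr, "tissue")
    median_by_tissue_dataset = compare.median_group_correlation(
        corr, ["tissue", "dataset_id"]
    )

    # ------------------------------------------------------------------ outputs
    outputs: dict[str, Path] = {}
    _write_matrix(sample_lfq, out / "sample_lfq.tsv")
    outputs["sample_lfq"] = out / "sample_lfq.tsv"
    write_atlas_export(sample_ibaq, out / "sample_ibaq.tsv")
    outputs["sample_ibaq"] = out / "sample_ibaq.tsv"
    outputs["sample_ibaq_coldata"] = out / "sample_ibaq.coldata.tsv"
    _write_matrix(sample_binned, out / "sample_binned.tsv")
    outputs["sample_binned"] = out / "sample_binned.tsv"
    missing.per_tissue.to_csv(out / "fm_per_tissue.tsv", sep="\t", index=False)
    outputs["fm_per_tissue"] = out / "fm_per_tissue.tsv"
    missing.per_dataset.to_csv(out / "fm_per_dataset.tsv", sep="\t", index=False)
    outputs["fm_per_dataset"] = out / "fm_per_dataset.tsv"
    corr.r2.to_csv(out / "correlation_r2.tsv", sep="\t")
    outputs["correlation_r2"] = out / "correlation_r2.tsv"
    corr.n_common.to_csv(out / "correlation_n_common.tsv", sep="\t")
    outputs["correlation_n_common"] = out / "correlation_n_common.tsv"
    median_by_tissue.to_csv(out / "median_r2_by_tissue.tsv", sep="\t")
    outputs["median_r2_by_tissue"] = out / "median_r2_by_tissue.tsv"
    median_by_tissue_dataset.to_csv(out / "median_r2_by_tissue_dataset.tsv", sep="\t")
    outputs["median_r2_by_tissue_dataset"] = out / "median_r2_by_tissue_dataset.tsv"
    coverage.per_tissue.to_csv(out / "coverage_per_tissue.tsv", sep="\t", index=False)
    outputs["coverage_per_tissue"] = out / "coverage_per_tissue.tsv"
    coverage.per_dataset.to_csv(out / "coverage_per_dataset.tsv", sep="\t", index=False)
    outputs["coverage_per_dataset"] = out / "coverage_per_dataset.tsv"
    if fdr_table is not None:
        fdr_table.to_csv(out / "fdr_table.tsv", sep="\t", index=False)
        outputs["fdr_table"] = out / "fdr_table.tsv"
        histogram.to_csv(out / "decoy_histogram.tsv", sep="\t", index=False)
        outputs["decoy_histogram"] = out / "decoy_histogram.tsv"

    meta_norm = metadata[metadata["disease_status"] == config.disease_status]
    manifest = {
        "parameters": {
            "q_value_threshold": config.q_value_threshold,
            "min_unique_peptides": config.min_unique_peptides,
            "disease_status": config.disease_status,
            "digestion": dataclasses.asdict(config.digestion) | {
                "cleave_after": sorted(config.digestion.cleave_after),
                "suppress_before": sorted(config.digestion.suppress_before),
            },
            "n_bins": config.n_bins,
            "bin_scope": config.bin_scope,
            "dn_mode": config.dn_mode,
            "dn": dn,
            "seed": config.seed,
        },
        "n_datasets": len(config.reports),
        "n_tissues": int(meta_norm["tissue"].nunique()),
        "n_runs": int(meta_norm["run_id"].nunique()),
        "n_samples": int(meta_norm["sample_id"].nunique()),
        "total_genes": coverage.total_genes,
        "datasets": dataset_counts,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        manifest=manifest,
        sample_lfq=sample_lfq,
        sample_ibaq=sample_ibaq,
        sample_binned=sample_binned,
        fdr_table=fdr_table,
        histogram=histogram,
        missingness=missing,
        correlations=corr,
        coverage=coverage,
    )


def quality_summary(result: PipelineResult, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset quality report: runs, samples, surviving rows, unique
    peptides and genes, and the dataset's median fraction of missingness."""
    meta = metadata
    fm = result.missingness.per_dataset.set_index("dataset_id")["fm_median"]
    present = result.sample_ibaq.values.notna()
    rows = []
    for ds, counts in sorted(result.manifest["datasets"].items()):
        ds_meta = meta[meta["dataset_id"] == ds]
        ds_samples = result.sample_ibaq.column_meta.query("dataset_id == @ds").index
        n_genes = int(present[list(ds_samples)].any(axis=1).sum()) if len(ds_samples) else 0
        rows.append(
            {
                "dataset_id": ds,
                "n_runs": int(ds_meta["run_id"].nunique()),
                "n_samples": int(ds_meta["sample_id"].nunique()),
                "rows_read": counts["rows_read"],
                "rows_surviving": counts["after_sample_selection"],
                "unique_peptides": counts["unique_peptides"],
                "unique_genes": n_genes,
                "fm_median": fm.get(ds, float("nan")),
            }
        )
    return pd.DataFrame(rows)
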
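"""Synthetic DIA study generator.

Emulates the structure of a multi-dataset, multi-tissue label-free DIA
reanalysis: a target "one protein sequence per gene" database, an
entrapment database from a foreign species, cRAP-style contaminants, an
SDRF-like sample table, and one DIA-NN-style precursor report per dataset.

The generator provides the ground truth every downstream stage is tested
against: true per-sample protein abundances with a tissue-shared "core"
gene fraction, per-peptide response factors, multiplicative log-normal
noise, abundance-dependent (logistic) dropout, and controlled injection of
contaminant rows, entrapment-only decoy protein groups, and multi-gene
protein groups.  All randomness flows from a single integer seed, so
identical parameters produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digestion import DigestionRules, digest_tryptic
from .errors import ConsistencyError, IntegrityError, InvalidParameterError
from .seqdb import DBEntry, ProteinSequenceDB

# residues that never create or block a tryptic cut site
_FILLER = [aa for aa in "ACDEFGHILMNPQSTVWY"]  # 18 residues, no K/R
_FILLER_NO_P = [aa for aa in _FILLER if aa != "P"]

#: Study design of the reanalysed public human tissue DIA datasets:
#: (dataset id, tissue, number of MS runs, number of healthy/normal samples).
#: Totals: 15 datasets, 12 tissues, 356 runs, 178 samples.
HUMAN_TISSUE_STUDY: tuple[tuple[str, str, int, int], ...] = (
    ("PXD031419", "brain", 75, 19),
    ("PXD012254", "colon", 19, 19),
    ("PXD001506", "duodenum", 6, 6),
    ("PXD001764", "esophagus", 3, 3),
    ("PXD019594", "heart", 10, 10),
    ("PXD025705", "liver", 33, 11),
    ("PXD004684", "lung", 8, 4),
    ("PXD032076", "pancreas", 25, 25),
    ("PXD025431", "skin", 10, 10),
    ("PXD002732", "thyroid", 8, 8),
    ("PXD022872", "brain", 71, 11),
    ("PXD033060", "brain", 17, 17),
    ("PXD018830", "breast epithelium", 4, 4),
    ("PXD039665", "skin", 13, 13),
    ("PXD034908", "skeletal muscle", 54, 18),
)

REPORT_COLUMNS = [
    "Run",
    "Protein.Group",
    "Genes",
    "Stripped.Sequence",
    "Precursor.Quantity",
    "Q.Value",
    "PG.Q.Value",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    Scales are log10: ``lfq_noise_sd = 0.25`` means a multiplicative noise
    factor with standard deviation 0.25 decades (~1.8-fold).  Dropout is
    logistic in log10 abundance: probability ``dropout_max`` far below
    ``dropout_midpoint_log10``, falling to 0 far above it.  Decoy protein
    groups are injected with odds ``decoy_row_rate / (1 - decoy_row_rate)``
    per emitted target group, so the expected entrapment-only fraction of
    emitted protein groups equals ``decoy_row_rate``.
    """

    n_target_genes: int = 300
    n_entrapment_genes: int = 600
    n_contaminants: int = 10
    n_datasets: int = 3
    tissues: tuple[str, ...] = ("brain", "liver", "colon")
    samples_per_tissue: int = 4
    runs_per_sample: int = 2
    mean_peptides_per_protein: float = 4.0
    base_log10_mean: float = 6.0
    base_log10_sd: float = 1.0
    tissue_effect_sd: float = 0.6
    lfq_noise_sd: float = 0.25
    peptide_factor_sd: float = 0.5
    core_gene_fraction: float = 0.15
    tissue_presence_prob: float = 0.5
    dropout_max: float = 0.6
    dropout_midpoint_log10: float = 4.5
    dropout_steepness: float = 1.5
    decoy_row_rate: float = 0.02
    multigene_group_rate: float = 0.02
    contaminant_row_rate: float = 0.3
    disease_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_target_genes", "n_entrapment_genes", "n_datasets",
                     "samples_per_tissue", "runs_per_sample"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if self.n_contaminants < 0:
            raise InvalidParameterError("n_contaminants must be >= 0")
        if not self.tissues:
            raise InvalidParameterError("at least one tissue is required")
        for name in ("core_gene_fraction", "tissue_presence_prob", "dropout_max",
                     "decoy_row_rate", "multigene_group_rate",
                     "contaminant_row_rate", "disease_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1]")
        if self.decoy_row_rate >= 1.0:
            raise InvalidParameterError("decoy_row_rate must be < 1")
        for name in ("lfq_noise_sd", "peptide_factor_sd", "tissue_effect_sd",
                     "base_log10_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.mean_peptides_per_protein < 1:
            raise InvalidParameterError("mean_peptides_per_protein must be >= 1")


@dataclass
class GroundTruth:
    """True abundance structure behind a simulated study.

    ``true_abundance`` is genes x samples with NaN where the gene is not part
    of the sample's tissue profile; present values are strictly positive.
    """

    true_abundance: pd.DataFrame
    tissue_of_sample: pd.Series
    dataset_of_sample: pd.Series
    tissue_presence: pd.DataFrame  # genes x tissues, bool
    core_genes: frozenset
    decoy_genes: frozenset = frozenset()
    contaminant_accessions: frozenset = frozenset()

    def __post_init__(self):
        vals = self.true_abundance.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ConsistencyError("true abundances must be strictly positive where present")
        samples = list(self.true_abundance.columns)
        if set(samples) != set(self.tissue_of_sample.index) or set(samples) != set(
            self.dataset_of_sample.index
        ):
            raise ConsistencyError("every sample needs exactly one tissue and one dataset")
        if self.decoy_genes & set(self.true_abundance.index):
            raise ConsistencyError("decoy genes must be disjoint from target genes")


@dataclass
class InjectionLog:
    """Bookkeeping of everything the generator injected, per dataset."""

    contaminant_rows: dict = field(default_factory=dict)
    multigene_rows: dict = field(default_factory=dict)
    decoy_groups: dict = field(default_factory=dict)       # dataset -> set of genes
    decoy_group_events: dict = field(default_factory=dict)  # dataset -> emission count
    target_group_emissions: dict = field(default_factory=dict)
    truth_cells: dict = field(default_factory=dict)         # (gene,run) cells offered
    dropped_cells: dict = field(default_factory=dict)       # cells lost to dropout


@dataclass
class SimulatedStudy:
    reports: dict  # dataset id -> DataFrame with REPORT_COLUMNS
    injections: InjectionLog


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def generate_sequence_db(
    n_genes: int,
    organism_tag: str,
    seed: int,
    *,
    contaminant: bool = False,
    accession_prefix: str | None = None,
) -> ProteinSequenceDB:
    """Generate ``n_genes`` random canonical protein sequences.

    Sequences are concatenations of 3-12 tryptic segments: each segment is
    6-29 non-cleaving residues (never starting with P, so the preceding K/R
    site always cuts) terminated by K or R.  Every sequence therefore digests
    to at least one — in practice several — peptides of length 7-30 under
    default trypsin rules.
    """
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    rng = np.random.default_rng([seed, zlib.crc32(organism_tag.encode()) % (2**31)])
    prefix = accession_prefix or organism_tag[:3].upper()
    db = ProteinSequenceDB()
    for i in range(n_genes):
        n_seg = int(rng.integers(3, 13))
        parts = []
        for _ in range(n_seg):
            length = int(rng.integers(6, 30))
            body = [str(rng.choice(_FILLER_NO_P))]
            body += list(rng.choice(_FILLER, size=length - 1))
            body.append(str(rng.choice(["K", "R"])))
            parts.append("".join(body))
        acc = f"{prefix}{i:05d}"
        db.add(
            DBEntry(
                accession=acc,
                gene=f"{prefix}_G{i:05d}",
                sequence="".join(parts),
                organism=organism_tag,
                is_contaminant=contaminant,
            )
        )
    return db


def generate_study_design(params: SimulationParams) -> pd.DataFrame:
    """Factorial study design: one row per MS run.

    Every dataset contains every tissue with ``samples_per_tissue`` samples of
    ``runs_per_sample`` runs each, so total runs = n_datasets x n_tissues x
    samples_per_tissue x runs_per_sample.  A ``disease_fraction`` of samples
    is flagged "disease"; the rest are "normal".
    """
    rng = _rng(params.seed, 1)
    rows = []
    for d in range(params.n_datasets):
        dataset = f"DS{d + 1:02d}"
        for tissue in params.tissues:
            for s in range(params.samples_per_tissue):
                sample = f"{dataset}_{tissue.replace(' ', '')}_s{s + 1:02d}"
                status = "disease" if rng.random() < params.disease_fraction else "normal"
                for r in range(params.runs_per_sample):
                    rows.append(
                        {
                            "run_id": f"{sample}_r{r + 1:02d}",
                            "sample_id": sample,
                            "dataset_id": dataset,
                            "tissue": tissue,
                            "disease_status": status,
                        }
                    )
    return pd.DataFrame(rows)


def design_from_counts(
    table: tuple[tuple[str, str, int, int], ...] = HUMAN_TISSUE_STUDY,
) -> pd.DataFrame:
    """Study design from explicit per-dataset (tissue, runs, samples) counts.

    Runs are distributed across samples as evenly as possible (earlier
    samples receive the remainder).  The default table reproduces the
     15-dataset / 12-tissue / 356-run / 178-sample human tissue study design.
    """
    rows = []
    for dataset, tissue, n_runs, n_samples in table:
        if n_samples < 1 or n_runs < n_samples:
            raise InvalidParameterError(
                f"{dataset}: need n_runs >= n_samples >= 1, got {n_runs}/{n_samples}"
            )
        base, extra = divmod(n_runs, n_samples)
        for s in range(n_samples):
            sample = f"{dataset}_{tissue.replace(' ', '')}_s{s + 1:03d}"
            for r in range(base + (1 if s < extra else 0)):
                rows.append(
                    {
                        "run_id": f"{sample}_r{r + 1:02d}",
                        "sample_id": sample,
                        "dataset_id": dataset,
                        "tissue": tissue,
                        "disease_status": "normal",
                    }
                )
    return pd.DataFrame(rows)


def simulate_true_abundances(
    db: ProteinSequenceDB, design: pd.DataFrame, params: SimulationParams
) -> GroundTruth:
    """Draw the true gene x sample abundance matrix behind a study.

    Each gene gets a base log10 abundance; a ``core_gene_fraction`` of genes
    is expressed in every tissue, the rest in a random subset (at least one).
    Tissue profiles add a per-(gene, tissue) effect of sd
    ``tissue_effect_sd``; samples scatter around their tissue profile with sd
    ``lfq_noise_sd``.  With zero noise all samples of a tissue are identical.
    """
    if len(db) == 0:
        raise InvalidParameterError("empty sequence database")
    if design.empty:
        raise InvalidParameterError("empty study design")
    rng = _rng(params.seed, 2)
    genes = sorted(e.gene for e in db if not e.is_contaminant)
    tissues = sorted(design["tissue"].unique())
    g, t = len(genes), len(tissues)

    base = rng.normal(params.base_log10_mean, params.base_log10_sd, size=g)
    core = rng.random(g) < params.core_gene_fraction
    presence = np.ones((g, t), dtype=bool)
    restricted = ~core
    presence[restricted] = rng.random((restricted.sum(), t)) < params.tissue_presence_prob
    # every gene is expressed somewhere
    orphan = ~presence.any(axis=1)
    if orphan.any():
        forced = rng.integers(0, t, size=int(orphan.sum()))
        presence[np.flatnonzero(orphan), forced] = True

    tissue_log10 = base[:, None] + rng.normal(0.0, params.tissue_effect_sd, size=(g, t))
    tissue_log10[~presence] = np.nan

    samples = design.drop_duplicates("sample_id")
    sample_ids = samples["sample_id"].tolist()
    tissue_idx = {tt: i for i, tt in enumerate(tissues)}
    cols = {}
    for _, row in samples.iterrows():
        ti = tissue_idx[row["tissue"]]
        noise = rng.normal(0.0, params.lfq_noise_sd, size=g) if params.lfq_noise_sd > 0 else 0.0
        cols[row["sample_id"]] = 10.0 ** (tissue_log10[:, ti] + noise)
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return GroundTruth(
        true_abundance=matrix,
        tissue_of_sample=samples.set_index("sample_id")["tissue"],
        dataset_of_sample=samples.set_index("sample_id")["dataset_id"],
        tissue_presence=pd.DataFrame(presence, index=matrix.index, columns=tissues),
        core_genes=frozenset(np.array(genes)[core]),
    )


def dropout_probability(abundance: np.ndarray | float, params: SimulationParams) -> np.ndarray:
    """Logistic missingness model: low-abundance proteins drop out more often."""
    x = np.log10(np.asarray(abundance, dtype=float))
    return params.dropout_max / (
        1.0 + np.exp(params.dropout_steepness * (x - params.dropout_midpoint_log10))
    )


def simulate_report(
    truth: GroundTruth,
    design: pd.DataFrame,
    target_db: ProteinSequenceDB,
    params: SimulationParams,
    entrapment_db: ProteinSequenceDB | None = None,
    contaminant_db: ProteinSequenceDB | None = None,
    rules: DigestionRules = DigestionRules(),
) -> SimulatedStudy:
    """Emit one DIA-NN-style precursor report per dataset.

    Per run and detected gene, one row per observed peptide is written with
    quantity = true abundance x peptide response factor x log-normal noise.
    Entrapment-only decoy groups, contaminant rows and two-gene protein
    groups are injected at their configured rates, and abundance-dependent
    dropout removes whole (gene, run) observations.  Q-values are uniform in
    [0, 0.01], i.e. everything passes a 1% run-level filter.
    """
    gene_entry = {e.gene: e for e in target_db if not e.is_contaminant}
    missing = set(truth.true_abundance.index) - set(gene_entry)
    if missing:
        raise ConsistencyError(f"{len(missing)} truth genes absent from the target database")

    digests = {g: digest_tryptic(gene_entry[g].sequence, rules) for g in truth.true_abundance.index}
    genes = list(truth.true_abundance.index)
    rng = _rng(params.seed, 3)
    factors = {
        g: (
            10.0 ** rng.normal(0.0, params.peptide_factor_sd, size=len(digests[g]))
            if params.peptide_factor_sd > 0
            else np.ones(len(digests[g]))
        )
        for g in genes
    }

    ent_entries = sorted(entrapment_db, key=lambda e: e.accession) if entrapment_db else []
    ent_digests = {e.gene: digest_tryptic(e.sequence, rules) for e in ent_entries}
    con_entries = sorted(contaminant_db, key=lambda e: e.accession) if contaminant_db else []

    decoy_odds = (
        params.decoy_row_rate / (1.0 - params.decoy_row_rate) if ent_entries else 0.0
    )
    log = InjectionLog()
    reports: dict[str, list[dict]] = {}
    abund = truth.true_abundance

    for _, run_row in design.iterrows():
        run, sample, dataset = run_row["run_id"], run_row["sample_id"], run_row["dataset_id"]
        rows = reports.setdefault(dataset, [])
        for key in ("contaminant_rows", "multigene_rows", "decoy_group_events",
                    "target_group_emissions", "truth_cells", "dropped_cells"):
            getattr(log, key).setdefault(dataset, 0)
        log.decoy_groups.setdefault(dataset, set())

        col = abund[sample]
        for gi, gene in enumerate(genes):
            a = col.iloc[gi]
            if math.isnan(a):
                continue
            log.truth_cells[dataset] += 1
            if params.dropout_max > 0 and rng.random() < float(dropout_probability(a, params)):
                log.dropped_cells[dataset] += 1
                continue
            dig = digests[gene]
            n_obs = min(len(dig), 1 + int(rng.poisson(params.mean_peptides_per_protein - 1.0)))
            picked = sorted(rng.choice(len(dig), size=n_obs, replace=False))
            entry = gene_entry[gene]
            prot_group, gene_group = entry.accession, gene
            if params.multigene_group_rate > 0 and rng.random() < params.multigene_group_rate:
                partner = genes[int(rng.integers(0, len(genes)))]
                if partner != gene:
                    pe = gene_entry[partner]
                    prot_group = ";".join(sorted([entry.accession, pe.accession]))
                    gene_group = ";".join(sorted([gene, partner]))
                    log.multigene_rows[dataset] += n_obs
            for j in picked:
                noise = (
                    10.0 ** rng.normal(0.0, params.lfq_noise_sd)
                    if params.lfq_noise_sd > 0
                    else 1.0
                )
                rows.append(
                    {
                        "Run": run,
                        "Protein.Group": prot_group,
                        "Genes": gene_group,
                        "Stripped.Sequence": dig[j],
                        "Precursor.Quantity": a * factors[gene][j] * noise,
                        "Q.Value": rng.uniform(0.0, 0.01),
                        "PG.Q.Value": rng.uniform(0.0, 0.01),
                    }
                )
            log.target_group_emissions[dataset] += 1
            # decoy protein groups ride alongside real emissions so their
            # expected share of emitted groups equals decoy_row_rate
            if decoy_odds > 0 and rng.random() < decoy_odds:
                de = ent_entries[int(rng.integers(0, len(ent_entries)))]
                ddig = ent_digests[de.gene]
                n_dec = min(len(ddig), max(2, 1 + int(rng.poisson(1.5))))
                d_a = 10.0 ** rng.normal(params.base_log10_mean - 1.5, 0.8)
                for j in sorted(rng.choice(len(ddig), size=n_dec, replace=False)):
                    rows.append(
                        {
                            "Run": run,
                            "Protein.Group": de.accession,
                            "Genes": de.gene,
                            "Stripped.Sequence": ddig[j],
                            "Precursor.Quantity": d_a * 10.0 ** rng.normal(0.0, 0.3),
                            "Q.Value": rng.uniform(0.0, 0.01),
                            "PG.Q.Value": rng.uniform(0.0, 0.01),
                        }
                    )
                log.decoy_group_events[dataset] += 1
                log.decoy_groups[dataset].add(de.gene)
        for ce in con_entries:
            if rng.random() < params.contaminant_row_rate:
                cdig = digest_tryptic(ce.sequence, rules)
                n_c = min(len(cdig), 1 + int(rng.poisson(1.0)))
                c_a = 10.0 ** rng.normal(params.base_log10_mean, 1.0)
                for j in sorted(rng.choice(len(cdig), size=n_c, replace=False)):
                    rows.append(
                        {
                            "Run": run,
                            "Protein.Group": ce.accession,
                            "Genes": ce.gene,
                            "Stripped.Sequence": cdig[j],
                            "Precursor.Quantity": c_a * 10.0 ** rng.normal(0.0, 0.3),
                            "Q.Value": rng.uniform(0.0, 0.01),
                            "PG.Q.Value": rng.uniform(0.0, 0.01),
                        }
                    )
                    log.contaminant_rows[dataset] += 1

    report_frames = {
        ds: pd.DataFrame(rows, columns=REPORT_COLUMNS) for ds, rows in sorted(reports.items())
    }
    return SimulatedStudy(reports=report_frames, injections=log)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write a report as tab-separated text (floats via repr: lossless round-trip)."""
    report.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def write_sdrf(design: pd.DataFrame, path: str | Path) -> None:
    """Write an SDRF-like sample table, one row per raw data file."""
    out = pd.DataFrame(
        {
            "source name": design["sample_id"],
            "characteristics[organism part]": design["tissue"],
            "characteristics[disease]": design["disease_status"],
            "comment[data file]": design["run_id"],
            "comment[dataset id]": design["dataset_id"],
        }
    )
    if out["comment[data file]"].duplicated().any():
        raise IntegrityError("duplicate run identifiers in design")
    out.to_csv(path, sep="\t", index=False)


@dataclass
class StudyPaths:
    """File layout of a written synthetic study."""

    directory: Path
    target_fasta: Path
    entrapment_fasta: Path | None
    contaminant_fasta: Path | None
    sdrf: Path
    reports: dict
    study: SimulatedStudy
    truth: GroundTruth
    design: pd.DataFrame
    target_db: ProteinSequenceDB
    entrapment_db: ProteinSequenceDB | None
    contaminant_db: ProteinSequenceDB | None


def generate_study(
    params: SimulationParams,
    out_dir: str | Path,
    design: pd.DataFrame | None = None,
) -> StudyPaths:
    """End-to-end generation: databases, design, truth, reports — written to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = generate_sequence_db(params.n_target_genes, "human", params.seed)
    entrap = generate_sequence_db(params.n_entrapment_genes, "arabidopsis", params.seed + 1)
    contam = (
        generate_sequence_db(
            params.n_contaminants, "contaminant", params.seed + 2, contaminant=True
        )
        if params.n_contaminants
        else None
    )
    if design is None:
        design = generate_study_design(params)
    truth = simulate_true_abundances(target, design, params)
    study = simulate_report(truth, design, target, params, entrap, contam)

    target_fa = out / "target.fasta"
    target.to_fasta(target_fa)
    entrap_fa = out / "entrapment.fasta"
    entrap.to_fasta(entrap_fa)
    contam_fa = None
    if contam is not None:
        contam_fa = out / "contaminants.fasta"
        contam.to_fasta(contam_fa)
    sdrf = out / "sdrf.tsv"
    write_sdrf(design, sdrf)
    report_paths = {}
    for ds, rep in study.reports.items():
        p = out / f"report_{ds}.tsv"
        write_report(rep, p)
        report_paths[ds] = p
    return StudyPaths(
        directory=out,
        target_fasta=target_fa,
        entrapment_fasta=entrap_fa,
        contaminant_fasta=contam_fa,
        sdrf=sdrf,
        reports=report_paths,
        study=study,
        truth=truth,
        design=design,
        target_db=target,
        entrapment_db=entrap,
        contaminant_db=contam,
    )


def params_to_dict(params: SimulationParams) -> dict:
    d = dataclasses.asdict(params)
    d["tissues"] = list(params.tissues)
    return d
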
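import pandas as pd
import pytest

from diaquant import ingest
from diaquant import simulate as sim


@pytest.fixture(scope="session")
def params():
    """Default-condition study: 3 datasets x 3 tissues x 4 samples x 2 runs."""
    return sim.SimulationParams(seed=123)


@pytest.fixture(scope="session")
def study(params, tmp_path_factory):
    return sim.generate_study(params, tmp_path_factory.mktemp("study"))


@pytest.fixture(scope="session")
def metadata(study):
    return ingest.read_sdrf(study.sdrf)


@pytest.fixture(scope="session")
def full_db(study):
    db = ingest.read_fasta(study.target_fasta, "human")
    db = db.merge(ingest.read_fasta(study.entrapment_fasta, "arabidopsis"))
    return db.merge(
        ingest.read_fasta(study.contaminant_fasta, "contaminant", contaminant=True)
    )


@pytest.fixture(scope="session")
def raw_records(study):
    """All report rows of the study, parsed but unfiltered."""
    frames = [
        ingest.read_report(path, ds) for ds, path in sorted(study.reports.items())
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def evidence(raw_records, full_db, metadata):
    """Fully filtered evidence: contaminants -> multimapped -> >=2 peptides -> normal samples."""
    rec = ingest.filter_contaminants(raw_records, full_db)
    rec = ingest.filter_multimapped(rec)
    rec = ingest.filter_min_unique_peptides(rec, 2)
    return ingest.select_samples(rec, metadata, "normal")


@pytest.fixture(scope="session")
def pipeline_result(study):
    """Full pipeline run on the default-condition study."""
    from diaquant import pipeline

    cfg = pipeline.PipelineConfig(
        reports=study.reports,
        target_fasta=study.target_fasta,
        entrapment_fasta=study.entrapment_fasta,
        contaminant_fasta=study.contaminant_fasta,
        sdrf=study.sdrf,
        output_dir=study.directory / "out",
    )
    return pipeline.run_pipeline(cfg)


@pytest.fixture(scope="session")
def zero_noise_study(tmp_path_factory):
    """Noise-free, dropout-free, injection-free study for exact recovery checks."""
    p = sim.SimulationParams(
        seed=7,
        n_target_genes=120,
        n_entrapment_genes=50,
        n_contaminants=0,
        n_datasets=2,
        tissues=("brain", "liver"),
        samples_per_tissue=3,
        runs_per_sample=2,
        lfq_noise_sd=0.0,
        peptide_factor_sd=0.0,
        dropout_max=0.0,
        decoy_row_rate=0.0,
        multigene_group_rate=0.0,
    )
    return sim.generate_study(p, tmp_path_factory.mktemp("zero_noise"))
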
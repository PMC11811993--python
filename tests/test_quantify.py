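"""Median aggregation, iBAQ conversion and ranked binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from diaquant import ingest, quantify
from diaquant.digestion import PeptideCounts, count_theoretical_peptides
from diaquant.errors import BinningError, ConsistencyError, InvalidParameterError
from diaquant.quantify import AbundanceMatrix

from .helpers import sort_slice_bins


def _meta(runs, sample=None):
    return pd.DataFrame(
        {
            "run_id": runs,
            "sample_id": sample or runs,
            "dataset_id": "DS",
            "tissue": "brain",
            "disease_status": "normal",
        }
    )


def _records(rows):
    return pd.DataFrame(
        {
            "run_id": [r[0] for r in rows],
            "dataset_id": "DS",
            "protein_group": [("P",)] * len(rows),
            "gene_group": [(r[1],) for r in rows],
            "stripped_peptide": [r[2] for r in rows],
            "quantity": [float(r[3]) for r in rows],
            "q_value": 0.001,
        }
    )


def _matrix(values, stage="ibaq", tissue=None, dataset=None):
    meta = pd.DataFrame(
        {
            "tissue": tissue or ["brain"] * values.shape[1],
            "dataset_id": dataset or ["DS"] * values.shape[1],
            "disease_status": "normal",
        },
        index=values.columns,
    )
    return AbundanceMatrix(values=values, stage=stage, column_meta=meta)


class TestRunAggregation:
    def test_odd_median(self):
        rec = _records([("r1", "G1", f"P{i}AAAAAK", q) for i, q in enumerate([1, 2, 3])])
        m = quantify.aggregate_run_abundance(rec, _meta(["r1"]))
        assert m.values.loc["G1", "r1"] == 2

    def test_even_median_is_mean_of_middle_two(self):
        rec = _records([("r1", "G1", "AAAAAAAK", 1), ("r1", "G1", "CCCCCCCK", 3)])
        m = quantify.aggregate_run_abundance(rec, _meta(["r1"]))
        assert m.values.loc["G1", "r1"] == 2

    def test_absent_pairs_are_missing_cells(self):
        rec = _records([("r1", "G1", "AAAAAAAK", 1), ("r2", "G2", "CCCCCCCK", 3)])
        m = quantify.aggregate_run_abundance(rec, _meta(["r1", "r2"]))
        assert np.isnan(m.values.loc["G2", "r1"]) and np.isnan(m.values.loc["G1", "r2"])

    def test_zero_noise_run_medians_recover_truth(self, zero_noise_study):
        st_ = zero_noise_study
        meta = ingest.read_sdrf(st_.sdrf)
        rec = pd.concat(
            [ingest.read_report(p, ds) for ds, p in sorted(st_.reports.items())],
            ignore_index=True,
        )
        m = quantify.aggregate_run_abundance(rec, meta)
        run_sample = meta.set_index("run_id")["sample_id"]
        for run in m.values.columns:
            truth_col = st_.truth.true_abundance[run_sample[run]]
            got = m.values[run].dropna()
            np.testing.assert_allclose(got.to_numpy(), truth_col[got.index].to_numpy(),
                                       rtol=1e-9)


class TestSampleAggregation:
    def test_single_run_per_sample_is_relabeling(self):
        rec = _records([("r1", "G1", "AAAAAAAK", 5)])
        meta = _meta(["r1"], sample=["s1"])
        run_m = quantify.aggregate_run_abundance(rec, meta)
        sample_m = quantify.aggregate_sample_abundance(run_m, meta)
        assert sample_m.values.loc["G1", "s1"] == 5

    def test_missing_runs_ignored_in_median(self):
        values = pd.DataFrame(
            {"r1": [2.0], "r2": [np.nan], "r3": [4.0]}, index=["G1"]
        )
        meta = _meta(["r1", "r2", "r3"], sample=["s1", "s1", "s1"])
        run_m = AbundanceMatrix(
            values=values, stage="lfq",
            column_meta=meta.set_index("run_id")[["sample_id", "tissue", "dataset_id"]],
        )
        out = quantify.aggregate_sample_abundance(run_m, meta)
        assert out.values.loc["G1", "s1"] == 3.0


class TestIbaq:
    def test_definition(self):
        m = _matrix(pd.DataFrame({"s1": [10.0]}, index=["G1"]), stage="lfq")
        counts = PeptideCounts(counts=pd.Series({"G1": 2}))
        assert quantify.lfq_to_ibaq(m, counts).values.loc["G1", "s1"] == 5.0

    def test_count_one_is_identity(self):
        vals = pd.DataFrame({"s1": [3.0, 7.0]}, index=["G1", "G2"])
        m = _matrix(vals, stage="lfq")
        counts = PeptideCounts(counts=pd.Series({"G1": 1, "G2": 1}))
        pd.testing.assert_frame_equal(quantify.lfq_to_ibaq(m, counts).values, vals)

    def test_missing_gene_count_is_consistency_error(self):
        m = _matrix(pd.DataFrame({"s1": [1.0]}, index=["G1"]), stage="lfq")
        with pytest.raises(ConsistencyError):
            quantify.lfq_to_ibaq(m, PeptideCounts(counts=pd.Series({"other": 1})))

    def test_zero_count_genes_dropped(self):
        vals = pd.DataFrame({"s1": [1.0, 2.0]}, index=["G1", "G0"])
        m = _matrix(vals, stage="lfq")
        counts = PeptideCounts(
            counts=pd.Series({"G1": 2, "G0": 0}), zero_count_genes=frozenset({"G0"})
        )
        out = quantify.lfq_to_ibaq(m, counts)
        assert list(out.values.index) == ["G1"]

    def test_ranking_matches_independent_recomputation(self, study, evidence, metadata):
        """Column-wise gene ranking by iBAQ equals ranking by LFQ/count."""
        target_genes = {e.gene for e in study.target_db}
        rec = evidence[evidence["gene_group"].str[0].isin(target_genes)]
        run_m = quantify.aggregate_run_abundance(rec, metadata)
        sample_m = quantify.aggregate_sample_abundance(run_m, metadata)
        counts = count_theoretical_peptides(study.target_db)
        ibaq = quantify.lfq_to_ibaq(sample_m, counts)
        for col in ibaq.values.columns[:5]:
            manual = (sample_m.values[col] / counts.counts).dropna()
            got = ibaq.values[col].dropna()
            assert got.rank().equals(manual[got.index].rank())


class TestBinning:
    def test_ten_sorted_values_into_five_equal_bins(self):
        vals = pd.DataFrame({"s1": np.arange(1.0, 11.0)})
        out = quantify.bin_abundances(_matrix(vals), 5)
        assert out.values["s1"].tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_equal_values_still_partition_evenly(self):
        vals = pd.DataFrame({"s1": np.ones(10)})
        out = quantify.bin_abundances(_matrix(vals), 5)
        assert out.values["s1"].tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_fewer_values_than_bins_is_column_error(self):
        vals = pd.DataFrame({"s1": [1.0, 2.0, np.nan, np.nan, np.nan]})
        with pytest.raises(BinningError, match="s1"):
            quantify.bin_abundances(_matrix(vals), 5)

    def test_already_binned_rejected(self):
        vals = pd.DataFrame({"s1": [1.0] * 5})
        binned = quantify.bin_abundances(_matrix(vals), 5)
        with pytest.raises(InvalidParameterError):
            quantify.bin_abundances(binned, 5)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        values=st.lists(
            st.one_of(st.floats(0.1, 1e9), st.none()), min_size=5, max_size=60
        ),
        n_bins=st.integers(2, 5),
    )
    def test_binning_matches_sort_slice_oracle(self, values, n_bins):
        arr = np.array([np.nan if v is None else v for v in values])
        if int((~np.isnan(arr)).sum()) < n_bins:
            return
        vals = pd.DataFrame({"s1": arr})
        out = quantify.bin_abundances(_matrix(vals), n_bins).values["s1"].to_numpy()
        np.testing.assert_array_equal(out, sort_slice_bins(arr, n_bins))

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame({"s1": rng.lognormal(size=40)})
        a = quantify.bin_abundances(_matrix(vals), 5).values
        b = quantify.bin_abundances(_matrix(vals * 17.3), 5).values
        pd.testing.assert_frame_equal(a, b)

    def test_monotone_and_balanced_within_columns(self, study, evidence, metadata):
        target_genes = {e.gene for e in study.target_db}
        rec = evidence[evidence["gene_group"].str[0].isin(target_genes)]
        run_m = quantify.aggregate_run_abundance(rec, metadata)
        sample_m = quantify.aggregate_sample_abundance(run_m, metadata)
        ibaq = quantify.lfq_to_ibaq(sample_m, count_theoretical_peptides(study.target_db))
        binned = quantify.bin_abundances(ibaq, 5)
        for col in binned.values.columns:
            x = ibaq.values[col].dropna()
            b = binned.values[col].dropna()
            assert set(b.index) == set(x.index)
            order = x.sort_values(kind="stable").index
            assert b[order].is_monotonic_increasing
            sizes = b.value_counts()
            assert sizes.max() - sizes.min() <= 1


class TestParameterRecovery:
    def test_zero_noise_rank_match_for_equal_peptide_counts(self, zero_noise_study):
        st_ = zero_noise_study
        meta = ingest.read_sdrf(st_.sdrf)
        rec = pd.concat(
            [ingest.read_report(p, ds) for ds, p in sorted(st_.reports.items())],
            ignore_index=True,
        )
        rec = ingest.filter_min_unique_peptides(ingest.filter_multimapped(rec), 2)
        run_m = quantify.aggregate_run_abundance(rec, meta)
        sample_m = quantify.aggregate_sample_abundance(run_m, meta)
        counts = count_theoretical_peptides(st_.target_db)
        ibaq = quantify.lfq_to_ibaq(sample_m, counts)
        for sample in ibaq.values.columns:
            got = ibaq.values[sample].dropna()
            truth = st_.truth.true_abundance[sample]
            for _, genes in counts.counts.loc[got.index].groupby(counts.counts):
                if len(genes) < 2:
                    continue
                idx = genes.index
                assert got[idx].rank().equals(truth[idx].rank())

    def test_default_noise_spearman_at_least_090_per_sample(
        self, study, evidence, metadata
    ):
        target_genes = {e.gene for e in study.target_db}
        rec = evidence[evidence["gene_group"].str[0].isin(target_genes)]
        run_m = quantify.aggregate_run_abundance(rec, metadata)
        sample_m = quantify.aggregate_sample_abundance(run_m, metadata)
        ibaq = quantify.lfq_to_ibaq(sample_m, count_theoretical_peptides(study.target_db))
        for sample in ibaq.values.columns:
            got = ibaq.values[sample].dropna()
            truth = study.truth.true_abundance.loc[got.index, sample]
            rho = stats.spearmanr(got, truth).statistic
            assert rho >= 0.9, (sample, rho)
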
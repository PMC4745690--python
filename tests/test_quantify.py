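"""Naive FPKM, expression aggregation across levels, and quality filters."""

import numpy as np
import pandas as pd
import pytest

import trilayer as tl


def _one_region_model(length_bp):
    model = tl.AnnotationModel(
        genes={"G": tl.Gene("G", "chr1")},
        transcripts={"T": tl.Transcript("T", "G", ((1, length_bp),))},
    )
    return tl.flatten_exonic_regions(model)


class TestNaiveFpkm:
    @pytest.mark.parametrize(
        "count,total,length,expected",
        [
            (100, 1_000_000, 1000, 100.0),  # units cancel exactly
            (0, 1_000_000, 1000, 0.0),
            (250, 5_000_000, 500, 100.0),
        ],
    )
    def test_formula(self, count, total, length, expected):
        annot = _one_region_model(length)
        rid = next(iter(annot.exonic_regions))
        cm = tl.CountMatrix(
            "exonic_region", pd.DataFrame({"s1": [count]}, index=[rid])
        )
        fpkm = tl.compute_naive_fpkm(cm, annot, {"s1": total})
        assert fpkm.data.loc[rid, "s1"] == pytest.approx(expected)

    def test_region_absent_from_annotation_rejected(self):
        annot = _one_region_model(1000)
        cm = tl.CountMatrix("exonic_region", pd.DataFrame({"s1": [5]}, index=["nope:1"]))
        with pytest.raises(ValueError, match="absent"):
            tl.compute_naive_fpkm(cm, annot, {"s1": 1e6})

    def test_zero_total_reads_rejected(self):
        annot = _one_region_model(1000)
        rid = next(iter(annot.exonic_regions))
        cm = tl.CountMatrix("exonic_region", pd.DataFrame({"s1": [5]}, index=[rid]))
        with pytest.raises(ValueError, match="positive"):
            tl.compute_naive_fpkm(cm, annot, {"s1": 0.0})

    def test_pseudo_count_inverse_recovers_integers_exactly(self):
        rng = np.random.default_rng(3)
        annot = _one_region_model(777)
        rid = next(iter(annot.exonic_regions))
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(1, 6)), index=[rid],
            columns=[f"s{i}" for i in range(6)],
        )
        totals = {f"s{i}": float(t) for i, t in enumerate(rng.integers(1e6, 5e7, size=6))}
        cm = tl.CountMatrix("exonic_region", counts)
        fpkm = tl.compute_naive_fpkm(cm, annot, totals)
        back = tl.pseudo_counts_from_fpkm(fpkm, annot, totals)
        pd.testing.assert_frame_equal(back.data, cm.data)

    def test_scales_inversely_with_totals_and_length(self):
        rng = np.random.default_rng(4)
        count = int(rng.integers(1, 1000))
        annot1, annot2 = _one_region_model(500), _one_region_model(1000)
        rid1, rid2 = next(iter(annot1.exonic_regions)), next(iter(annot2.exonic_regions))
        f = lambda annot, rid, total: tl.compute_naive_fpkm(
            tl.CountMatrix("exonic_region", pd.DataFrame({"s": [count]}, index=[rid])),
            annot, {"s": total},
        ).data.iloc[0, 0]
        assert f(annot1, rid1, 2e6) == pytest.approx(f(annot1, rid1, 1e6) / 2)
        assert f(annot2, rid2, 1e6) == pytest.approx(f(annot1, rid1, 1e6) / 2)


@pytest.fixture
def two_tx_annot(overlap_model):
    return overlap_model  # T1 100-300, T2 200-400, shared region 200-300


class TestAggregation:
    def test_gene_fpkm_is_sum_of_transcript_fpkm(self, two_tx_annot):
        em = tl.ExpressionMatrix(
            "transcript", pd.DataFrame({"s1": [3.0, 2.0]}, index=["T1", "T2"])
        )
        gene = tl.gene_expression_from_transcripts(em, two_tx_annot)
        assert gene.data.loc["G1", "s1"] == pytest.approx(5.0)

    def test_single_transcript_gene_passes_through(self):
        annot = _one_region_model(100)
        em = tl.ExpressionMatrix("transcript", pd.DataFrame({"s1": [7.5]}, index=["T"]))
        gene = tl.gene_expression_from_transcripts(em, annot)
        assert gene.data.loc["G", "s1"] == 7.5

    def test_unknown_transcript_rejected(self, two_tx_annot):
        em = tl.ExpressionMatrix("transcript", pd.DataFrame({"s1": [1.0]}, index=["T9"]))
        with pytest.raises(ValueError, match="T9"):
            tl.gene_expression_from_transcripts(em, two_tx_annot)

    def test_region_fpkm_sums_member_transcripts(self, two_tx_annot):
        em = tl.ExpressionMatrix(
            "transcript", pd.DataFrame({"s1": [1.5, 2.5]}, index=["T1", "T2"])
        )
        regions = tl.exonic_region_expression(em, two_tx_annot)
        assert regions.data.loc["G1:2", "s1"] == pytest.approx(4.0)  # shared by T1+T2
        assert regions.data.loc["G1:3", "s1"] == pytest.approx(2.5)  # private to T2

    def test_silent_gene_gives_zero_regions(self, two_tx_annot):
        em = tl.ExpressionMatrix(
            "transcript", pd.DataFrame({"s1": [0.0, 0.0]}, index=["T1", "T2"])
        )
        regions = tl.exonic_region_expression(em, two_tx_annot)
        assert (regions.data["s1"] == 0).all()

    def test_aggregation_conserves_mass_and_is_linear(self, mixed_cohort):
        annot, tx = mixed_cohort.annotation, mixed_cohort.tx_fpkm
        gene = tl.gene_expression_from_transcripts(tx, annot)
        # per sample, total gene FPKM equals total transcript FPKM
        np.testing.assert_allclose(
            gene.data.sum(axis=0).to_numpy(), tx.data.sum(axis=0).to_numpy(), rtol=1e-12
        )
        # linearity: scaling the transcript matrix scales both aggregates
        tx3 = tl.ExpressionMatrix("transcript", tx.data * 3.0)
        gene3 = tl.gene_expression_from_transcripts(tx3, annot)
        np.testing.assert_allclose(gene3.data.to_numpy(), 3.0 * gene.data.to_numpy(), rtol=1e-12)
        reg = tl.exonic_region_expression(tx, annot)
        reg3 = tl.exonic_region_expression(tx3, annot)
        np.testing.assert_allclose(reg3.data.to_numpy(), 3.0 * reg.data.to_numpy(), rtol=1e-12)


def _prevalence_fixture(n_patients, n_nonzero, paired_metadata):
    """One gene/transcript pair non-zero in both tissues of n_nonzero patients."""
    meta = paired_metadata(n_patients)
    samples = meta.sample_ids
    values = np.ones((1, len(samples)))
    for i in range(n_nonzero, n_patients):
        values[0, 2 * i] = 0.0  # zero out the tumor sample of later patients
    gene = tl.ExpressionMatrix("gene", pd.DataFrame(values, index=["G"], columns=samples))
    tx = tl.ExpressionMatrix("transcript", pd.DataFrame(values, index=["G.t1"], columns=samples))
    annot = tl.AnnotationModel(
        genes={"G": tl.Gene("G", "chr1")},
        transcripts={"G.t1": tl.Transcript("G.t1", "G", ((1, 100),))},
    )
    return gene, tx, annot, meta


class TestQualityFilters:
    @pytest.mark.parametrize("n_nonzero,kept", [(39, True), (38, False)])
    def test_39_of_77_prevalence_boundary(self, n_nonzero, kept, paired_metadata):
        gene, tx, annot, meta = _prevalence_fixture(77, n_nonzero, paired_metadata)
        report = tl.apply_quality_filters(gene, tx, annot, meta, min_nonzero_patients=39)
        assert ("G" in report.kept["gene"]) is kept
        assert ("G.t1" in report.kept["transcript"]) is kept

    def test_default_threshold_is_39_for_77_patients(self):
        assert tl.default_min_nonzero_patients(77) == 39
        assert tl.default_min_nonzero_patients(40) == 21

    def test_absent_transcript_removes_gene_and_its_transcripts(self, paired_metadata):
        meta = paired_metadata(4)
        samples = meta.sample_ids
        annot = tl.AnnotationModel(
            genes={"G1": tl.Gene("G1", "chr1"), "G2": tl.Gene("G2", "chr1")},
            transcripts={
                "G1.t1": tl.Transcript("G1.t1", "G1", ((1, 100),)),
                "G1.t2": tl.Transcript("G1.t2", "G1", ((1, 100),)),
                "G2.t1": tl.Transcript("G2.t1", "G2", ((1, 100),)),
            },
        )
        tx_vals = pd.DataFrame(
            np.ones((3, len(samples))), index=["G1.t1", "G1.t2", "G2.t1"], columns=samples
        )
        tx_vals.loc["G1.t2", samples[0]] = np.nan  # absent, not zero
        tx = tl.ExpressionMatrix("transcript", tx_vals)
        gene = tl.ExpressionMatrix(
            "gene", pd.DataFrame(np.ones((2, len(samples))), index=["G1", "G2"], columns=samples)
        )
        report = tl.apply_quality_filters(gene, tx, annot, meta)
        assert report.removed_absent_transcript == {"G1"}
        assert report.kept["gene"] == ["G2"]
        assert report.kept["transcript"] == ["G2.t1"]

    def test_duplicate_gene_rows_removed_as_multi_fpkm(self, paired_metadata):
        meta = paired_metadata(4)
        samples = meta.sample_ids
        annot = tl.AnnotationModel(
            genes={"G1": tl.Gene("G1", "chr1")},
            transcripts={"G1.t1": tl.Transcript("G1.t1", "G1", ((1, 100),))},
        )
        gene = tl.ExpressionMatrix(
            "gene",
            pd.DataFrame(np.ones((2, len(samples))), index=["G1", "G1"], columns=samples),
            allow_duplicate_features=True,
        )
        tx = tl.ExpressionMatrix(
            "transcript", pd.DataFrame(np.ones((1, len(samples))), index=["G1.t1"], columns=samples)
        )
        report = tl.apply_quality_filters(gene, tx, annot, meta)
        assert report.removed_multi_fpkm == {"G1"}
        assert report.kept["gene"] == []

    def test_report_partitions_features(self, paired_metadata):
        gene, tx, annot, meta = _prevalence_fixture(10, 3, paired_metadata)
        report = tl.apply_quality_filters(gene, tx, annot, meta, min_nonzero_patients=6)
        removed = (report.removed_multi_fpkm | report.removed_absent_transcript
                   | report.removed_low_prevalence)
        kept = set(report.kept["gene"]) | set(report.kept["transcript"])
        assert removed & kept == set()
        assert kept | removed == {"G", "G.t1"}

    def test_threshold_above_patient_count_rejected(self, paired_metadata):
        gene, tx, annot, meta = _prevalence_fixture(10, 10, paired_metadata)
        with pytest.raises(ValueError, match="paired patients"):
            tl.apply_quality_filters(gene, tx, annot, meta, min_nonzero_patients=11)


class TestShortRegionFilter:
    @pytest.mark.parametrize("length,removed", [(99, True), (100, False), (5000, False)])
    def test_length_boundary(self, length, removed):
        annot = _one_region_model(length)
        rid = next(iter(annot.exonic_regions))
        report = tl.filter_short_regions(annot, min_length_bp=100)
        assert (rid in report.removed_short_regions) is removed
        assert (rid in report.kept["exonic_region"]) is not removed
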
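"""NB differential testing: size factors, dispersions, Wald test, overlap stats."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trilayer as tl
from trilayer.diffexpr import significant_features
from trilayer.simulate import simulate_null_counts


def _counts(values, features=None, samples=None, level="gene"):
    values = np.asarray(values)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return tl.CountMatrix(level, pd.DataFrame(values, index=features, columns=samples))


def _meta(tissues):
    return tl.SampleMetadata(pd.DataFrame(
        {"patient_id": [f"P{i}" for i in range(len(tissues))], "tissue": tissues},
        index=pd.Index([f"s{j}" for j in range(len(tissues))], name="sample_id"),
    ))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        sf = tl.estimate_size_factors(_counts([[5, 5], [9, 9]]))
        np.testing.assert_allclose(sf.to_numpy(), [1.0, 1.0])

    def test_doubled_column_splits_symmetrically(self):
        sf = tl.estimate_size_factors(_counts([[10, 20], [4, 8], [7, 14]]))
        np.testing.assert_allclose(sf.to_numpy(), [1 / math.sqrt(2), math.sqrt(2)], rtol=1e-12)

    def test_matches_brute_force_median_of_ratios(self):
        # independent oracle: explicit per-feature ratios and an explicit median
        values = np.array([[4, 8, 6], [10, 1, 7], [3, 9, 12], [20, 40, 10]])
        cm = _counts(values)
        oracle = []
        geo = [math.exp(np.mean([math.log(v) for v in row])) for row in values]
        for j in range(3):
            ratios = sorted(values[i, j] / geo[i] for i in range(4))
            oracle.append((ratios[1] * ratios[2]) ** 0.5)  # median of 4
        oracle = np.array(oracle)
        oracle /= np.exp(np.mean(np.log(oracle)))  # geometric mean 1 convention
        np.testing.assert_allclose(tl.estimate_size_factors(cm).to_numpy(), oracle, rtol=1e-12)

    def test_no_all_positive_feature_rejected(self):
        with pytest.raises(ValueError, match="positive counts"):
            tl.estimate_size_factors(_counts([[0, 5], [3, 0]]))

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(8)
        cm = _counts(rng.integers(1, 500, size=(30, 7)))
        sf = tl.estimate_size_factors(cm)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, rel=1e-12)


class TestDispersions:
    def test_constant_feature_has_zero_raw_dispersion(self):
        cm = _counts([[7] * 8, [3, 9, 4, 8, 2, 7, 5, 6]])
        sf = pd.Series(1.0, index=cm.sample_ids)
        fit = tl.estimate_dispersions(cm, sf, ["tumor"] * 4 + ["normal"] * 4)
        assert fit.raw_dispersions.iloc[0] == 0.0

    def test_recovers_true_dispersion_from_nb_counts(self):
        rng = np.random.default_rng(5)
        alpha, mean = 0.2, 500.0
        r = 1 / alpha
        counts = rng.negative_binomial(r, r / (r + mean), size=(2000, 20))
        cm = _counts(counts)
        sf = pd.Series(1.0, index=cm.sample_ids)
        fit = tl.estimate_dispersions(cm, sf, ["tumor"] * 10 + ["normal"] * 10)
        assert fit.raw_dispersions.median() == pytest.approx(alpha, rel=0.15)

    def test_poisson_counts_give_small_dispersions(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(300.0, size=(2000, 30))
        cm = _counts(counts)
        sf = pd.Series(1.0, index=cm.sample_ids)
        fit = tl.estimate_dispersions(cm, sf, ["tumor"] * 15 + ["normal"] * 15)
        assert fit.raw_dispersions.median() < 0.005
        assert fit.trend_coef[0] < 0.005

    def test_single_sample_group_rejected(self):
        cm = _counts([[1, 2, 3]])
        sf = pd.Series(1.0, index=cm.sample_ids)
        with pytest.raises(ValueError, match="at least 2"):
            tl.estimate_dispersions(cm, sf, ["tumor", "normal", "normal"])


def poisson_wald_oracle(row, sf, tumor_mask):
    """Independent closed-form Wald p for the alpha -> 0 (Poisson) limit."""
    q = np.asarray(row, dtype=float) / sf
    mu_t, mu_n = q[tumor_mask].mean(), q[~tumor_mask].mean()
    n_t, n_n = tumor_mask.sum(), (~tumor_mask).sum()
    var_t = mu_t * (1.0 / sf[tumor_mask]).sum() / n_t**2
    var_n = mu_n * (1.0 / sf[~tumor_mask]).sum() / n_n**2
    se = math.sqrt(var_t / (mu_t + 0.5) ** 2 + var_n / (mu_n + 0.5) ** 2)
    z = (math.log(mu_t + 0.5) - math.log(mu_n + 0.5)) / se
    return 2 * stats.norm.sf(abs(z))


class TestWald:
    def test_identical_groups_give_zero_lfc_and_p_one(self):
        row = pd.Series([5, 8, 5, 8], index=[f"s{j}" for j in range(4)], name="f")
        sf = pd.Series(1.0, index=row.index)
        res = tl.nb_wald_test(row, sf, 0.1, ["tumor", "tumor", "normal", "normal"])
        assert res.log2_fold_change == 0.0
        assert res.p_value == 1.0

    def test_poisson_limit_matches_closed_form_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 400, size=(50, 12))
        sf_vals = rng.uniform(0.5, 2.0, size=12)
        sf_vals /= np.exp(np.mean(np.log(sf_vals)))
        sf = pd.Series(sf_vals, index=[f"s{j}" for j in range(12)])
        tumor = np.array([True] * 6 + [False] * 6)
        design = ["tumor"] * 6 + ["normal"] * 6
        for i in range(50):
            row = pd.Series(counts[i], index=sf.index, name=f"f{i}")
            res = tl.nb_wald_test(row, sf, 0.0, design)
            assert res.p_value == pytest.approx(
                poisson_wald_oracle(counts[i], sf_vals, tumor), abs=1e-6
            )

    def test_group_relabeling_flips_sign_keeps_p(self):
        rng = np.random.default_rng(10)
        row = pd.Series(rng.integers(0, 300, size=10), index=[f"s{j}" for j in range(10)], name="f")
        sf = pd.Series(1.0, index=row.index)
        a = tl.nb_wald_test(row, sf, 0.15, ["tumor"] * 5 + ["normal"] * 5)
        b = tl.nb_wald_test(row, sf, 0.15, ["normal"] * 5 + ["tumor"] * 5)
        assert a.log2_fold_change == pytest.approx(-b.log2_fold_change, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_all_zero_feature_is_degenerate(self):
        row = pd.Series([0] * 6, index=[f"s{j}" for j in range(6)], name="f")
        sf = pd.Series(1.0, index=row.index)
        res = tl.nb_wald_test(row, sf, 0.2, ["tumor"] * 3 + ["normal"] * 3)
        assert res.p_value == 1.0 and res.log2_fold_change == 0.0 and res.degenerate

    def test_power_at_fourfold_change_8v8(self):
        # 500 simulated features with a true 4-fold tumor shift, alpha = 0.1
        rng = np.random.default_rng(11)
        alpha, mean_n = 0.1, 200.0
        r = 1 / alpha
        tumor_counts = rng.negative_binomial(r, r / (r + 4 * mean_n), size=(500, 8))
        normal_counts = rng.negative_binomial(r, r / (r + mean_n), size=(500, 8))
        counts = np.hstack([tumor_counts, normal_counts])
        sf = pd.Series(1.0, index=[f"s{j}" for j in range(16)])
        design = ["tumor"] * 8 + ["normal"] * 8
        hits = 0
        for i in range(500):
            row = pd.Series(counts[i], index=sf.index)
            if tl.nb_wald_test(row, sf, alpha, design).p_value < 0.001:
                hits += 1
        assert hits / 500 >= 0.95


class TestTestLevel:
    def test_empty_matrix_gives_empty_results(self):
        cm = _counts(np.empty((0, 4), dtype=int), features=[], level="gene")
        assert tl.test_level(cm, _meta(["tumor", "tumor", "normal", "normal"]), "gene") == []

    def test_level_mismatch_rejected(self, mixed_cohort):
        with pytest.raises(ValueError, match="level"):
            tl.test_level(mixed_cohort.counts["gene"], mixed_cohort.metadata, "transcript")

    def test_planted_sixfold_deg_significant_at_all_cutoffs(self, mixed_cohort):
        results = tl.test_level(mixed_cohort.counts["gene"], mixed_cohort.metadata, "gene")
        (gene_de,) = [e.gene_id for e in mixed_cohort.truth.events if e.kind == "gene_de"]
        hit = next(r for r in results if r.feature_id == gene_de)
        assert all(hit.is_significant[c] for c in (0.05, 0.01, 0.001))

    def test_bonferroni_family_is_feature_count(self):
        rng = np.random.default_rng(12)
        cm = _counts(rng.integers(10, 300, size=(40, 8)))
        res = tl.test_level(cm, _meta(["tumor"] * 4 + ["normal"] * 4), "gene")
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_value * 40), rel=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.001, 50, 0.05), (0.5, 3, 1.0), (0.0, 7, 0.0)])
    def test_examples(self, p, m, expected):
        assert tl.bonferroni_adjust([p], m)[0] == pytest.approx(expected, abs=1e-12)

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            tl.bonferroni_adjust([1.5], 2)

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            tl.bonferroni_adjust([0.1, 0.2, 0.3], 2)


class TestMapToGenes:
    def test_transcripts_collapse_to_parent_genes(self, mixed_cohort):
        annot = mixed_cohort.annotation
        gid = sorted(annot.genes)[0]
        txs = [t.transcript_id for t in annot.transcripts_of_gene(gid)]
        other = sorted(annot.genes)[1]
        other_tx = annot.transcripts_of_gene(other)[0].transcript_id
        assert tl.map_to_genes(txs + [other_tx], "transcript", annot) == {gid, other}

    def test_regions_of_one_gene_collapse_to_it(self, mixed_cohort):
        annot = mixed_cohort.annotation
        gid = sorted(annot.genes)[0]
        rids = [r.region_id for r in annot.regions_of_gene(gid)]
        assert tl.map_to_genes(rids, "exonic_region", annot) == {gid}

    def test_empty_input_gives_empty_set(self, mixed_cohort):
        assert tl.map_to_genes([], "transcript", mixed_cohort.annotation) == set()

    def test_unresolvable_feature_listed_in_error(self, mixed_cohort):
        with pytest.raises(ValueError, match="TX_MISSING"):
            tl.map_to_genes(["TX_MISSING"], "transcript", mixed_cohort.annotation)


def hypergeom_enumeration_oracle(universe_size, a_size, b_size, k):
    """P(overlap >= k) by explicit combinatorial enumeration."""
    total = math.comb(universe_size, b_size)
    num = sum(
        math.comb(a_size, j) * math.comb(universe_size - a_size, b_size - j)
        for j in range(k, min(a_size, b_size) + 1)
    )
    return num / total


class TestHypergeometricOverlap:
    def test_matches_enumeration_for_all_small_universes(self):
        for u in range(1, 13):
            universe = set(range(u))
            for a_size in range(u + 1):
                for b_size in range(u + 1):
                    set_a = set(range(a_size))
                    set_b = set(range(u - b_size, u))  # arbitrary placement
                    res = tl.hypergeometric_overlap(set_a, set_b, universe)
                    oracle = hypergeom_enumeration_oracle(u, a_size, b_size, res.overlap_size)
                    assert res.hypergeometric_p == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_zero_overlap_has_p_one(self):
        res = tl.hypergeometric_overlap({1, 2}, {3, 4}, set(range(10)))
        assert res.hypergeometric_p == 1.0

    def test_forced_total_overlap_has_p_one(self):
        u = set(range(6))
        res = tl.hypergeometric_overlap(u, u, u)
        assert res.overlap_size == 6 and res.hypergeometric_p == pytest.approx(1.0)

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            tl.hypergeometric_overlap({99}, {1}, {1, 2})


def test_null_pvalues_uniform_and_switch_events_invisible_at_gene_level(mixed_cohort):
    """Planted isoform switches show at transcript level but not gene level."""
    sig_tx = significant_features(
        tl.test_level(mixed_cohort.counts["transcript"], mixed_cohort.metadata, "transcript"), 0.05
    )
    sig_gene = significant_features(
        tl.test_level(mixed_cohort.counts["gene"], mixed_cohort.metadata, "gene"), 0.05
    )
    (switch,) = [e.gene_id for e in mixed_cohort.truth.events if e.kind == "transcript_switch"]
    switch_tx = {t for t in mixed_cohort.truth.dets
                 if mixed_cohort.annotation.transcripts[t].gene_id == switch}
    assert switch_tx & sig_tx  # detected among isoforms
    assert switch not in sig_gene  # invisible in the gene total
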
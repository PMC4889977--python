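"""OLS association fits, collinearity rule, hierarchical FDR, X comparisons."""

import numpy as np
import pandas as pd
import pytest

from sexreg import dataio, eqtl, synthetic
from sexreg.dataio import FEMALE, MALE, GeneAnnotation


def _annotation(tss=2_000_000, tes=2_010_000, chrom="chr1"):
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["g1"], "chrom": [chrom], "tss": [tss], "tes": [tes],
        "strand": ["+"]}))


class TestCisPairs:
    def test_window_boundaries(self, tiny_cohort):
        ann = _annotation()
        gm = tiny_cohort.genotypes
        gm2 = dataio.GenotypeMatrix(
            np.array(["in_lo", "out_lo", "body", "in_hi", "out_hi"], dtype=object),
            np.array(["chr1"] * 5, dtype=object),
            np.array([1_000_001, 999_999, 2_005_000, 3_010_000, 3_010_001]),
            np.zeros((5, gm.samples.n)), gm.samples)
        pairs = eqtl.cis_pairs(ann, gm2, window=1e6)
        assert set(pairs["variant_id"]) == {"in_lo", "body", "in_hi"}

    def test_zero_window_intragenic_only(self, tiny_cohort):
        gm = tiny_cohort.genotypes
        gm2 = dataio.GenotypeMatrix(
            np.array(["inside", "outside"], dtype=object),
            np.array(["chr1"] * 2, dtype=object),
            np.array([2_005_000, 2_010_001]),
            np.zeros((2, gm.samples.n)), gm.samples)
        pairs = eqtl.cis_pairs(_annotation(), gm2, window=0)
        assert list(pairs["variant_id"]) == ["inside"]


class TestFits:
    def test_noise_free_additive_exact(self):
        g = np.array([0., 1., 2., 0., 1., 2., 1., 0.])
        y = 2.0 * g
        rec = eqtl.fit_additive(y, g, None, stratum=eqtl.MALE_STRATUM)
        assert rec.beta1 == pytest.approx(2.0, abs=1e-12)
        assert rec.p < 1e-12

    def test_six_point_fixture_matches_normal_equations(self):
        g = np.array([0., 1., 2., 0., 1., 2.])
        s = np.array([0., 0., 0., 1., 1., 1.])
        y = np.array([0.3, 1.1, 2.4, 0.9, 1.8, 3.1])
        X = np.column_stack([np.ones(6), g, s])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        rec = eqtl.fit_additive(y, g, s.astype(int))
        assert rec.intercept == pytest.approx(beta_oracle[0], abs=1e-10)
        assert rec.beta1 == pytest.approx(beta_oracle[1], abs=1e-10)
        assert rec.beta2 == pytest.approx(beta_oracle[2], abs=1e-10)

    def test_interaction_pure_product_signal(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.4, 200).astype(float)
        s = rng.integers(0, 2, 200).astype(float)
        y = g * s
        rec = eqtl.fit_interaction(y, g, s)
        assert rec.beta3 == pytest.approx(1.0, abs=1e-10)
        assert abs(rec.beta1) < 1e-10 and abs(rec.beta2) < 1e-10

    def test_missing_genotypes_dropped(self, rng):
        g = rng.binomial(2, 0.5, 100).astype(float)
        y = 0.5 * g + rng.normal(0, 0.1, 100)
        g[:10] = np.nan
        rec = eqtl.fit_additive(y, g, None, stratum=eqtl.MALE_STRATUM)
        assert rec.n == 90

    def test_constant_genotype_raises(self):
        with pytest.raises(ValueError, match="variance"):
            eqtl.fit_additive(np.arange(10.0), np.ones(10), None,
                              stratum=eqtl.MALE_STRATUM)


class TestCollinearity:
    def test_genotype_equal_to_sex_dropped(self):
        s = np.array([0., 1.] * 20)
        keep, reason = eqtl.collinearity_filter(s.copy(), s)
        assert not keep and "collinear" in reason

    def test_constant_genotype_dropped(self):
        keep, reason = eqtl.collinearity_filter(np.ones(40),
                                                np.array([0., 1.] * 20))
        assert not keep and "constant" in reason

    def test_independent_kept(self, rng):
        keep, _ = eqtl.collinearity_filter(
            rng.binomial(2, 0.5, 40).astype(float),
            rng.integers(0, 2, 40).astype(float))
        assert keep


class TestGeneLevelFdr:
    def test_bonferroni_arithmetic(self):
        recs = pd.DataFrame({
            "gene_id": ["g1"] * 10, "variant_id": [f"v{i}" for i in range(10)],
            "p": [0.004] + [0.5] * 9})
        out = eqtl.gene_level_fdr(recs)
        assert out["bonf_p"].iloc[0] == pytest.approx(0.04)
        assert out["best_variant"].iloc[0] == "v0"

    def test_single_test_gene_unchanged(self):
        out = eqtl.gene_level_fdr(pd.DataFrame({
            "gene_id": ["g"], "variant_id": ["v"], "p": [0.03]}))
        assert out["bonf_p"].iloc[0] == pytest.approx(0.03)

    def test_tie_break_lexicographic(self):
        out = eqtl.gene_level_fdr(pd.DataFrame({
            "gene_id": ["g", "g"], "variant_id": ["vB", "vA"],
            "p": [0.01, 0.01]}))
        assert out["best_variant"].iloc[0] == "vA"


class TestScan:
    def test_map_cis_recovers_strong_eqtls(self, tiny_cohort):
        pairs, summary = eqtl.map_cis(tiny_cohort.expression,
                                      tiny_cohort.genotypes,
                                      tiny_cohort.annotation)
        truth = tiny_cohort.truth.genes.set_index("gene_id")
        strong = set(truth[truth["beta1"].abs() > 0.4].index)
        hits = summary[summary["gene_id"].isin(strong)]
        assert len(hits) > 0
        assert (hits["q"] < 0.05).mean() > 0.8

    def test_sample_permutation_identical_results(self, tiny_cohort, rng):
        co = tiny_cohort
        perm = rng.permutation(co.samples.n)
        samples_p = dataio.SampleInfo(co.samples.sample_ids[perm],
                                      co.samples.sex[perm])
        gm_p = dataio.GenotypeMatrix(co.genotypes.variant_ids,
                                     co.genotypes.chrom, co.genotypes.pos,
                                     co.genotypes.dosage[:, perm], samples_p,
                                     co.genotypes.x_coding)
        ex_p = dataio.ExpressionMatrix(co.expression.gene_ids,
                                       co.expression.values[:, perm],
                                       samples_p, co.expression.kind)
        _, s1 = eqtl.map_cis(co.expression, co.genotypes, co.annotation)
        _, s2 = eqtl.map_cis(ex_p, gm_p, co.annotation)
        np.testing.assert_allclose(s1["best_p"], s2["best_p"], rtol=1e-9)

    def test_interaction_maf_filter_is_per_sex(self):
        # variant common overall but absent in males must be excluded
        cfg = synthetic.SimConfig(n_male=50, n_female=100, n_genes_auto=2,
                                  n_genes_x=0, variants_per_gene=1,
                                  gwas_n_traits=0, seed=0)
        co = synthetic.simulate_cohort(cfg)
        gm = co.genotypes
        male = co.samples.sex == MALE
        gm.dosage[0, male] = 0.0
        _, summary = eqtl.map_cis(co.expression, gm, co.annotation,
                                  eqtl.INTERACTION)
        tested = set(summary["best_variant"])
        assert gm.variant_ids[0] not in tested


class TestXaStatistics:
    def test_depletion_null_uniformish(self, rng):
        summary = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(400)],
            "q": rng.random(400)})
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(400)],
            "chrom": ["chrX"] * 100 + ["chr1"] * 300,
            "tss": np.arange(400) + 1, "tes": np.arange(400) + 2,
            "strand": ["+"] * 400}))
        out = eqtl.xa_eqtl_depletion(summary, ann, (0.3,))
        assert out["p"].iloc[0] > 0.001

    def test_qq_enrichment_detects_shift(self, rng):
        p_auto = rng.random(2000)
        p_x = rng.random(2000) ** 3  # enriched small p
        res = eqtl.qq_enrichment(p_x, p_auto, top_k=50)
        assert res.p_value < 0.01

    def test_qq_enrichment_refuses_topk_one(self, rng):
        with pytest.raises(ValueError):
            eqtl.qq_enrichment(rng.random(10), rng.random(10), top_k=1)

    def test_effect_size_fold_recovery(self, rng):
        a = np.abs(rng.normal(0, 0.3, 500))        # X-like, smaller
        b = np.abs(rng.normal(0, 0.4, 500))        # autosome-like
        out = eqtl.effect_size_compare(a, b)
        assert out["fold_b_over_a"].iloc[0] == pytest.approx(4 / 3, rel=0.15)

    def test_quantile_bins_partition_fifths(self, rng):
        score = rng.random(250)
        a = np.abs(rng.normal(0, 1, 250))
        b = np.abs(rng.normal(0, 1, 400))
        out = eqtl.effect_size_compare(a, b, score=score, n_bins=5)
        assert sorted(out["n_a"]) == [50, 50, 50, 50, 50]
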
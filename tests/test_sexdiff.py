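"""Differential variance strategies, matching, and X-vs-autosome tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sexreg import dataio, sexdiff, stats
from sexreg.dataio import FEMALE, MALE, ExpressionMatrix, SampleInfo


def _expr(values, sex, kind=dataio.RESIDUALS):
    values = np.atleast_2d(values)
    n = values.shape[1]
    samples = SampleInfo(np.array([f"s{i}" for i in range(n)], dtype=object),
                         np.asarray(sex))
    genes = np.array([f"g{i}" for i in range(values.shape[0])], dtype=object)
    return ExpressionMatrix(genes, values, samples, kind)


class TestMatchSubsample:
    def test_minority_kept_majority_subsampled(self):
        sex = np.array([MALE] * 5 + [FEMALE] * 9)
        idx = sexdiff.match_subsample(sex, seed=0)
        assert (sex[idx] == MALE).sum() == 5 and (sex[idx] == FEMALE).sum() == 5
        assert set(np.flatnonzero(sex == MALE)) <= set(idx)

    def test_deterministic_per_seed(self):
        sex = np.array([MALE] * 274 + [FEMALE] * 648)
        a = sexdiff.match_subsample(sex, 7)
        b = sexdiff.match_subsample(sex, 7)
        np.testing.assert_array_equal(a, b)
        assert (sex[a] == FEMALE).sum() == 274

    def test_balanced_identity(self):
        sex = np.array([MALE, FEMALE] * 4)
        np.testing.assert_array_equal(sexdiff.match_subsample(sex, 0),
                                      np.arange(8))

    def test_single_sex_rejected(self):
        with pytest.raises(ValueError):
            sexdiff.match_subsample(np.zeros(10, dtype=int), 0)


class TestQuantileNormalize:
    def test_three_point_example(self):
        out = sexdiff.quantile_normalize_to_normal([5.0, 1.0, 9.0])
        expected = sps.norm.ppf([(2 - .5) / 3, (1 - .5) / 3, (3 - .5) / 3])
        np.testing.assert_allclose(out, expected, atol=1e-9)
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[2] == pytest.approx(0.9674216, abs=1e-6)

    def test_rank_preservation(self, rng):
        x = rng.normal(0, 1, 100)
        out = sexdiff.quantile_normalize_to_normal(x)
        assert sps.spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            sexdiff.quantile_normalize_to_normal(np.ones(5))


class TestDv:
    def test_strategy_a_detects_doubled_sd(self, rng):
        sex = np.array([MALE] * 274 + [FEMALE] * 274)
        y = np.where(sex == FEMALE, rng.normal(0, 2.0, 548),
                     rng.normal(0, 1.0, 548))
        out = sexdiff.test_dv(_expr(y, sex), strategy=sexdiff.STRATEGY_A)
        assert out["p"].iloc[0] < 1e-6
        assert out["direction"].iloc[0] == "female"

    def test_strategy_b_takes_bf_branch_on_exponential(self, rng):
        sex = np.array([MALE] * 100 + [FEMALE] * 100)
        y = rng.exponential(1.0, 200)
        out = sexdiff.test_dv(_expr(y, sex), strategy=sexdiff.STRATEGY_B)
        assert out["branch"].iloc[0] == "BF"
        assert out["shapiro_p"].iloc[0] < 0.05

    def test_strategy_c_immune_to_pure_mean_shift(self, rng):
        # strong DE, no DV: strategy C should not reject more than nominally
        sex = np.array([MALE] * 150 + [FEMALE] * 150)
        vals = rng.normal(0, 1, (300, 300)) + 1.5 * sex[None, :]
        out = sexdiff.test_dv(_expr(vals, sex), strategy=sexdiff.STRATEGY_C)
        assert (out["p"] < 0.05).mean() < 0.1

    def test_sample_order_permutation_invariant(self, rng):
        sex = np.array([MALE] * 30 + [FEMALE] * 30)
        vals = rng.normal(0, 1, (5, 60))
        out1 = sexdiff.test_dv(_expr(vals, sex), strategy=sexdiff.STRATEGY_A)
        perm = rng.permutation(60)
        out2 = sexdiff.test_dv(_expr(vals[:, perm], sex[perm]),
                               strategy=sexdiff.STRATEGY_A)
        np.testing.assert_allclose(out1["p"], out2["p"], rtol=1e-10)


class TestDe:
    def test_identical_columns_p_one(self):
        sex = np.array([MALE] * 5 + [FEMALE] * 5)
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.concatenate([base, base])
        out = sexdiff.test_de(_expr(y, sex))
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_power_on_sex_shift(self, rng):
        sex = np.array([MALE] * 274 + [FEMALE] * 648)
        y = rng.normal(0, 0.5, 922) + 1.0 * sex
        out = sexdiff.test_de(_expr(y, sex), seed=1)
        assert out["q"].iloc[0] < 0.05
        assert out["direction"].iloc[0] == "female"

    def test_nb_counts_path(self, tiny_cohort):
        out = sexdiff.test_de(tiny_cohort.counts, method="nb", seed=0)
        assert len(out) == tiny_cohort.counts.n_genes
        assert ((out["p"] > 0) & (out["p"] <= 1)).all()
        # strong simulated escape/sex genes should surface
        truth = tiny_cohort.truth.genes.set_index("gene_id")
        null_genes = out[out["gene_id"].map(
            lambda g: abs(truth.loc[g, "beta2"]) < 1e-9
            and abs(truth.loc[g, "beta3"]) < 1e-9)]
        assert (null_genes["p"] < 0.05).mean() < 0.2

    def test_wrong_kind_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="counts"):
            sexdiff.test_de(tiny_cohort.expression, method="nb")


class TestXaComparisons:
    def test_proportions_and_fisher_oracle(self):
        flags = np.array([True] * 10 + [False] * 90 + [True] * 60 + [False] * 940)
        chrom = np.array(["chrX"] * 100 + ["chr1"] * 1000)
        out = sexdiff.xa_proportion_test(flags, chrom)
        assert out["prop_x"] == pytest.approx(0.10)
        assert out["prop_auto"] == pytest.approx(0.06)
        expected = sps.fisher_exact([[10, 90], [60, 940]],
                                    alternative="greater")[1]
        assert out["p"] == pytest.approx(expected, abs=1e-12)

    def test_null_odds_ratio_near_one(self):
        flags = np.array([True] * 10 + [False] * 90 + [True] * 100 + [False] * 900)
        chrom = np.array(["chrX"] * 100 + ["chr1"] * 1000)
        out = sexdiff.xa_proportion_test(flags, chrom)
        assert out["odds_ratio"] == pytest.approx(1.0, abs=0.05)

    def test_dv_de_overlap_independent_and_nested(self, rng):
        dv = rng.random(2000) < 0.1
        de = rng.random(2000) < 0.2
        assert sexdiff.dv_de_overlap_test(dv, de).p_value > 0.001
        nested = dv.copy()
        assert sexdiff.dv_de_overlap_test(dv, nested).p_value < 1e-10

    def test_all_false_column_p_one(self):
        res = sexdiff.dv_de_overlap_test(np.zeros(50, bool),
                                         np.array([True] * 25 + [False] * 25))
        assert res.p_value == 1.0
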
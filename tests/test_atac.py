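"""Size factors, NB dispersion, the exact NB test, and peak-gene integration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sexreg import atac, dataio
from sexreg.dataio import FEMALE, MALE, GeneAnnotation, PeakCountMatrix, SampleInfo


def _samples(n_m, n_f, prefix="s"):
    ids = np.array([f"{prefix}{i}" for i in range(n_m + n_f)], dtype=object)
    return SampleInfo(ids, np.array([MALE] * n_m + [FEMALE] * n_f))


from _oracles import nb_oracle


class TestSizeFactors:
    def test_identical_samples_unity(self):
        c = np.tile([[10], [20], [30]], (1, 4))
        np.testing.assert_allclose(atac.size_factors(c), 1.0)

    def test_doubled_sample_median_of_ratios(self):
        a = np.array([10, 20, 40, 100])
        c = np.column_stack([a, 2 * a])
        sf = atac.size_factors(c)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-9)

    def test_single_sample_unity(self):
        np.testing.assert_allclose(atac.size_factors(np.array([[5], [9]])), 1.0)

    def test_global_scaling_invariance(self, rng):
        c = rng.poisson(50, (40, 6))
        c[0] += 1  # ensure an all-positive row
        sf1 = atac.size_factors(c)
        sf2 = atac.size_factors(c * 3)
        q1 = c / sf1
        q2 = (c * 3) / sf2
        np.testing.assert_allclose(q1 / q2, q1[0, 0] / q2[0, 0], rtol=1e-9)

    def test_fallback_without_allpositive_peak(self, rng):
        c = rng.poisson(3, (6, 4))
        c[np.arange(6), np.arange(6) % 4] = 0  # every peak has a zero
        sf = atac.size_factors(c)
        assert np.all(sf > 0) and np.all(np.isfinite(sf))


class TestDispersion:
    def test_poisson_counts_alpha_near_zero(self, rng):
        c = rng.poisson(100, (500, 20))
        groups = np.array([0] * 10 + [1] * 10)
        alpha = atac.estimate_dispersion(c, groups, np.ones(20))
        assert np.median(alpha) < 0.01

    def test_nb_alpha_recovered(self, rng):
        alpha_true, mu = 0.2, 100.0
        r = 1 / alpha_true
        c = rng.negative_binomial(r, r / (r + mu), (400, 20))
        groups = np.array([0] * 10 + [1] * 10)
        alpha = atac.estimate_dispersion(c, groups, np.ones(20))
        assert 0.1 < np.median(alpha) < 0.35

    def test_constant_counts_zero(self):
        c = np.full((3, 8), 50)
        groups = np.array([0] * 4 + [1] * 4)
        np.testing.assert_allclose(
            atac.estimate_dispersion(c, groups, np.ones(8)), 0.0)


class TestNbTest:
    def test_identical_groups_p_one(self):
        counts = np.array([50, 50, 50, 50])
        sex = np.array([MALE, MALE, FEMALE, FEMALE])
        out = atac.nb_test(counts, sex, np.ones(4), 0.1)
        assert out["p"] == pytest.approx(1.0, abs=1e-9)
        assert out["l2fc_fm"] == pytest.approx(0.0)

    @pytest.mark.parametrize("kM,kF,alpha", [
        (10, 20, 0.0), (5, 40, 0.1), (30, 30, 0.2), (0, 25, 0.05), (13, 47, 0.3)])
    def test_matches_enumeration_oracle(self, kM, kF, alpha):
        # 2 + 2 samples, unit size factors; totals <= 60
        counts = np.array([kM // 2, kM - kM // 2, kF // 2, kF - kF // 2])
        sex = np.array([MALE, MALE, FEMALE, FEMALE])
        out = atac.nb_test(counts, sex, np.ones(4), alpha)
        mu = (kM + kF) / 4
        meanM = meanF = 2 * mu
        varM = varF = meanM + alpha * mu**2 * 2
        expected = nb_oracle(kM, kF, meanM, varM, meanF, varF)
        assert out["p"] == pytest.approx(expected, abs=1e-12)

    def test_sex_swap_flips_fold_keeps_p(self, rng):
        counts = rng.poisson([30, 35, 80, 90])
        sex = np.array([MALE, MALE, FEMALE, FEMALE])
        out1 = atac.nb_test(counts, sex, np.ones(4), 0.05)
        out2 = atac.nb_test(counts, 1 - sex, np.ones(4), 0.05)
        assert out2["l2fc_fm"] == pytest.approx(-out1["l2fc_fm"])
        assert out2["p"] == pytest.approx(out1["p"], abs=1e-12)

    def test_diff_accessibility_recovers_truth(self, tiny_cohort):
        out = atac.diff_accessibility(tiny_cohort.peaks)
        truth = tiny_cohort.truth.peaks.set_index("peak_id").rename(
            columns={"l2fc_fm": "true_l2fc"})
        merged = out.set_index("peak_id").join(truth)
        true_pos = merged[merged["sex_specific"]]
        true_null = merged[~merged["sex_specific"]]
        assert (true_pos["q"] < 0.1).mean() > 0.6
        assert (true_null["p"] < 0.05).mean() < 0.15
        # fold direction matches the simulated female/male shift
        called = true_pos[true_pos["q"] < 0.1]
        assert (np.sign(called["l2fc_fm"]) == np.sign(called["true_l2fc"])).all()


class TestLinking:
    def _peaks_at(self, positions, chrom="chr1"):
        df = pd.DataFrame({
            "peak_id": [f"p{i}" for i in range(len(positions))],
            "chrom": chrom, "start": positions,
            "end": [p + 500 for p in positions]})
        s = _samples(2, 2, "a")
        return PeakCountMatrix(df, np.ones((len(positions), 4), dtype=np.int64), s)

    def test_40kb_boundary(self):
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["g"], "chrom": ["chr1"], "tss": [100_000],
            "tes": [110_000], "strand": ["+"]}))
        peaks = self._peaks_at([100_000 - 39_000, 100_000 - 41_000])
        links = atac.peak_gene_link(peaks, ann, upstream_bp=40_000)
        assert set(links["peak_id"]) == {"p0"}

    def test_zero_window_tss_overlap_only(self):
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["g"], "chrom": ["chr1"], "tss": [100_000],
            "tes": [110_000], "strand": ["+"]}))
        peaks = self._peaks_at([99_800, 98_000])
        links = atac.peak_gene_link(peaks, ann, upstream_bp=0)
        assert set(links["peak_id"]) == {"p0"}

    def test_minus_strand_upstream_is_higher_coordinates(self):
        ann = GeneAnnotation(pd.DataFrame({
            "gene_id": ["g"], "chrom": ["chr1"], "tss": [200_000],
            "tes": [100_000], "strand": ["-"]}))
        # promoter at 200,000; upstream extends to higher coordinates
        peaks = self._peaks_at([200_000 + 10_000, 100_000 - 10_000])
        links = atac.peak_gene_link(peaks, ann, upstream_bp=40_000)
        assert set(links["peak_id"]) == {"p0"}


class TestEnrichment:
    def test_escape_decile_floor(self, tiny_cohort, rng):
        diff = pd.DataFrame({
            "peak_id": [f"x{i}" for i in range(25)], "chrom": "chrX",
            "p": rng.random(25), "l2fc_fm": rng.normal(0, 1, 25)})
        links = pd.DataFrame({"peak_id": [f"x{i}" for i in range(25)],
                              "gene_id": [f"g{i}" for i in range(25)]})
        out = atac.escape_enrichment(diff, {"g0"}, links)
        assert out["n_top_peaks"] == 2

    def test_escape_truth_enriched(self, tiny_cohort):
        diff = atac.diff_accessibility(tiny_cohort.peaks)
        links = atac.peak_gene_link(tiny_cohort.peaks, tiny_cohort.annotation)
        truth = tiny_cohort.truth.genes
        escape = set(truth.loc[truth["escape"], "gene_id"])
        if not escape:
            pytest.skip("no escape genes drawn in fixture")
        out = atac.escape_enrichment(diff, escape, links, top_fraction=0.3)
        assert out["prop_escape_top"] >= out["prop_escape_shared"]

    def test_integration_null_or_near_one(self, rng):
        n_peaks, n_genes = 200, 200
        diff = pd.DataFrame({
            "peak_id": [f"p{i}" for i in range(n_peaks)], "chrom": "chr1",
            "p": rng.random(n_peaks), "q": rng.random(n_peaks),
            "direction": rng.choice(["female", "male"], n_peaks),
            "l2fc_fm": rng.normal(0, 1, n_peaks)})
        links = pd.DataFrame({"peak_id": [f"p{i}" for i in range(n_peaks)],
                              "gene_id": [f"g{i}" for i in range(n_genes)]})
        flags = pd.Series(rng.random(n_genes) < 0.3,
                          index=[f"g{i}" for i in range(n_genes)])
        out = atac.integration_enrichment(diff, flags, links, (0.5,))
        row = out["per_threshold"].iloc[0]
        assert row["p"] > 0.001
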
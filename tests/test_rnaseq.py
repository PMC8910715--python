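"""FPKM, normalisation, the NB Wald test, DEG rules, clustering, qPCR ops."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkseg import rnaseq


class TestFpkm:
    def test_worked_example(self):
        assert rnaseq.compute_fpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self):
        assert rnaseq.compute_fpkm(0, 1234, 5_000_000) == 0.0

    def test_scale_invariance_in_library_size(self, counts_3v3):
        counts, _ = counts_3v3
        lengths = np.full(len(counts), 1500)
        a = rnaseq.compute_fpkm(counts, lengths, None)
        b = rnaseq.compute_fpkm(counts * 2, lengths, None)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rnaseq.compute_fpkm(5, 1000, 0)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        np.testing.assert_allclose(rnaseq.size_factors(counts), 1.0)

    def test_doubled_column_has_doubled_factor(self):
        base = np.array([10, 25, 40, 7, 100])
        counts = pd.DataFrame({"a": base, "b": base, "c": 2 * base})
        f = rnaseq.size_factors(counts)
        assert f["c"] == pytest.approx(2 * f["a"])

    def test_matches_hand_median_of_ratios(self):
        counts = pd.DataFrame(
            {"s1": [4, 10, 20, 8, 100], "s2": [8, 10, 10, 16, 100], "s3": [2, 40, 40, 4, 100]}
        )
        mat = counts.to_numpy(float)
        gm = np.exp(np.log(mat).mean(axis=1))
        want = np.median(mat / gm[:, None], axis=0)
        np.testing.assert_allclose(rnaseq.size_factors(counts), want)

    def test_requires_an_all_nonzero_gene(self):
        counts = pd.DataFrame({"a": [0, 3], "b": [5, 0]})
        with pytest.raises(ValueError):
            rnaseq.size_factors(counts)


class TestNbWald:
    def test_identical_group_means_are_null(self):
        cols = ["Tall1", "Tall2", "Tall3", "Dwarf1", "Dwarf2", "Dwarf3"]
        counts = pd.DataFrame([[30, 40, 50, 30, 40, 50]], columns=cols, index=["g"])
        groups = pd.Series(["tall"] * 3 + ["dwarf"] * 3, index=cols)
        de = rnaseq.nb_wald_test(counts, groups, pd.Series(1.0, index=cols))
        assert de.loc["g", "log2fc"] == 0.0
        assert de.loc["g", "pvalue"] == pytest.approx(1.0)

    def test_single_gene_matches_delta_method_oracle(self):
        cols = ["Tall1", "Tall2", "Tall3", "Dwarf1", "Dwarf2", "Dwarf3"]
        row = [12, 18, 15, 48, 60, 52]
        counts = pd.DataFrame([row], columns=cols, index=["g"])
        groups = pd.Series(["tall"] * 3 + ["dwarf"] * 3, index=cols)
        de = rnaseq.nb_wald_test(counts, groups, pd.Series(1.0, index=cols))
        # independent recomputation of the specified statistic
        t = np.array(row[:3], float)
        d = np.array(row[3:], float)
        mu_t, mu_d = t.mean(), d.mean()
        s2 = (((t - mu_t) ** 2).sum() + ((d - mu_d) ** 2).sum()) / 4
        mu_bar = (mu_t + mu_d) / 2
        alpha = max(0.0, (s2 - mu_bar) / mu_bar**2)
        lnfc = np.log((mu_d + 0.5) / (mu_t + 0.5))
        se = np.sqrt((1 / 3) * (1 / (mu_t + 0.5) + alpha) + (1 / 3) * (1 / (mu_d + 0.5) + alpha))
        z = lnfc / se
        p = 2 * stats.norm.sf(abs(z))
        assert de.loc["g", "wald_z"] == pytest.approx(z, abs=1e-12)
        assert de.loc["g", "pvalue"] == pytest.approx(p, abs=1e-12)
        assert de.loc["g", "log2fc"] == pytest.approx(lnfc / np.log(2), abs=1e-12)

    def test_all_zero_group_uses_pseudocount_path(self):
        cols = ["Tall1", "Tall2", "Tall3", "Dwarf1", "Dwarf2", "Dwarf3"]
        counts = pd.DataFrame([[0, 0, 0, 20, 25, 30]], columns=cols, index=["g"])
        groups = pd.Series(["tall"] * 3 + ["dwarf"] * 3, index=cols)
        de = rnaseq.nb_wald_test(counts, groups, pd.Series(1.0, index=cols))
        assert np.isfinite(de.loc["g", "wald_z"])
        assert de.loc["g", "log2fc"] > 4


class TestBhAdjust:
    def test_step_up_enumeration_example(self):
        np.testing.assert_allclose(rnaseq.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert rnaseq.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=40)
        padj = rnaseq.bh_adjust(p)
        assert (padj >= p).all() and (padj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()

    def test_matches_explicit_step_up(self, rng):
        p = rng.uniform(size=25)
        n = len(p)
        order = np.argsort(p)
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        want = np.empty(n)
        want[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(rnaseq.bh_adjust(p), want, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rnaseq.bh_adjust([0.5, 1.5])


class TestClassify:
    @pytest.fixture
    def de_and_fpkm(self):
        de = pd.DataFrame(
            {
                "log2fc": [1.5, 0.5, 3.0, -2.0],
                "pvalue": [1e-5, 1e-6, 1e-6, 1e-5],
            },
            index=["up_gene", "small_fc", "low_fpkm", "down_gene"],
        )
        fpkm = pd.DataFrame(
            {
                "s1": [2.0, 5.0, 0.4, 3.0],
                "s2": [4.0, 5.0, 9.0, 3.0],
            },
            index=de.index,
        )
        return de, fpkm

    def test_status_examples(self, de_and_fpkm):
        de, fpkm = de_and_fpkm
        out = rnaseq.classify_degs(de, fpkm)
        assert out.loc["up_gene", "status"] == "up"
        assert out.loc["small_fc", "status"] == "ns"
        assert out.loc["low_fpkm", "status"] == "filtered"
        assert out.loc["down_gene", "status"] == "down"

    def test_all_rule_keeps_partially_expressed_gene(self, de_and_fpkm):
        de, fpkm = de_and_fpkm
        out = rnaseq.classify_degs(de, fpkm, filter_rule="all")
        assert out.loc["low_fpkm", "status"] == "up"

    def test_statuses_partition_all_genes(self, counts_3v3):
        counts, groups = counts_3v3
        lengths = pd.Series(2000, index=counts.index)
        fpkm = rnaseq.compute_fpkm(counts, lengths, None)
        de = rnaseq.nb_wald_test(counts, groups)
        out = rnaseq.classify_degs(de, fpkm)
        assert out["status"].isin(["up", "down", "ns", "filtered"]).all()
        assert out["status"].value_counts().sum() == len(counts)

    def test_padj_never_below_p(self, counts_3v3):
        counts, groups = counts_3v3
        lengths = pd.Series(2000, index=counts.index)
        fpkm = rnaseq.compute_fpkm(counts, lengths, None)
        out = rnaseq.classify_degs(rnaseq.nb_wald_test(counts, groups), fpkm)
        tested = out["padj"].notna()
        assert (out.loc[tested, "padj"] >= out.loc[tested, "pvalue"] - 1e-12).all()


class TestKmeans:
    COLS = ["Tall1", "Tall2", "Tall3", "Dwarf1", "Dwarf2", "Dwarf3"]
    GROUPS = pd.Series(["tall"] * 3 + ["dwarf"] * 3, index=COLS)

    def _blobs(self):
        up = np.tile([-1, -1, -1, 1, 1, 1], (20, 1)) + 0.01 * np.arange(20)[:, None]
        down = -up
        return pd.DataFrame(
            np.vstack([up, down]),
            index=[f"g{i}" for i in range(40)],
            columns=self.COLS,
        )

    def test_two_separated_blobs_recovered_exactly(self):
        prof = self._blobs()
        out = rnaseq.kmeans_cluster(prof, self.GROUPS, k=2, seed=0)
        # cluster 1 = up in dwarf by the relabelling rule
        assert (out.iloc[:20]["cluster"] == 1).all()
        assert (out.iloc[20:]["cluster"] == 2).all()

    def test_sizes_sum_to_gene_count(self):
        prof = self._blobs()
        out = rnaseq.kmeans_cluster(prof, self.GROUPS, k=4, seed=3)
        assert out["cluster"].value_counts().sum() == 40

    def test_fixed_seed_deterministic(self):
        prof = self._blobs()
        a = rnaseq.kmeans_cluster(prof, self.GROUPS, k=3, seed=11)
        b = rnaseq.kmeans_cluster(prof, self.GROUPS, k=3, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_fewer_genes_than_k_rejected(self):
        prof = self._blobs().iloc[:4]
        with pytest.raises(ValueError):
            rnaseq.kmeans_cluster(prof, self.GROUPS, k=6, seed=0)


class TestQpcr:
    def test_ddct_examples(self):
        assert rnaseq.delta_delta_ct(20, 15, 22, 15) == pytest.approx(4.0)
        assert rnaseq.delta_delta_ct(20, 20, 20, 20) == pytest.approx(1.0)
        assert rnaseq.delta_delta_ct(21, 15, 20, 15) == pytest.approx(0.5)

    def test_concordance_identity_and_affine(self):
        x = np.array([1.0, -2.0, 0.5, 3.0])
        assert rnaseq.qpcr_concordance(x, x) == pytest.approx(1.0)
        assert rnaseq.qpcr_concordance(x, 2 * x + 1) == pytest.approx(1.0)

    def test_concordance_matches_covariance_formula(self, rng):
        a = rng.normal(size=12)
        b = 0.8 * a + rng.normal(scale=0.5, size=12)
        want = (np.cov(a, b, ddof=1)[0, 1] / (np.std(a, ddof=1) * np.std(b, ddof=1))) ** 2
        assert rnaseq.qpcr_concordance(a, b) == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rnaseq.qpcr_concordance([1, 1, 1], [1, 2, 3])
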
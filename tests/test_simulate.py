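"""Backcross simulator: meiosis, pedigree advance, bulks, assay generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkseg import simulate


def _pure_parent(genome, donor_first=True):
    """Individual with one all-recurrent and one all-donor haplotype."""
    return simulate.f1_hybrid(genome)


class TestMeiosis:
    def test_zero_recombination_returns_one_parental_haplotype(self):
        genome = simulate.GenomeModel(
            chrom_lengths={"chr1": 100_000},
            markers={"chr1": np.array([10_000, 10_001, 10_002], dtype=np.int64)},
            rate_cm_per_mb=0.0,
            causal=("chr1", 10_000),
        )
        f1 = simulate.f1_hybrid(genome)
        rng = np.random.default_rng(0)
        picks = []
        for _ in range(400):
            g = simulate.simulate_meiosis(f1, genome, rng)["chr1"]
            assert g.all() or not g.any()  # intact haplotype
            picks.append(bool(g[0]))
        # each parental haplotype chosen with probability ~1/2
        assert 0.4 < np.mean(picks) < 0.6

    def test_haldane_recombinant_fraction_at_50_cm(self, two_marker_genome, rng):
        f1 = simulate.f1_hybrid(two_marker_genome)
        n = 10_000
        rec = 0
        for _ in range(n):
            g = simulate.simulate_meiosis(f1, two_marker_genome, rng)["chr1"]
            rec += g[0] != g[1]
        expected = 0.5 * (1 - np.exp(-1.0))  # Haldane closed form for d = 50 cM
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec / n - expected) < 3 * se

    def test_unlinked_chromosomes_assort_independently(self, tiny_genome, rng):
        f1 = simulate.f1_hybrid(tiny_genome)
        a, b = [], []
        for _ in range(10_000):
            g = simulate.simulate_meiosis(f1, tiny_genome, rng)
            a.append(bool(g["chr1"][0]))
            b.append(bool(g["chr2"][0]))
        table = pd.crosstab(np.array(a), np.array(b))
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_mismatched_marker_map_raises(self, tiny_genome, two_marker_genome, rng):
        f1 = simulate.f1_hybrid(two_marker_genome)
        with pytest.raises((ValueError, KeyError)):
            simulate.simulate_meiosis(f1, tiny_genome, rng)


class TestBackcross:
    def test_carrier_selection_keeps_causal_segregating(self, tiny_genome, rng):
        pop = simulate.advance_backcross(
            simulate.f1_hybrid(tiny_genome),
            simulate.recurrent_parent(tiny_genome),
            8,
            tiny_genome,
            rng,
            select_carriers=True,
            n_offspring=2_000,
        )
        chrom, idx = tiny_genome.causal_index()
        het = np.mean([ind.haplotypes[chrom][:, idx].sum() == 1 for ind in pop])
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / 2_000)

    def test_unselected_heterozygosity_decays_as_half_power_n(self, tiny_genome, rng):
        n = 10_000
        pop = simulate.advance_backcross(
            simulate.f1_hybrid(tiny_genome),
            simulate.recurrent_parent(tiny_genome),
            8,
            tiny_genome,
            rng,
            select_carriers=False,
            n_offspring=n,
        )
        het = np.mean([ind.haplotypes["chr2"][:, 5].sum() == 1 for ind in pop])
        expected = 0.5**8
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(het - expected) < 3 * se

    def test_single_generation_is_half_heterozygous(self, tiny_genome, rng):
        pop = simulate.advance_backcross(
            simulate.f1_hybrid(tiny_genome),
            simulate.recurrent_parent(tiny_genome),
            1,
            tiny_genome,
            rng,
            select_carriers=False,
            n_offspring=4_000,
        )
        het = np.mean(
            [ind.haplotypes["chr1"][:, 3].sum() == 1 for ind in pop]
        )
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / 4_000)

    def test_invalid_generations_raises(self, tiny_genome, rng):
        with pytest.raises(ValueError):
            simulate.advance_backcross(
                simulate.f1_hybrid(tiny_genome),
                simulate.recurrent_parent(tiny_genome),
                0,
                tiny_genome,
                rng,
            )


class TestBulks:
    @pytest.fixture
    def population(self, tiny_genome, rng):
        return simulate.advance_backcross(
            simulate.f1_hybrid(tiny_genome),
            simulate.recurrent_parent(tiny_genome),
            8,
            tiny_genome,
            rng,
            select_carriers=True,
            n_offspring=500,
        )

    def test_dwarf_bulk_fixed_recurrent_at_causal(self, population, tiny_genome, rng):
        tall, dwarf = simulate.select_bulks(population, 36, 40, rng)
        chrom, idx = tiny_genome.causal_index()
        assert all(ind.haplotypes[chrom][:, idx].sum() == 0 for ind in dwarf)
        assert all(ind.haplotypes[chrom][:, idx].sum() == 1 for ind in tall)
        f_t = simulate.bulk_allele_frequency(tall, chrom)[idx]
        f_d = simulate.bulk_allele_frequency(dwarf, chrom)[idx]
        assert f_d == 1.0 and f_t == 0.5

    def test_insufficient_or_empty_bulk_raises(self, population, rng):
        with pytest.raises(ValueError):
            simulate.select_bulks(population, 5_000, 40, rng)
        with pytest.raises(ValueError):
            simulate.select_bulks(population, 0, 40, rng)


class TestBulkDepths:
    def test_pool_frequency_recovered_in_reads(self, rng):
        # bulk with 'M' frequency 0.7 at every one of 10,000 markers, depth ~50
        m = 10_000
        genome = simulate.GenomeModel(
            chrom_lengths={"c": m * 100 + 1},
            markers={"c": np.arange(100, m * 100 + 1, 100, dtype=np.int64)},
            rate_cm_per_mb=1.0,
            causal=("c", 100),
        )
        bulk = [
            simulate.Individual(
                {"c": np.vstack([np.full(m, i < 6), np.zeros(m, dtype=bool)])}, genome
            )
            for i in range(10)
        ]  # 6/20 donor haplotypes -> f_M = 0.7
        rec = simulate.simulate_bulk_depths(bulk, bulk, genome, 50, 50, rng)
        ok = ~rec["missing"]
        frac = rec.loc[ok, "M_tall"] / (rec.loc[ok, "M_tall"] + rec.loc[ok, "P_tall"])
        se = np.sqrt(0.7 * 0.3 / 50 / ok.sum())
        assert abs(frac.mean() - 0.7) < 3 * se

    def test_high_depth_limit_gives_half_delta_at_causal(self, tiny_genome, rng):
        pop = simulate.advance_backcross(
            simulate.f1_hybrid(tiny_genome),
            simulate.recurrent_parent(tiny_genome),
            8,
            tiny_genome,
            rng,
            select_carriers=True,
            n_offspring=500,
        )
        tall, dwarf = simulate.select_bulks(pop, 36, 40, rng)
        rec = simulate.simulate_bulk_depths(tall, dwarf, tiny_genome, 50_000, 50_000, rng)
        chrom, cpos = tiny_genome.causal
        row = rec[(rec["chrom"] == chrom) & (rec["pos"] == cpos)].iloc[0]
        idx_d = row["M_dwarf"] / (row["M_dwarf"] + row["P_dwarf"])
        idx_t = row["M_tall"] / (row["M_tall"] + row["P_tall"])
        assert idx_d == pytest.approx(1.0, abs=1e-3)
        assert idx_t == pytest.approx(0.5, abs=5e-3)
        assert idx_d - idx_t == pytest.approx(0.5, abs=6e-3)

    def test_zero_depth_rows_flagged_missing(self, tiny_genome, rng):
        pop = simulate.advance_backcross(
            simulate.f1_hybrid(tiny_genome),
            simulate.recurrent_parent(tiny_genome),
            2,
            tiny_genome,
            rng,
            select_carriers=True,
            n_offspring=100,
        )
        tall, dwarf = simulate.select_bulks(pop, 10, 10, rng)
        rec = simulate.simulate_bulk_depths(tall, dwarf, tiny_genome, 0.0, 30.0, rng)
        assert rec["missing"].all()


class TestCounts:
    def test_nb_moments_recovered_by_method_of_moments(self, rng):
        # var = mu + alpha mu^2 -> alpha = (var - mu) / mu^2
        alpha = 0.1
        mu = 200.0
        draws = simulate._nb_draw(np.full(2_000, mu), alpha, rng)
        m, v = draws.mean(), draws.var(ddof=1)
        assert abs((v - m) / m**2 - alpha) < 0.03

    def test_planted_fold_changes_shift_group_means(self, tiny_genome, rng):
        cfg = simulate.SimulationConfig(seed=0, lfc_min=2, lfc_max=2, nb_dispersion=0.0)
        genes = simulate.default_gene_models(tiny_genome, 400)
        counts, truth = simulate.simulate_counts(cfg, genes, ("chr1", 1, 600_000), rng)
        de = truth[truth["is_de"] & (truth["true_log2fc"] > 0)]["gene_id"]
        sub = counts.loc[de]
        ratio = sub[["Dwarf1", "Dwarf2", "Dwarf3"]].to_numpy().mean() / sub[
            ["Tall1", "Tall2", "Tall3"]
        ].to_numpy().mean()
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimulationConfig(seed=0, nb_dispersion=-1.0)

    def test_region_up_skew_planted(self, tiny_genome, rng):
        cfg = simulate.SimulationConfig(seed=0, de_fraction=0.5, up_fraction_region=1.0)
        genes = simulate.default_gene_models(tiny_genome, 600)
        _, truth = simulate.simulate_counts(cfg, genes, ("chr1", 1, 900_000), rng)
        reg = truth[truth["in_region"] & truth["is_de"]]
        assert (reg["true_log2fc"] > 0).all()


class TestHormonesQpcr:
    def test_noiseless_class_ratio_exact(self):
        cfg = simulate.SimulationConfig(seed=0, hormone_noise_sd=0.0)
        panel = simulate.simulate_hormones(cfg, np.random.default_rng(0))
        totals = panel.groupby(["class", "group"])["concentration"].sum()
        for cls, ratio in cfg.hormone_ratios.items():
            assert totals[cls, "dwarf"] / totals[cls, "tall"] == pytest.approx(ratio)

    def test_noiseless_ct_recovers_fold_change(self, rng):
        truth = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(15)],
                "is_de": True,
                "true_log2fc": np.linspace(-3, 3, 15),
                "in_region": False,
            }
        )
        ct = simulate.simulate_qpcr(truth, rng, n_genes=12, noise_sd=0.0)
        from bulkseg.rnaseq import qpcr_fold_changes

        fc = qpcr_fold_changes(ct)
        want = truth.set_index("gene_id")["true_log2fc"].reindex(fc.index)
        np.testing.assert_allclose(fc.to_numpy(), want.to_numpy(), atol=1e-12)


class TestReproducibility:
    def test_generators_bit_reproducible_for_fixed_seed(self, tiny_genome):
        def build(seed):
            rng = np.random.default_rng(seed)
            pop = simulate.advance_backcross(
                simulate.f1_hybrid(tiny_genome),
                simulate.recurrent_parent(tiny_genome),
                4,
                tiny_genome,
                rng,
                n_offspring=120,
            )
            t, d = simulate.select_bulks(pop, 10, 10, rng)
            return simulate.simulate_bulk_depths(t, d, tiny_genome, 30, 30, rng)

        pd.testing.assert_frame_equal(build(99), build(99))
        assert not build(99).equals(build(100))
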
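"""Generator statistics: determinism, structure, variance bookkeeping."""

import numpy as np
import pytest

from modscreen.relatedness import centered_grm
from modscreen.simulate import (
    ConfigurationError,
    SimConfig,
    simulate_cross_counts,
    simulate_gene_models,
    simulate_gene_sets,
    simulate_genotype_panel,
    simulate_phenotypes,
    simulate_rate_trees,
)


class TestConfig:
    def test_variance_partition_must_not_exceed_one(self):
        with pytest.raises(ConfigurationError):
            SimConfig(polygenic_var=0.7, noise_var=0.5)

    def test_maf_range_bounds(self):
        with pytest.raises(ConfigurationError):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ConfigurationError):
            SimConfig(maf_range=(0.1, 0.6))

    def test_too_many_causal(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_variants=10, n_causal=11)


class TestGenotypePanel:
    def test_seeded_determinism(self):
        cfg = SimConfig(n_strains=30, n_variants=100, seed=7)
        a = simulate_genotype_panel(cfg)
        b = simulate_genotype_panel(cfg)
        assert a.equals(b)

    def test_unstructured_grm_offdiag_mean_near_zero(self):
        cfg = SimConfig(n_strains=100, n_variants=5000, n_subpops=1, fst_like_drift=0.0, seed=1)
        panel = simulate_genotype_panel(cfg)
        K = centered_grm(panel).K
        off = K[~np.eye(len(K), dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_two_subpops_show_block_structure(self):
        cfg = SimConfig(n_strains=80, n_variants=2000, n_subpops=2, fst_like_drift=0.3, seed=2)
        panel = simulate_genotype_panel(cfg)
        K = centered_grm(panel).K
        sub = np.arange(80) % 2
        same = (sub[:, None] == sub[None, :]) & ~np.eye(80, dtype=bool)
        diff = sub[:, None] != sub[None, :]
        assert K[same].mean() > K[diff].mean()

    def test_genotypes_are_binary_and_maf_respected(self):
        cfg = SimConfig(n_strains=160, n_variants=3000, seed=3)
        panel = simulate_genotype_panel(cfg)
        assert set(np.unique(panel.genotypes)) <= {0.0, 1.0}
        assert np.mean(panel.maf() >= min(cfg.maf_range)) >= 0.95


class TestPhenotypes:
    def test_degenerate_config_gives_constant(self, medium_panel):
        cfg = SimConfig(n_strains=100, n_variants=2000, polygenic_var=0, noise_var=0, seed=5)
        res = simulate_phenotypes(medium_panel, cfg)
        assert np.allclose(res.y, cfg.mean_survival)

    def test_causal_variant_correlates_with_phenotype(self):
        cfg = SimConfig(
            n_strains=160, n_variants=2000, n_causal=1, causal_effects=[0.3],
            polygenic_var=0.0, noise_var=0.01, seed=6,
        )
        panel = simulate_genotype_panel(cfg)
        res = simulate_phenotypes(panel, cfg)
        x = panel.genotypes[:, res.causal_indices[0]]
        assert np.corrcoef(x, res.y)[0, 1] > 0.5

    def test_seeded_repeatability(self, medium_panel):
        cfg = SimConfig(n_strains=100, n_variants=2000, polygenic_var=0.3, noise_var=0.5, seed=8)
        a = simulate_phenotypes(medium_panel, cfg)
        b = simulate_phenotypes(medium_panel, cfg)
        assert np.array_equal(a.y, b.y)

    def test_variance_partition_bookkeeping(self):
        """Across seeds, var(g)/var(y) tracks the configured polygenic share."""
        ratios = []
        for seed in range(50):
            cfg = SimConfig(
                n_strains=150, n_variants=800, polygenic_var=0.6, noise_var=0.4, seed=seed,
            )
            panel = simulate_genotype_panel(cfg)
            res = simulate_phenotypes(panel, cfg)
            ratios.append(np.var(res.polygenic) / np.var(res.y))
        mean_ratio = np.mean(ratios)
        assert abs(mean_ratio - 0.6) / 0.6 < 0.2


class TestCrossCounts:
    def test_zero_survival_gives_zero_knockdown(self):
        t = simulate_cross_counts([0.0, 0.5], 100, seed=1)
        assert t.loc[0, "count_none"] == 0

    def test_full_survival_recovered_at_large_n(self):
        t = simulate_cross_counts([1.0], 10**6, seed=2)
        prop = t.loc[0, "count_none"] / max(t.loc[0, ["count_cyo", "count_sb", "count_double"]])
        assert abs(prop - 1.0) < 0.01

    def test_monte_carlo_mean_matches_binomial_expectation(self):
        """1000 draws at survival 0.25: mean recovered proportion within 3 SE."""
        rng = np.random.default_rng(3)
        n_exp, p_true, reps = 200, 0.25, 1000
        props = []
        for _ in range(reps):
            t = simulate_cross_counts([p_true], n_exp, rng=rng)
            props.append(t.loc[0, "count_none"] / n_exp)
        se = np.sqrt(p_true * (1 - p_true) / n_exp / reps)
        assert abs(np.mean(props) - p_true) < 3 * se

    def test_input_validation(self):
        with pytest.raises(ValueError):
            simulate_cross_counts([1.5], 100)
        with pytest.raises(ValueError):
            simulate_cross_counts([0.5], 0)


class TestGeneModelsAndSets:
    def test_deterministic_layout(self):
        cfg = SimConfig(n_genes=50, chrom_length=500_000, seed=9)
        a = simulate_gene_models(cfg)
        b = simulate_gene_models(cfg)
        assert a.genes == b.genes
        for g in a:
            assert g.start <= g.end
            for lo, hi in g.exons:
                assert g.start <= lo <= hi <= g.end

    def test_chromosome_too_small(self):
        with pytest.raises(ConfigurationError):
            simulate_gene_models(SimConfig(n_genes=1000, chrom_length=10_000))

    def test_causal_set_is_exactly_the_causal_genes(self):
        cfg = SimConfig(n_genes=50, chrom_length=500_000, n_gene_sets=5, seed=10)
        models = simulate_gene_models(cfg)
        sets = simulate_gene_sets(cfg, models, enriched_genes=["gene_0003", "gene_0007"])
        assert sets["set_causal"] == ["gene_0003", "gene_0007"]
        assert len(sets) == 5


class TestRateTrees:
    def test_zero_noise_group_correlates_perfectly(self):
        group = ["gene_0001", "gene_0004"]
        cfg = SimConfig(n_genes=10, covarying_group=group, rate_sd=0.0,
                        presence_prob=1.0, seed=11)
        trees = simulate_rate_trees(cfg)
        for clade in trees.clade_ids:
            a = np.log(trees.branch_lengths[clade][group[0]])
            b = np.log(trees.branch_lengths[clade][group[1]])
            assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_independent_pairs_uncorrelated_on_average(self):
        """Mean pairwise log-rate correlation over 500 null pairs near 0."""
        from modscreen.erc import relative_rates

        cfg = SimConfig(n_genes=40, covarying_group=[], presence_prob=1.0,
                        n_clades=1, seed=12)
        trees = simulate_rate_trees(cfg)
        clade = trees.clade_ids[0]
        mean = trees.clade_mean(clade)
        rng = np.random.default_rng(0)
        genes = sorted(trees.branch_lengths[clade])
        rr = {g: relative_rates(trees.branch_lengths[clade][g], mean) for g in genes}
        rs = []
        for _ in range(500):
            g1, g2 = rng.choice(genes, size=2, replace=False)
            rs.append(np.corrcoef(rr[g1], rr[g2])[0, 1])
        nb = trees.n_branches[clade]
        se = (1 / np.sqrt(nb - 3)) / np.sqrt(500)  # Fisher-z scale approximation
        assert abs(np.mean(rs)) < 3 * se + 0.05

    def test_absence_and_determinism(self):
        cfg = SimConfig(n_genes=30, presence_prob=0.7, seed=13)
        a = simulate_rate_trees(cfg)
        b = simulate_rate_trees(cfg)
        assert a.clade_ids == b.clade_ids
        for clade in a.clade_ids:
            assert set(a.branch_lengths[clade]) == set(b.branch_lengths[clade])
            for g in a.branch_lengths[clade]:
                assert np.array_equal(a.branch_lengths[clade][g], b.branch_lengths[clade][g])
        # every gene present somewhere
        assert len(a.genes()) == 30

    def test_unknown_group_member_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_rate_trees(SimConfig(n_genes=5, covarying_group=["gene_9999"]))
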
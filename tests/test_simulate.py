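import numpy as np
import pandas as pd
import pytest

from epilipid.simulate import (
    SimulationConfig,
    TrueEffect,
    gene_annotation_for_blocks,
    merge_discovery,
    simulate_cohorts,
    simulate_covariates,
    simulate_genotypes,
    simulate_knowledge_base,
    simulate_phenotypes,
    split_cohorts,
)


class TestConfigValidation:
    def test_block_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum to n_snps"):
            SimulationConfig(n_snps=5, ld_block_sizes=[2, 2])

    def test_r2_below_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(within_block_r2=1.0)

    def test_maf_range_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.01, 0.3))

    def test_interaction_requires_second_snp(self):
        with pytest.raises(ValueError, match="snp_b"):
            TrueEffect("snp0001", beta_interaction=0.5)


class TestGenotypes:
    def test_values_and_maf_range(self):
        config = SimulationConfig(
            n_cohorts=2, n_per_cohort=500, n_snps=10, ld_block_sizes=[5, 5],
            within_block_r2=0.3, maf_range=(0.1, 0.4), seed=1,
        )
        G = simulate_genotypes(config)
        vals = G.dosages[~np.isnan(G.dosages)]
        assert set(np.unique(vals)) <= {0.0, 1.0, 2.0}
        maf = G.maf()
        assert np.all(maf > 0.03) and np.all(maf < 0.5)

    def test_zero_r2_blocks_independent(self):
        config = SimulationConfig(
            n_cohorts=2, n_per_cohort=1000, n_snps=10, ld_block_sizes=[10],
            within_block_r2=0.0, maf_range=(0.2, 0.4), missing_rate=0.0,
            seed=2,
        )
        D = simulate_genotypes(config).dosages
        r2 = np.corrcoef(D.T) ** 2
        off = r2[np.triu_indices(10, 1)]
        assert off.mean() < 0.005  # ~1/n under independence

    def test_high_ld_block_hits_band(self):
        config = SimulationConfig(
            n_cohorts=2, n_per_cohort=2500, n_snps=10, ld_block_sizes=[10],
            within_block_r2=0.9, maf_range=(0.28, 0.32), missing_rate=0.0,
            seed=3,
        )
        D = simulate_genotypes(config).dosages
        adj = [np.corrcoef(D[:, i], D[:, i + 1])[0, 1] ** 2 for i in range(9)]
        assert 0.8 <= np.mean(adj) <= 0.95

    def test_cross_block_independence(self):
        config = SimulationConfig(
            n_cohorts=2, n_per_cohort=1500, n_snps=6, ld_block_sizes=[3, 3],
            within_block_r2=0.9, maf_range=(0.28, 0.32), missing_rate=0.0,
            seed=4,
        )
        D = simulate_genotypes(config).dosages
        cross = [
            np.corrcoef(D[:, i], D[:, j])[0, 1] ** 2
            for i in range(3)
            for j in range(3, 6)
        ]
        assert max(cross) < 0.01

    def test_ld_monotone_in_target(self):
        means = []
        for t in (0.0, 0.3, 0.6, 0.9):
            config = SimulationConfig(
                n_cohorts=2, n_per_cohort=2500, n_snps=8, ld_block_sizes=[8],
                within_block_r2=t, maf_range=(0.28, 0.32), missing_rate=0.0,
                seed=5,
            )
            D = simulate_genotypes(config).dosages
            means.append(
                np.mean(
                    [np.corrcoef(D[:, i], D[:, i + 1])[0, 1] ** 2 for i in range(7)]
                )
            )
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_determinism(self):
        config = SimulationConfig(seed=11)
        G1, G2 = simulate_genotypes(config), simulate_genotypes(config)
        assert G1.equals(G2)

    def test_missing_rate_approximate(self):
        config = SimulationConfig(
            n_cohorts=2, n_per_cohort=1000, missing_rate=0.05, seed=6
        )
        G = simulate_genotypes(config)
        frac = np.isnan(G.dosages).mean()
        assert frac == pytest.approx(0.05, abs=0.01)


class TestCovariates:
    def test_shape_and_columns(self):
        X = simulate_covariates(100, seed=1)
        assert X.shape == (100, 16)
        assert list(X.columns[:6]) == [
            "age", "sex", "smoking", "t2d", "medication", "bmi",
        ]

    def test_adult_age_floor(self):
        X = simulate_covariates(5000, seed=2)
        assert X["age"].min() >= 21

    def test_determinism_and_error(self):
        assert simulate_covariates(50, seed=3).equals(
            simulate_covariates(50, seed=3)
        )
        with pytest.raises(ValueError):
            simulate_covariates(0, seed=1)


class TestPhenotypes:
    def base_config(self, **kw):
        defaults = dict(
            n_cohorts=2, n_per_cohort=2500, n_snps=4,
            ld_block_sizes=[1, 1, 1, 1], within_block_r2=0.0,
            maf_range=(0.3, 0.3), missing_rate=0.0, seed=7,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def generate(self, config):
        G = simulate_genotypes(config)
        X = simulate_covariates(G.n_samples, config.seed + 1,
                                sample_ids=G.sample_ids)
        return G, X, simulate_phenotypes(G, X, config)

    def test_pure_noise_variance(self):
        config = self.base_config(noise_sd=1.0)
        _, _, P = self.generate(config)
        for col in ("hdl", "ldl", "log_tg"):
            assert P[col].var() == pytest.approx(1.0, rel=0.1)

    def test_friedewald_identity_holds_without_tc_noise(self):
        _, _, P = self.generate(self.base_config())
        lhs = P["tc"].to_numpy()
        rhs = (P["ldl"] + P["hdl"] + 0.45 * P["tg"]).to_numpy()
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_log_tg_is_linear_scale(self):
        _, _, P = self.generate(self.base_config())
        np.testing.assert_allclose(
            P["log_tg"], np.log(P["tg"]), atol=1e-12
        )

    def test_unknown_snp_in_effect_raises(self):
        config = self.base_config(
            true_models=[TrueEffect("rs-ghost", beta_main_a=0.3, trait="HDL")]
        )
        G = simulate_genotypes(config)
        X = simulate_covariates(G.n_samples, 1, sample_ids=G.sample_ids)
        with pytest.raises(ValueError, match="absent"):
            simulate_phenotypes(G, X, config)

    def test_determinism(self):
        config = self.base_config()
        _, _, P1 = self.generate(config)
        _, _, P2 = self.generate(config)
        assert P1.equals(P2)


class TestKnowledgeBase:
    @pytest.fixture
    def genes(self):
        return pd.DataFrame(
            {
                "chrom": "1",
                "start": [0, 100, 200, 300],
                "end": [50, 150, 250, 350],
                "gene": ["G1", "G2", "G3", "G4"],
            }
        )

    def test_zero_density_empty(self, genes):
        kb = simulate_knowledge_base(genes, n_sources=6, density=0.0, seed=1)
        assert len(kb) == 0

    def test_saturation(self, genes):
        kb = simulate_knowledge_base(genes, n_sources=6, density=1.0, seed=1)
        counts = kb.groupby(["gene1", "gene2"])["source"].nunique()
        assert len(counts) == 6 and (counts == 6).all()

    def test_threshold_exercisable(self, genes):
        kb = simulate_knowledge_base(genes, n_sources=6, density=0.5, seed=2)
        counts = kb.groupby(["gene1", "gene2"])["source"].nunique()
        assert (counts >= 5).any() or len(counts) < 6
        assert (counts < 5).any() or (counts >= 5).all()

    def test_determinism_and_errors(self, genes):
        a = simulate_knowledge_base(genes, 6, 0.5, seed=3)
        b = simulate_knowledge_base(genes, 6, 0.5, seed=3)
        assert a.equals(b)
        with pytest.raises(ValueError):
            simulate_knowledge_base(genes, 0, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate_knowledge_base(genes.iloc[:1], 6, 0.5, seed=1)


class TestCohortSplit:
    def full_data(self, config):
        G = simulate_genotypes(config)
        X = simulate_covariates(G.n_samples, 1, sample_ids=G.sample_ids)
        P = simulate_phenotypes(G, X, config)
        return G, X, P

    def test_partition_covers_and_disjoint(self):
        config = SimulationConfig(n_cohorts=3, n_per_cohort=100, seed=8)
        G, X, P = self.full_data(config)
        cohorts = split_cohorts(G, X, P, config)
        all_ids = [s for c in cohorts for s in c.sample_ids]
        assert sorted(all_ids) == sorted(G.sample_ids)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not set(cohorts[i].sample_ids) & set(cohorts[j].sample_ids)

    def test_oversized_partition_raises(self):
        config = SimulationConfig(n_cohorts=3, n_per_cohort=100, seed=8)
        G, X, P = self.full_data(config)
        big = SimulationConfig(n_cohorts=4, n_per_cohort=100, seed=8)
        with pytest.raises(ValueError, match="exceeds"):
            split_cohorts(G, X, P, big)

    def test_discovery_flagging_and_merge(self):
        config = SimulationConfig(
            n_cohorts=4, n_per_cohort=50, n_discovery_cohorts=2, seed=9
        )
        cohorts = simulate_cohorts(config)
        roles = [c.role for c in cohorts]
        assert roles == ["discovery", "discovery", "replication", "replication"]
        disc = merge_discovery(cohorts)
        assert disc.genotypes.n_samples == 100

    def test_gene_annotation_per_block(self):
        config = SimulationConfig(
            n_cohorts=2, n_per_cohort=50, n_snps=6, ld_block_sizes=[3, 3],
            seed=10,
        )
        G = simulate_genotypes(config)
        ann = gene_annotation_for_blocks(G)
        assert list(ann["gene"]) == ["GENE1", "GENE2"]
        assert (ann["start"] < ann["end"]).all()
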
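"""Synthetic-locus generator: determinism, association models, recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cismr.exceptions import ValidationError
from cismr.mr import bidirectional_mr
from cismr.simulate import (
    CohortData,
    SyntheticLocusConfig,
    cohort_sumstats,
    cross_pools,
    default_haplotype_pool,
    pool_allele_freq,
    pool_ld,
    random_haplotype_pool,
    recovery_experiment,
    simulate_cohort,
    standardized_mediation_effect,
)
from cismr.sumstats import harmonize


def small_config(**kw):
    defaults = dict(n_individuals=1000, seed=42)
    defaults.update(kw)
    return SyntheticLocusConfig(**defaults)


class TestConfig:
    def test_single_haplotype_pool_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            small_config(haplotype_pool=[("101", 1.0)])

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            small_config(haplotype_pool=[("1", 0.6), ("0", 0.6)])

    def test_causal_index_bounds_checked(self):
        with pytest.raises(ValidationError, match="causal_snp_index"):
            small_config(causal_snp_index=10)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(beta_gp=0.4, direct_bmd_effects={2: 0.1})
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert SyntheticLocusConfig.from_yaml(p) == cfg


class TestSimulateCohort:
    def test_deterministic_under_seed(self):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config())
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.protein, b.protein)
        assert np.array_equal(a.bmd, b.bmd)
        assert np.array_equal(a.fracture, b.fracture)

    def test_different_seed_differs(self):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config(seed=43))
        assert not np.array_equal(a.genotypes, b.genotypes)

    def test_allele_frequency_matches_pool(self):
        cfg = small_config(n_individuals=10_000)
        cohort = simulate_cohort(cfg)
        f_pool = pool_allele_freq(cfg.haplotype_pool, 0)
        f_hat = cohort.genotypes[:, 0].mean() / 2
        se = np.sqrt(f_pool * (1 - f_pool) / (2 * cfg.n_individuals))
        assert abs(f_hat - f_pool) < 3 * se

    def test_genotype_ld_matches_pool(self):
        cfg = small_config(n_individuals=20_000)
        cohort = simulate_cohort(cfg)
        expected_r2 = pool_ld(cfg.haplotype_pool, 0, 1).r2
        r = np.corrcoef(cohort.genotypes[:, 0], cohort.genotypes[:, 1])[0, 1]
        assert r**2 == pytest.approx(expected_r2, abs=0.03)
        # the independent third SNP stays near linkage equilibrium
        r_indep = np.corrcoef(cohort.genotypes[:, 0], cohort.genotypes[:, 2])[0, 1]
        assert abs(r_indep) < 0.03

    def test_traits_standardized(self):
        cohort = simulate_cohort(small_config(n_individuals=5000))
        for y in (cohort.protein, cohort.bmd):
            assert y.mean() == pytest.approx(0.0, abs=1e-12)
            assert y.std() == pytest.approx(1.0, abs=1e-12)
        assert set(np.unique(cohort.fracture)) <= {0, 1}

    def test_null_model_type_i_error(self):
        """With all effects zero, |z| > 3.29 for about 0.1% of SNP-trait
        pairs (continuous traits)."""
        exceed = total = 0
        for rep in range(100):
            cfg = small_config(
                n_individuals=500, beta_gp=0.0, beta_pb=0.0, beta_bf=0.0, seed=rep
            )
            cohort = simulate_cohort(cfg)
            for trait in ("protein", "bmd"):
                for r in cohort_sumstats(cohort, trait):
                    total += 1
                    exceed += abs(r.beta / r.se) > 3.29
        assert total == 600
        assert exceed <= 5  # expected ~0.6 under the null


class TestCohortSumstats:
    def test_perfect_association(self):
        g = np.tile([0, 1, 2], 400).astype(np.int8).reshape(-1, 1)
        y = (g[:, 0] - g[:, 0].mean()) / g[:, 0].std()
        cohort = CohortData(
            genotypes=g, protein=y, bmd=y, fracture=np.zeros(1200, dtype=np.int8),
            snp_ids=["snp0"],
        )
        (r,) = cohort_sumstats(cohort, "protein")
        assert r.beta == pytest.approx(1.0 / g[:, 0].std(), rel=1e-9)
        assert r.pval < 1e-200

    def test_monomorphic_snp_skipped_with_warning(self):
        pool = [("10", 0.5), ("11", 0.5)]
        cfg = small_config(haplotype_pool=pool, causal_snp_index=1)
        cohort = simulate_cohort(cfg)
        with pytest.warns(UserWarning, match="monomorphic"):
            out = cohort_sumstats(cohort, "protein")
        assert [r.snp_id for r in out] == ["snp1"]

    def test_logistic_matches_reference_ml_fit(self):
        """IRLS betas/SEs agree with an independently fitted GLM."""
        import statsmodels.api as sm

        # small hand-checkable dataset plus a simulated cohort
        g20 = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2, 1])
        y20 = np.array([0, 0, 1, 0, 0, 1, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 1])
        cohort = simulate_cohort(small_config(n_individuals=800, alpha0=-1.0))
        datasets = [(g20.astype(np.int8), y20)] + [
            (cohort.genotypes[:, j], cohort.fracture) for j in range(3)
        ]
        for g, y in datasets:
            c = CohortData(
                genotypes=g.reshape(-1, 1).astype(np.int8),
                protein=np.zeros(len(g)), bmd=np.zeros(len(g)),
                fracture=np.asarray(y, dtype=np.int8), snp_ids=["snp0"],
            )
            (r,) = cohort_sumstats(c, "fracture")
            X = sm.add_constant(g.astype(float))
            fit = sm.GLM(np.asarray(y, float), X, family=sm.families.Binomial()).fit()
            assert r.beta == pytest.approx(fit.params[1], abs=1e-6)
            assert r.se == pytest.approx(fit.bse[1], abs=1e-6)

    def test_permuted_trait_pvalues_uniform(self):
        """Permutation destroys the association; p-values become uniform."""
        rng = np.random.default_rng(11)
        cfg = small_config(
            n_individuals=400, haplotype_pool=[("1", 0.5), ("0", 0.5)],
            beta_gp=0.5, seed=3,
        )
        cohort = simulate_cohort(cfg)
        pvals = []
        for _ in range(250):
            perm = CohortData(
                genotypes=cohort.genotypes,
                protein=rng.permutation(cohort.protein),
                bmd=cohort.bmd, fracture=cohort.fracture, snp_ids=cohort.snp_ids,
            )
            (r,) = cohort_sumstats(perm, "protein")
            pvals.append(r.pval)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRecovery:
    def test_null_effect_recovered(self):
        cfg = small_config(n_individuals=2000, beta_pb=0.0, beta_gp=0.33, seed=9)
        rep = recovery_experiment(cfg, 200)
        assert rep.true_effect == 0.0
        mc_se = rep.estimates.std() / np.sqrt(rep.n_replicates)
        assert abs(rep.estimates.mean()) < 2 * mc_se + 1e-12

    def test_rmse_scales_with_sqrt_n(self):
        cfg = small_config(n_individuals=3000, beta_pb=0.3, beta_gp=0.33, seed=5)
        small = recovery_experiment(cfg, 150)
        big = recovery_experiment(
            dataclasses.replace(cfg, n_individuals=12_000), 150
        )
        # quadrupling n should halve the RMSE, up to Monte-Carlo noise
        assert 0.4 < big.rmse / small.rmse < 0.65

    def test_zero_instrument_effect_rejected(self):
        with pytest.raises(ValidationError, match="beta_gp"):
            recovery_experiment(small_config(beta_gp=0.0), 10)

    def test_analytic_standardized_effect(self):
        """The closed-form standardized effect is what large-sample MR at
        the causal SNP converges to."""
        cfg = small_config(n_individuals=50_000, beta_pb=0.3, beta_gp=0.32, seed=1)
        truth = standardized_mediation_effect(cfg)
        rep = recovery_experiment(cfg, 20)
        assert rep.true_effect == pytest.approx(truth)
        assert abs(rep.mean_bias) < 0.02


class TestBidirectional:
    def test_forward_effect_recovered_reverse_null(self):
        """Protein→BMD chain with no feedback: the forward IVW estimate
        tracks the generative effect and the reverse direction is null."""
        protein_block = [("11", 0.48), ("10", 0.02), ("01", 0.05), ("00", 0.45)]
        bmd_block = [("1", 0.4), ("0", 0.6)]
        pool = cross_pools(protein_block, bmd_block)  # SNP2 ⊥ SNP0/1
        cfg = SyntheticLocusConfig(
            n_individuals=6000, haplotype_pool=pool, causal_snp_index=0,
            beta_gp=0.33, beta_pb=0.3, direct_bmd_effects={2: 0.3}, seed=77,
        )
        truth = standardized_mediation_effect(cfg)
        fwd_estimates, rev_nonsig = [], 0
        n_rep = 60
        seeds = np.random.SeedSequence(123).generate_state(n_rep) & 0x7FFFFFFF
        for s in seeds:
            cohort = simulate_cohort(dataclasses.replace(cfg, seed=int(s)))
            prot = {r.snp_id: r for r in cohort_sumstats(cohort, "protein")}
            bmd = {r.snp_id: r for r in cohort_sumstats(cohort, "bmd")}
            fwd_pairs = [harmonize(prot["snp0"], bmd["snp0"])]
            rev_pairs = [harmonize(bmd["snp2"], prot["snp2"])]
            fwd, rev = bidirectional_mr(fwd_pairs, rev_pairs)
            fwd_estimates.append(fwd.beta_mr)
            rev_nonsig += rev.pval > 0.05
        assert np.mean(fwd_estimates) == pytest.approx(truth, abs=0.02)
        assert rev_nonsig >= 0.85 * n_rep
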
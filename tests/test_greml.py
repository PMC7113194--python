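"""REML likelihood, AI-REML fitting, LRT convention, chromosome partition."""

import warnings

import numpy as np
import pytest
from scipy import stats

from longreml.greml import (
    chromosome_length_correlation,
    fit_chromosomal,
    fit_greml,
    fit_null,
    lrt_pvalue,
    restricted_log_likelihood,
)
from longreml.grm import compute_grm, partition_by_chromosome
from longreml.simulate import SimulationConfig, simulate_genotypes, simulate_longitudinal_phenotypes


def sim_grm(n, m, seed):
    cfg = SimulationConfig(n_subjects=n, n_snps=m, seed=seed)
    return simulate_genotypes(cfg)


class TestRestrictedLikelihood:
    def test_zero_genetic_variance_matches_iid_closed_form(self, rng):
        n = 30
        y = rng.standard_normal(n) * 2.0 + 1.0
        X = np.ones((n, 1))
        A = compute_grm(sim_grm(n, 100, 1)).values
        s2 = 1.7
        ll = restricted_log_likelihood(y, X, [A], [0.0, s2])
        # closed-form REML of iid N(mu, s2):
        # -1/2 [n log s2 + log(n/s2) + RSS/s2]
        rss = float(((y - y.mean()) ** 2).sum())
        expected = -0.5 * (n * np.log(s2) + np.log(n / s2) + rss / s2)
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_fixed_effect_shifts(self, rng):
        n = 25
        A = compute_grm(sim_grm(n, 80, 2)).values
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        ll1 = restricted_log_likelihood(y, X, [A], [0.4, 0.8])
        ll2 = restricted_log_likelihood(y + X @ np.array([3.0, -1.5]), X, [A], [0.4, 0.8])
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_diagonal_grm_matches_eigenbasis_computation(self, rng):
        n = 20
        d = rng.uniform(0.5, 2.0, n)
        X = np.ones((n, 1))
        y = rng.standard_normal(n)
        sg, se = 0.7, 0.9
        ll = restricted_log_likelihood(y, X, [np.diag(d)], [sg, se])
        # independent weighted-model computation in the eigenbasis
        v = sg * d + se
        xtvx = float(np.sum(1.0 / v))
        beta = float(np.sum(y / v) / xtvx)
        ypy = float(np.sum((y - beta) ** 2 / v))
        expected = -0.5 * (np.sum(np.log(v)) + np.log(xtvx) + ypy)
        assert ll == pytest.approx(expected, abs=1e-8)


class TestLRT:
    def test_zero_statistic_has_half_mass(self):
        assert lrt_pvalue(10.0, 10.0) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "lrt,expected", [(3.841, 0.025), (2.706, 0.050)]
    )
    def test_mixture_tail(self, lrt, expected):
        p = lrt_pvalue(lrt / 2.0, 0.0)
        assert p == pytest.approx(expected, abs=5e-4)
        assert p == pytest.approx(0.5 * stats.chi2.sf(lrt, 1), rel=1e-12)

    def test_negative_statistic_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert lrt_pvalue(0.0, 1.0) == pytest.approx(0.5)


class TestFitGreml:
    def test_scale_equivariance(self):
        geno = sim_grm(120, 400, 3)
        cfg = SimulationConfig(n_subjects=120, n_snps=400, h2_B0=0.4, seed=3)
        _, truth = simulate_longitudinal_phenotypes(geno, cfg)
        A = compute_grm(geno).values
        X = np.ones((120, 1))
        f1 = fit_greml(truth.b0, X, [A])
        f2 = fit_greml(5.0 * truth.b0, X, [A])
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-6)
        assert f2.sigma2_g[0] == pytest.approx(25.0 * f1.sigma2_g[0], rel=1e-4)
        assert f2.sigma2_e == pytest.approx(25.0 * f1.sigma2_e, rel=1e-4)

    def test_null_simulations_give_small_mean_h2(self):
        A = compute_grm(sim_grm(300, 800, 4)).values
        X = np.ones((300, 1))
        rng = np.random.default_rng(40)
        h2s = []
        for _ in range(50):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                h2s.append(fit_greml(rng.standard_normal(300), X, [A]).h2)
        assert np.mean(h2s) < 0.05

    def test_identity_grm_reports_flat_likelihood(self, rng):
        y = rng.standard_normal(200)
        with pytest.warns(UserWarning, match="flat"):
            fit = fit_greml(y, np.ones((200, 1)), [np.eye(200)])
        assert fit.status == "flat"

    def test_misaligned_ids_rejected(self, rng):
        grm = compute_grm(sim_grm(20, 60, 5))
        y = rng.standard_normal(20)
        ids = list(grm.ids["iid"])[::-1]
        with pytest.raises(Exception, match="aligned"):
            fit_greml(y, np.ones((20, 1)), [grm], ids=ids)

    def test_null_fit_matches_ols_variance(self, rng):
        n = 60
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([1.0, 2.0]) + rng.standard_normal(n) * 1.5
        s2, ll = fit_null(y, X)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        assert s2 == pytest.approx(rss / (n - 2), rel=1e-10)
        assert ll == pytest.approx(restricted_log_likelihood(y, X, [], [s2]))


class TestChromosomal:
    def test_sum_of_fractions_is_one(self):
        geno = sim_grm(150, 440, 6)
        cfg = SimulationConfig(n_subjects=150, n_snps=440, h2_B0=0.5, seed=6)
        _, truth = simulate_longitudinal_phenotypes(geno, cfg)
        grms = partition_by_chromosome(geno)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_chromosomal(truth.b0, np.ones((150, 1)), grms)
        total = fit.h2_per_component.sum() + fit.sigma2_e / fit.total_variance
        assert total == pytest.approx(1.0, abs=1e-8)
        assert len(fit.sigma2_g) == 22

    def test_equal_architecture_h2_tracks_snp_count(self):
        # chromosomes with more SNPs should absorb more genetic variance
        cfg = SimulationConfig(n_subjects=300, n_snps=600, h2_B0=0.6, seed=7)
        geno = simulate_genotypes(cfg)
        # unequal blocks: chrom 1 gets half the SNPs
        chrom = np.ones(600, dtype=int)
        chrom[300:] = 1 + np.arange(300) % 21 + 1
        geno.snp_meta["chrom"] = chrom
        _, truth = simulate_longitudinal_phenotypes(geno, cfg)
        grms = partition_by_chromosome(geno)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_chromosomal(truth.b0, np.ones((300, 1)), grms)
        counts = np.array([g.m for g in grms], dtype=float)
        slope = np.polyfit(counts, fit.h2_per_component, 1)[0]
        assert slope > 0

    def test_separate_fits_assemble_per_component_table(self):
        geno = sim_grm(80, 120, 8)
        geno.snp_meta["chrom"] = 1 + np.arange(120) % 3
        cfg = SimulationConfig(n_subjects=80, n_snps=120, h2_B0=0.4, seed=8)
        _, truth = simulate_longitudinal_phenotypes(geno, cfg)
        grms = partition_by_chromosome(geno)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_chromosomal(truth.b0, np.ones((80, 1)), grms, joint=False)
        assert fit.status == "separate"
        assert len(fit.h2_per_component) == 3


class TestChromosomeLengthCorrelation:
    def test_proportional_gives_r_one(self):
        lengths = np.arange(1, 23, dtype=float)
        r, p = chromosome_length_correlation(0.01 * lengths, lengths)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_constant_h2_gives_nan_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = chromosome_length_correlation(np.full(22, 0.02), np.arange(1.0, 23.0))
        assert np.isnan(r) and np.isnan(p)

    def test_permutation_destroys_monotone_correlation(self, rng):
        lengths = np.arange(1, 23, dtype=float)
        h2c = 0.002 * lengths + rng.normal(0, 0.002, 22)
        r0, _ = chromosome_length_correlation(h2c, lengths)
        weaker = 0
        for _ in range(100):
            rp, _ = chromosome_length_correlation(rng.permutation(h2c), lengths)
            weaker += abs(rp) < abs(r0)
        assert weaker >= 90
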
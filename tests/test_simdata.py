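"""Tests for the pedigree/Balding-Nichols generator and trait calibration."""

import numpy as np
import pytest

from brass import simdata
from brass.simdata import (
    PedigreeConfig,
    TraitModelSpec,
    ascertain_sample,
    calibrate_trait_model,
    default_three_generation_pedigree,
    gene_drop_pedigrees,
    simulate_covariates,
    simulate_subpop_frequencies,
    simulate_trait,
)


class TestPedigreeConfig:
    def test_default_pedigree_shape(self):
        ped = default_three_generation_pedigree()
        assert ped.n_members == 16
        assert ped.n_generations == 3
        assert len(ped.founders) == 8
        for i, pr in enumerate(ped.parents):
            if pr is not None:
                assert len(pr) == 2 and pr[0] < i and pr[1] < i

    def test_invalid_parent_order_rejected(self):
        with pytest.raises(ValueError):
            PedigreeConfig(parents=(None, (0, 2), None))


class TestSubpopFrequencies:
    def test_moments_match_balding_nichols(self):
        """At ancestral p = .5: mean p, variance p(1-p)F (Beta oracle)."""
        rng = np.random.default_rng(50)
        f = simulate_subpop_frequencies(
            100_000, 0.01, rng=rng, ancestral_range=(0.5, 0.5))
        assert abs(f.mean() - 0.5) < 0.001
        assert abs(f.var() - 0.25 * 0.01) < 0.0002

    def test_low_fst_limit_tracks_ancestral(self):
        rng = np.random.default_rng(51)
        f = simulate_subpop_frequencies(
            10_000, 1e-6, rng=rng, ancestral_range=(0.5, 0.5))
        assert np.max(np.abs(f - 0.5)) < 1e-2

    def test_invalid_fst(self):
        with pytest.raises(ValueError):
            simulate_subpop_frequencies(10, 0.0)


class TestGeneDrop:
    def test_mendelian_certainty_at_fixed_markers(self):
        """Frequency 1 (or 0) forces genotype 2 (or 0) down the pedigree."""
        ped = default_three_generation_pedigree()
        freqs = np.tile([[1.0, 0.0]], (2, 1))
        geno, _, _ = gene_drop_pedigrees(freqs, ped, 4, seed=1)
        assert np.all(geno[:, 0] == 2)
        assert np.all(geno[:, 1] == 0)

    def test_mendelian_consistency_everywhere(self):
        """Child dosage is bounded by what the parents can transmit."""
        rng = np.random.default_rng(52)
        ped = default_three_generation_pedigree()
        freqs = simulate_subpop_frequencies(300, 0.01, rng=rng)
        geno, _, pedlab = gene_drop_pedigrees(freqs, ped, 20, rng=rng)
        nm = ped.n_members
        for p in range(20):
            block = geno[p * nm:(p + 1) * nm]
            for i, parents in enumerate(ped.parents):
                if parents is None:
                    continue
                fa, mo = block[parents[0]], block[parents[1]]
                child = block[i]
                lower = (fa == 2).astype(int) + (mo == 2).astype(int)
                upper = (fa > 0).astype(int) + (mo > 0).astype(int)
                assert np.all(child >= lower) and np.all(child <= upper)

    def test_sibling_genotype_correlation_near_half(self):
        """Full sibs share half their genome: genotype correlation ~ 0.5."""
        rng = np.random.default_rng(53)
        ped = PedigreeConfig(parents=(None, None, (0, 1), (0, 1)))
        freqs = simulate_subpop_frequencies(
            1, 1e-6, rng=rng, ancestral_range=(0.5, 0.5))
        geno, _, _ = gene_drop_pedigrees(freqs, ped, 20_000, rng=rng)
        sib1 = geno[2::4, 0]
        sib2 = geno[3::4, 0]
        corr = np.corrcoef(sib1, sib2)[0, 1]
        assert abs(corr - 0.5) < 0.03

    def test_fst_recovered_from_markers(self):
        """Hudson-style FST across many markers is close to the F used."""
        rng = np.random.default_rng(54)
        ped = PedigreeConfig(parents=(None,))
        freqs = simulate_subpop_frequencies(2000, 0.01, rng=rng)
        geno, subpop, _ = gene_drop_pedigrees(freqs, ped, 400, rng=rng)
        p1 = geno[subpop == 0].mean(axis=0) / 2
        p2 = geno[subpop == 1].mean(axis=0) / 2
        n_per = 200
        num = (p1 - p2) ** 2 - (p1 * (1 - p1) + p2 * (1 - p2)) / (n_per - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = num.sum() / den.sum()
        assert abs(fst - 0.01) < 0.004

    def test_odd_pedigree_count_rejected(self):
        freqs = np.full((2, 5), 0.5)
        with pytest.raises(ValueError, match="evenly"):
            gene_drop_pedigrees(freqs, default_three_generation_pedigree(), 3)


class TestCovariates:
    def test_moments(self):
        cov = simulate_covariates(100_000, seed=55)
        assert abs(cov["sex"].mean() - 0.5) < 0.01
        assert abs(cov["normal"].var() - 1.0) < 0.02
        assert abs(cov["age"].mean()) < 0.01
        assert abs(cov["age"].var() - 1.0) < 0.02


class TestCalibration:
    def test_scenario_b_targets(self):
        """Low-prevalence scenario: 5% prevalence, 55% Bernoulli-error share."""
        spec = calibrate_trait_model(
            model="logistic", covariate_fraction=0.4, prevalence=0.05,
            error_share=0.55, wald_sample_size=1000, n_mc=60_000, seed=56)
        # independent evaluation draw
        rng = np.random.default_rng(57)
        n = 100_000
        cov = simulate_covariates(n, rng=rng)
        from scipy.special import expit
        eta = (spec.intercept
               + cov[["age", "sex", "normal"]].to_numpy() @ spec.beta_vector
               + rng.normal(0, np.sqrt(spec.sigma_a_sq), n))
        p = expit(eta)
        prev = p.mean()
        share = np.mean(p * (1 - p)) / (prev * (1 - prev))
        assert abs(prev - 0.05) < 0.005
        assert abs(share - 0.55) < 0.03

    def test_liability_calibration(self):
        spec = calibrate_trait_model(
            model="liability", covariate_fraction=0.6, prevalence=0.30,
            error_share=0.20, wald_sample_size=1000, n_mc=60_000, seed=58)
        assert spec.sigma_e_sq == 1.0
        rng = np.random.default_rng(59)
        n = 100_000
        cov = simulate_covariates(n, rng=rng)
        eta = (spec.intercept
               + cov[["age", "sex", "normal"]].to_numpy() @ spec.beta_vector
               + rng.normal(0, np.sqrt(spec.sigma_a_sq), n))
        y = (eta + rng.standard_normal(n) > 0)
        assert abs(y.mean() - 0.30) < 0.01

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(ValueError):
            calibrate_trait_model(covariate_fraction=1.5)


class TestSimulateTrait:
    def _spec(self, model="logistic", intercept=0.0, sigma_a=0.0, sigma_e=1.0):
        return TraitModelSpec(
            model=model, intercept=intercept, betas=(0.0, 0.0, 0.0),
            sigma_a_sq=sigma_a, sigma_e_sq=None if model == "logistic" else sigma_e,
            covariate_fraction=0.5, prevalence_target=0.5, error_share_target=0.2)

    def test_logistic_intercept_only_prevalence(self):
        rng = np.random.default_rng(60)
        n = 40_000
        geno = rng.binomial(2, 0.5, (n, 5)).astype(float)
        cov = simulate_covariates(n, rng=rng)
        b0 = 0.8473
        spec = self._spec(intercept=b0)
        y = simulate_trait(spec, geno, cov, rng=rng)
        from scipy.special import expit
        assert abs(y.mean() - expit(b0)) < 0.01

    def test_liability_symmetric_threshold(self):
        rng = np.random.default_rng(61)
        n = 40_000
        geno = rng.binomial(2, 0.5, (n, 5)).astype(float)
        cov = simulate_covariates(n, rng=rng)
        spec = self._spec(model="liability")
        y = simulate_trait(spec, geno, cov, rng=rng)
        assert abs(y.mean() - 0.5) < 0.01

    def test_sibling_trait_correlation_monotone_in_polygenic_variance(self):
        rng = np.random.default_rng(62)
        ped = simdata.PedigreeConfig(parents=(None, None, (0, 1), (0, 1)))
        freqs = simulate_subpop_frequencies(80, 0.01, rng=rng)
        geno, _, _ = gene_drop_pedigrees(freqs, ped, 6000, rng=rng)
        cov = simulate_covariates(geno.shape[0], rng=rng)
        corrs = []
        for sa in (0.0, 2.0, 8.0):
            spec = self._spec(sigma_a=sa)
            y = simulate_trait(spec, geno, cov, rng=rng)
            corrs.append(np.corrcoef(y[2::4], y[3::4])[0, 1])
        assert corrs[0] < corrs[1] < corrs[2]

    def test_null_markers_uncorrelated_with_trait(self):
        """Markers outside the causal set show no systematic trait correlation."""
        rng = np.random.default_rng(63)
        ped = default_three_generation_pedigree()
        freqs = simulate_subpop_frequencies(120, 0.01, rng=rng)
        cors = []
        for _ in range(50):
            geno, _, _ = gene_drop_pedigrees(freqs, ped, 6, rng=rng)
            cov = simulate_covariates(geno.shape[0], rng=rng)
            spec = self._spec(sigma_a=2.0)
            y = simulate_trait(spec, geno[:, :100], cov, rng=rng)
            if y.std() == 0:
                continue
            null = geno[:, 100:]
            cors.extend(np.corrcoef(y, g)[0, 1] for g in null.T)
        mean_abs = np.mean(cors)
        assert abs(mean_abs) < 3.0 / np.sqrt(len(cors) * geno.shape[0])


class TestAscertainment:
    @pytest.mark.parametrize("ratio, expected", [((1, 1), (500, 500)),
                                                 ((3, 7), (300, 700))])
    def test_exact_counts(self, ratio, expected):
        rng = np.random.default_rng(64)
        y = (rng.random(5000) < 0.4).astype(float)
        idx = ascertain_sample(y, ratio, 1000, rng=rng)
        assert idx.size == 1000
        assert int(y[idx].sum()) == expected[0]
        assert int((1 - y[idx]).sum()) == expected[1]

    def test_insufficient_cases_raises(self):
        y = np.concatenate([np.ones(400), np.zeros(600)])
        with pytest.raises(ValueError, match="cases"):
            ascertain_sample(y, (1, 1), 1000, seed=1)
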
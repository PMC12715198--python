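"""Direct+indirect genetic effects: covariance, fits, mixture LRT, permutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sgekit as sk
from sgekit.sge import _fit_dge_cage_only

from conftest import reml_loglik_contrasts


class TestMarginalCovariance:
    def test_no_cagemates_reduces_to_heritability_model(self, tiny_population):
        _, _, _, design, A = tiny_population
        n = design.n_individuals
        Z0 = np.zeros((n, n))
        params = {
            "sigma2_AD": 0.3, "sigma2_AS": 0.2, "sigma_ADS": 0.1,
            "sigma2_ED": 0.4, "sigma2_ES": 0.3, "sigma_EDS": 0.2,
            "sigma2_C": 0.25, "sigma2_M": 0.15,
        }
        V = sk.marginal_covariance(params, A, Z0, design.W, design.W_mother)
        expect = (
            0.3 * A.A + 0.4 * np.eye(n)
            + 0.25 * design.W @ design.W.T
            + 0.15 * design.W_mother @ design.W_mother.T
        )
        np.testing.assert_allclose(V, expect, atol=1e-12)

    def test_pure_direct_environment_gives_identity(self, tiny_population):
        _, _, _, design, A = tiny_population
        V = sk.marginal_covariance(
            {"sigma2_ED": 1.0}, np.eye(design.n_individuals), design.Z,
            design.W, design.W_mother,
        )
        np.testing.assert_allclose(V, np.eye(design.n_individuals), atol=1e-12)

    def test_asymmetric_z_rejected(self, tiny_population):
        _, _, _, design, A = tiny_population
        Zbad = design.Z.copy()
        Zbad[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            sk.marginal_covariance({"sigma2_ED": 1.0}, A, Zbad, design.W,
                                   design.W_mother)

    def test_matches_monte_carlo_covariance(self, tiny_population):
        """V equals the empirical covariance of simulated phenotypes
        (n = 20, 5000 draws, entrywise within 4 Monte-Carlo s.e.)."""
        _, _, _, design, A = tiny_population
        truth = sk.SimTruth(
            n_families=10, offspring_per_family=2, n_snps=600, cage_size=2,
            var_dge=0.5, var_ige=0.3, cor_dge_ige=0.6,
            var_env_direct=0.4, var_env_indirect=0.2, cor_env=-0.5,
            var_cage=0.3, var_maternal=0.2, seed=3,
        )
        params = {
            "sigma2_AD": 0.5, "sigma2_AS": 0.3,
            "sigma_ADS": 0.6 * np.sqrt(0.5 * 0.3),
            "sigma2_ED": 0.4, "sigma2_ES": 0.2,
            "sigma_EDS": -0.5 * np.sqrt(0.4 * 0.2),
            "sigma2_C": 0.3, "sigma2_M": 0.2,
        }
        V = sk.marginal_covariance(params, A, design.Z, design.W, design.W_mother)
        draws = np.array([
            sk.simulate_phenotype(truth, A, design, seed=10_000 + r)[0]
            for r in range(5000)
        ])
        emp = np.cov(draws, rowvar=False)
        se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V**2) / draws.shape[0])
        assert np.all(np.abs(emp - V) < 4 * se + 1e-8)


class TestFitSGE:
    def test_full_likelihood_matches_dense_oracle(self, tiny_population):
        """REML optimum agrees with an orthonormal-contrast evaluation of
        the restricted likelihood at the fitted parameters (n = 40)."""
        truth = sk.SimTruth(
            n_families=20, offspring_per_family=2, n_snps=800, cage_size=2, seed=13
        )
        G, ped = sk.simulate_genotypes(truth)
        design = sk.make_design(ped, cage_size=2, cohousing=False, seed=13)
        A = sk.compute_grm(G)
        y, _ = sk.simulate_phenotype(truth, A, design)
        from sgekit.varcomp import build_fixed_effects

        for model in ("full", "null"):
            fit = sk.fit_sge(y, A, design, model, n_restarts=2, seed=1,
                             compute_se=False)
            V = sk.marginal_covariance(
                fit.params, A, design.Z, design.W, design.W_mother
            )
            X = build_fixed_effects(design)
            oracle = reml_loglik_contrasts(y, X, V)
            assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_null_likelihood_never_exceeds_full(self, small_truth, small_population):
        _, _, design, A = small_population
        for s in range(3):
            y, _ = sk.simulate_phenotype(small_truth, A, design, seed=60 + s)
            lam, full, null = sk.sge_lrt(y, A, design, n_restarts=2, seed=s)
            assert full.loglik >= null.loglik - 1e-6
            assert lam >= 0.0

    def test_cage_size_two_confounding_note(self, tiny_population):
        truth, _, _, design, A = tiny_population
        y, _ = sk.simulate_phenotype(truth, A, design, seed=5)
        fit = sk.fit_sge(y, A, design, "full", n_restarts=1, compute_se=False)
        assert any("size 2" in note for note in fit.notes)

    def test_singletons_flagged_and_retained(self, tiny_population):
        truth, _, _, design, A = tiny_population
        Z = design.Z.copy()
        Z[0, :] = 0.0
        Z[:, 0] = 0.0
        lonely = design.with_Z(Z)
        y, _ = sk.simulate_phenotype(truth, A, design, seed=6)
        fit = sk.fit_sge(y, A, lonely, "null", n_restarts=1, compute_se=False)
        assert any("no cage mates" in note for note in fit.notes)


class TestMixtureLRT:
    def test_chi2_reference_quantiles(self):
        assert sk.mixture_lrt_pvalue(3.841, 0.0) == pytest.approx(0.05, abs=5e-4)
        assert sk.mixture_lrt_pvalue(5.991, 1.0) == pytest.approx(0.05, abs=5e-4)
        assert sk.mixture_lrt_pvalue(0.0, 0.3) == 1.0
        assert sk.mixture_lrt_pvalue(-2.0, 0.5) == 1.0  # clamped

    def test_invalid_mixture_weight_rejected(self):
        with pytest.raises(ValueError):
            sk.mixture_lrt_pvalue(1.0, 1.2)

    @given(
        lam=st.floats(0.0, 50.0),
        dlam=st.floats(0.0, 5.0),
        m=st.floats(0.0, 1.0),
        dm=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_statistic_and_weight(self, lam, dlam, m, dm):
        """p decreases as the statistic grows and increases with the weight
        on the heavier chi2(2) tail (for lam in the crossover region the
        chi2(2) tail is larger)."""
        if m + dm > 1:
            dm = 1 - m
        p1 = sk.mixture_lrt_pvalue(lam, m)
        p2 = sk.mixture_lrt_pvalue(lam + dlam, m)
        assert p2 <= p1 + 1e-12
        # chi2(2) survival exceeds chi2(1) survival for lam > ~0; mixture
        # p is monotone non-decreasing in m
        p3 = sk.mixture_lrt_pvalue(lam, m + dm)
        assert p3 >= p1 - 1e-12

    def test_calibrate_selects_pure_components(self):
        rng = np.random.default_rng(17)
        lam1 = stats.chi2.rvs(1, size=4000, random_state=rng)
        lam2 = stats.chi2.rvs(2, size=4000, random_state=rng)
        assert sk.calibrate_mixture(lam1).m == 0.0
        assert sk.calibrate_mixture(lam2).m == 1.0

    def test_calibrate_selects_half_for_even_mixture(self):
        rng = np.random.default_rng(18)
        pick = rng.random(6000) < 0.5
        lam = np.where(
            pick,
            stats.chi2.rvs(1, size=6000, random_state=rng),
            stats.chi2.rvs(2, size=6000, random_state=rng),
        )
        assert abs(sk.calibrate_mixture(lam).m - 0.5) <= 0.1


class TestTotalGeneticVariance:
    def test_hand_arithmetic_from_printed_parameters(self):
        # sigma_ADS = 0.9 * sqrt(0.4 * 0.2); n = 3 cage mates
        s_ads = 0.9 * np.sqrt(0.08)
        params = {"sigma2_AD": 0.4, "sigma2_AS": 0.2, "sigma_ADS": s_ads}
        expect = 0.4 + 2 * 2 * s_ads + 4 * 0.2
        got = sk.total_genetic_variance(params, n_bar=3)
        assert got == expect  # exact arithmetic, no tolerance
        assert got == pytest.approx(2.2182, abs=5e-4)

    def test_degenerate_cases_exact(self):
        params = {"sigma2_AD": 0.37, "sigma2_AS": 0.5, "sigma_ADS": -0.2}
        assert sk.total_genetic_variance(params, n_bar=1) == 0.37
        no_ige = {"sigma2_AD": 0.37, "sigma2_AS": 0.0, "sigma_ADS": 0.0}
        assert sk.total_genetic_variance(no_ige, n_bar=4) == 0.37

    @given(
        s_ad=st.floats(0, 2), s_as=st.floats(0, 2),
        rho=st.floats(-1, 1), n=st.floats(1, 6),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_exact_polynomial_identity(self, s_ad, s_as, rho, n):
        s_ads = rho * np.sqrt(s_ad * s_as)
        got = sk.total_genetic_variance(
            {"sigma2_AD": s_ad, "sigma2_AS": s_as, "sigma_ADS": s_ads}, n_bar=n
        )
        assert got == s_ad + 2 * (n - 1) * s_ads + (n - 1) ** 2 * s_as

    def test_invalid_cage_size_rejected(self):
        with pytest.raises(ValueError, match="cage size"):
            sk.total_genetic_variance({"sigma2_AD": 1.0}, n_bar=0.5)


class TestPermuteCagemates:
    def test_w_untouched_and_rowsum_multiset_preserved(self, small_population):
        _, _, design, _ = small_population
        W_before = design.W.copy()
        perm = sk.permute_cagemates(design, seed=5)
        np.testing.assert_array_equal(perm.W, W_before)
        assert sorted(perm.Z.sum(axis=1)) == sorted(design.Z.sum(axis=1))
        assert np.allclose(perm.Z, perm.Z.T)
        assert np.all(np.diag(perm.Z) == 0)

    def test_determinism_and_variation(self, small_population):
        _, _, design, _ = small_population
        p1 = sk.permute_cagemates(design, seed=9)
        p2 = sk.permute_cagemates(design, seed=9)
        p3 = sk.permute_cagemates(design, seed=10)
        np.testing.assert_array_equal(p1.Z, p2.Z)
        assert not np.array_equal(p1.Z, p3.Z)


class TestDGEBiasExperiment:
    def test_null_truth_models_agree(self):
        """With zero indirect effects and zero correlation the full and the
        no-IGE model estimate the same direct variance on average, up to
        Monte-Carlo error plus a small boundary allowance (the constraint
        sigma2_AS >= 0 keeps its estimate slightly positive under the null,
        depressing the full model's direct estimate by a few hundredths at
        this sample size)."""
        truth = sk.SimTruth(
            n_families=100, offspring_per_family=3, n_snps=2000,
            var_dge=0.4, var_ige=0.0, cor_dge_ige=0.0,
            var_cage=0.2, var_env_direct=0.4, seed=79,
        )
        G, ped = sk.simulate_genotypes(truth)
        design = sk.make_design(ped, cage_size=3, cohousing=False, seed=79)
        A = sk.compute_grm(G)
        df = sk.dge_bias_experiment(truth, 15, A, design, seed=79, n_restarts=1)
        d = df["full_sigma2_AD"] - df["noige_sigma2_AD"]
        se = d.std() / np.sqrt(len(d))
        assert abs(d.mean()) < 3 * se + 0.06

    def test_negative_correlation_flips_bias(self, small_population):
        """With direct and indirect effects negatively correlated, ignoring
        the social term overestimates the direct variance."""
        _, _, design, A = small_population
        truth = sk.SimTruth(
            n_families=40, offspring_per_family=3, n_snps=1500,
            var_dge=0.4, var_ige=0.2, cor_dge_ige=-0.9,
            var_cage=0.2, var_env_direct=0.4, seed=78,
        )
        df = sk.dge_bias_experiment(truth, 12, A, design, seed=78, n_restarts=1)
        assert df["noige_sigma2_AD"].mean() > df["full_sigma2_AD"].mean()
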
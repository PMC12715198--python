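"""Heritability model fits, LRTs, genetic correlations and BH FDR."""

import numpy as np
import pytest
from scipy import stats

import sgekit as sk
from sgekit.reml import VarianceTerm, reml_fit, restricted_loglik

from conftest import reml_loglik_contrasts


@pytest.fixture(scope="module")
def mid_population():
    truth = sk.SimTruth(
        n_families=70, offspring_per_family=3, n_snps=2500, cage_size=3, seed=21
    )
    G, ped = sk.simulate_genotypes(truth)
    design = sk.make_design(ped, cage_size=3, cohousing=False, seed=21)
    A = sk.compute_grm(G)
    return truth, design, A


class TestREMLEngine:
    def test_optimum_matches_contrast_likelihood_oracle(self, tiny_population):
        """The fitted restricted likelihood equals an independent dense
        evaluation through orthonormal error contrasts (n = 40)."""
        rng = np.random.default_rng(0)
        n = 40
        # random PSD kernel plus identity
        B = rng.normal(size=(n, n))
        K1 = B @ B.T / n
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        terms = [VarianceTerm("k1", K1), VarianceTerm("noise", np.eye(n))]
        V_true = 0.7 * K1 + 0.5 * np.eye(n)
        y = np.linalg.cholesky(V_true) @ rng.normal(size=n)
        res = reml_fit(y, X, terms, n_restarts=3, seed=1)
        V_hat = res.params["k1"] * K1 + res.params["noise"] * np.eye(n)
        oracle = reml_loglik_contrasts(y, X, V_hat)
        assert res.loglik == pytest.approx(oracle, abs=1e-6)
        # and the package's own evaluator agrees with the fit
        assert restricted_loglik(y, X, res.params, terms) == pytest.approx(
            res.loglik, abs=1e-6
        )

    def test_invariant_to_individual_reordering(self, tiny_population):
        truth, _, _, design, A = tiny_population
        y, _ = sk.simulate_phenotype(truth, A, design, seed=5)
        fit = sk.fit_model1(y, A, design, n_restarts=2)
        perm = np.random.default_rng(3).permutation(y.size)
        design_p = sk.StudyDesign(
            design.W[perm], design.W_mother[perm], design.Z[np.ix_(perm, perm)],
            design.cage_size[perm],
        )
        A_p = sk.KinshipMatrix(A.A[np.ix_(perm, perm)])
        fit_p = sk.fit_model1(y[perm], A_p, design_p, n_restarts=2)
        assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-4)
        assert fit_p.sigma2_A == pytest.approx(fit.sigma2_A, abs=1e-3)

    def test_nested_model_never_beats_full(self, tiny_population):
        truth, _, _, design, A = tiny_population
        for s in range(3):
            y, _ = sk.simulate_phenotype(truth, A, design, seed=40 + s)
            full = sk.fit_model1(y, A, design, n_restarts=2)
            red = sk.fit_model1(y, A, design, include_genetic=False, n_restarts=2)
            assert full.loglik >= red.loglik - 1e-6


class TestFitModel1:
    def test_parameter_recovery(self, mid_population):
        """Mean REML estimates across replicates recover the generating
        variances (sigma2_A, sigma2_C, sigma2_M, sigma2_E) = (.3,.2,.1,.4)."""
        _, design, A = mid_population
        truth = sk.SimTruth(
            n_families=70, offspring_per_family=3, n_snps=2500,
            var_dge=0.3, var_ige=0.0, cor_dge_ige=0.0,
            var_cage=0.2, var_maternal=0.1, var_env_direct=0.4, seed=22,
        )
        est = []
        for r in range(25):
            y, _ = sk.simulate_phenotype(truth, A, design, seed=300 + r)
            f = sk.fit_model1(y, A, design, n_restarts=2, seed=r)
            est.append([f.sigma2_A, f.sigma2_C, f.sigma2_M, f.sigma2_E])
        mean = np.array(est).mean(axis=0)
        np.testing.assert_allclose(mean, [0.3, 0.2, 0.1, 0.4], atol=0.08)

    def test_pure_noise_heritability_near_zero(self):
        """Mean boundary estimate of h2 under a pure-noise model stays
        small once n is large enough to pin the genetic variance."""
        truth = sk.SimTruth(
            n_families=200, offspring_per_family=3, n_snps=2000,
            var_dge=0.0, var_ige=0.0, cor_dge_ige=0.0, var_cage=0.0,
            var_maternal=0.0, var_env_direct=1.0, seed=23,
        )
        G, ped = sk.simulate_genotypes(truth)
        design = sk.make_design(ped, cage_size=3, cohousing=False, seed=23)
        A = sk.compute_grm(G)
        h2 = []
        for r in range(50):
            y, _ = sk.simulate_phenotype(truth, A, design, seed=500 + r)
            h2.append(sk.fit_model1(y, A, design, n_restarts=1, seed=r).h2)
        assert np.mean(h2) <= 0.05

    def test_requires_multiple_cages_and_mothers(self, tiny_population):
        truth, _, ped, design, A = tiny_population
        one_cage = sk.StudyDesign(
            np.ones((design.n_individuals, 1)), design.W_mother,
            np.zeros_like(design.Z), design.cage_size,
        )
        y = np.random.default_rng(0).normal(size=design.n_individuals)
        with pytest.raises(ValueError, match="cages"):
            sk.fit_model1(y, A, one_cage)


class TestHeritabilityLRT:
    def test_chi2_reference_values(self, tiny_population):
        truth, _, _, design, A = tiny_population

        def fake(ll, has_gen):
            return sk.VarCompFit(0.1, 0.1, 0.1, 0.7, np.zeros(1), ll, True, has_gen)

        assert sk.heritability_lrt(fake(-10.0, True), fake(-10.0, False)) == 1.0
        p = sk.heritability_lrt(fake(-10.0 + 3.841 / 2, True), fake(-10.0, False))
        assert p == pytest.approx(0.05, abs=5e-4)
        # clamped when the boundary makes the reduced fit win numerically
        assert sk.heritability_lrt(fake(-10.001, True), fake(-10.0, False)) == 1.0

    def test_non_nested_rejected(self):
        fit = sk.VarCompFit(0.1, 0.1, 0.1, 0.7, np.zeros(1), -1.0, True, True)
        with pytest.raises(ValueError):
            sk.heritability_lrt(fit, fit)

    def test_null_pvalues_uniform_or_conservative(self, mid_population):
        """Boundary 1-dof LRT: under the null, P(p <= a) <= a roughly."""
        _, design, A = mid_population
        truth = sk.SimTruth(
            n_families=70, offspring_per_family=3, n_snps=2500,
            var_dge=0.0, var_ige=0.0, cor_dge_ige=0.0, var_cage=0.15,
            var_maternal=0.0, var_env_direct=0.85, seed=24,
        )
        pvals = []
        for r in range(40):
            y, _ = sk.simulate_phenotype(truth, A, design, seed=700 + r)
            full = sk.fit_model1(y, A, design, n_restarts=1, seed=r)
            red = sk.fit_model1(
                y, A, design, include_genetic=False, n_restarts=1, seed=r
            )
            pvals.append(sk.heritability_lrt(full, red))
        pvals = np.array(pvals)
        # conservative or uniform: no excess of small p-values
        assert (pvals <= 0.05).mean() <= 0.15
        assert np.median(pvals) > 0.25


class TestBivariateGencor:
    @pytest.fixture(scope="class")
    def two_cohorts(self):
        # families split across two cohorts so genetic covariance flows
        # through cross-cohort relatedness
        truth = sk.SimTruth(
            n_families=60, offspring_per_family=4, n_snps=2000, seed=31
        )
        G, ped = sk.simulate_genotypes(truth)
        A = sk.compute_grm(G)
        # alternate sibs between cohorts
        idx1 = np.flatnonzero(ped.index % 4 < 2)
        idx2 = np.flatnonzero(ped.index % 4 >= 2)
        d1 = sk.make_design(ped.iloc[idx1].reset_index(drop=True), 2, False, seed=1)
        d2 = sk.make_design(ped.iloc[idx2].reset_index(drop=True), 2, False, seed=2)
        order = np.concatenate([idx1, idx2])
        A_joint = sk.KinshipMatrix(A.A[np.ix_(order, order)])
        return truth, A, A_joint, idx1, idx2, d1, d2

    def _simulate_pair(self, two_cohorts, r_g, seed):
        truth, A, A_joint, idx1, idx2, d1, d2 = two_cohorts
        n = A.n_individuals
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(A.A + 1e-8 * np.eye(n))
        g = L @ rng.normal(size=(n, 2))
        g2 = r_g * g[:, 0] + np.sqrt(1 - r_g**2) * g[:, 1]
        h2 = 0.6
        y1 = np.sqrt(h2) * g[idx1, 0] + np.sqrt(1 - h2) * rng.normal(size=idx1.size)
        y2 = np.sqrt(h2) * g2[idx2] + np.sqrt(1 - h2) * rng.normal(size=idx2.size)
        return y1, y2

    def test_duplicated_trait_recovers_unit_correlation(self, two_cohorts):
        truth, A, A_joint, idx1, idx2, d1, d2 = two_cohorts
        y1, y2 = self._simulate_pair(two_cohorts, r_g=1.0, seed=8)
        fit = sk.fit_bivariate_gencor(y1, y2, A_joint, d1, d2, n_restarts=2)
        se = fit.r_G_se if np.isfinite(fit.r_G_se) else 0.15
        assert fit.r_G > 1.0 - 2 * max(se, 0.1)

    def test_moderate_correlation_recovery(self, two_cohorts):
        truth, A, A_joint, idx1, idx2, d1, d2 = two_cohorts
        ests = [
            sk.fit_bivariate_gencor(
                *self._simulate_pair(two_cohorts, r_g=0.5, seed=100 + s),
                A_joint, d1, d2, n_restarts=2, seed=s,
            ).r_G
            for s in range(8)
        ]
        assert abs(np.mean(ests) - 0.5) < 0.2

    def test_zero_correlation_lrt_not_anticonservative(self, two_cohorts):
        truth, A, A_joint, idx1, idx2, d1, d2 = two_cohorts
        ps = [
            sk.fit_bivariate_gencor(
                *self._simulate_pair(two_cohorts, r_g=0.0, seed=200 + s),
                A_joint, d1, d2, n_restarts=1, seed=s,
            ).p_gencor
            for s in range(10)
        ]
        assert np.median(ps) > 0.1

    def test_too_few_individuals_rejected(self, two_cohorts):
        truth, A, A_joint, idx1, idx2, d1, d2 = two_cohorts
        with pytest.raises(ValueError, match="at least 2"):
            sk.fit_bivariate_gencor(np.zeros(1), np.zeros(5), A_joint, d1, d2)


class TestBHFDR:
    def test_step_up_worked_example(self):
        # BH at q=0.1 on (0.001, 0.02, 0.03, 0.5): thresholds i*q/m =
        # (0.025, 0.05, 0.075, 0.1); largest i with p_(i) <= thr is 3
        sig = sk.bh_fdr(np.array([0.001, 0.02, 0.03, 0.5]), q=0.1)
        np.testing.assert_array_equal(sig, [True, True, True, False])

    def test_degenerate_inputs(self):
        assert not sk.bh_fdr(np.ones(6), q=0.1).any()
        assert sk.bh_fdr(np.zeros(6), q=0.1).all()
        with pytest.raises(ValueError):
            sk.bh_fdr(np.array([1.5]))

    def test_matches_manual_step_up_on_random_inputs(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50) ** 2
        q = 0.1
        order = np.argsort(p)
        passed = np.flatnonzero(p[order] <= (np.arange(1, 51) * q / 50))
        manual = np.zeros(50, dtype=bool)
        if passed.size:
            manual[order[: passed.max() + 1]] = True
        np.testing.assert_array_equal(sk.bh_fdr(p, q), manual)
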
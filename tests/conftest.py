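import numpy as np
import pytest

import sgekit as sk


@pytest.fixture(scope="session")
def small_truth():
    """Desk-size population: 40 families of 3 sibs, cages of 3, no co-housing."""
    return sk.SimTruth(
        n_families=40,
        offspring_per_family=3,
        n_snps=1500,
        cage_size=3,
        cohousing=False,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_population(small_truth):
    G, ped = sk.simulate_genotypes(small_truth)
    design = sk.make_design(ped, cage_size=3, cohousing=False, seed=small_truth.seed)
    A = sk.compute_grm(G)
    return G, ped, design, A


@pytest.fixture(scope="session")
def tiny_population():
    """20 individuals for brute-force covariance/likelihood oracles."""
    truth = sk.SimTruth(
        n_families=10, offspring_per_family=2, n_snps=600, cage_size=2, seed=3
    )
    G, ped = sk.simulate_genotypes(truth)
    design = sk.make_design(ped, cage_size=2, cohousing=False, seed=3)
    A = sk.compute_grm(G)
    return truth, G, ped, design, A


def reml_loglik_contrasts(y, X, V):
    """Independent restricted-likelihood oracle.

    Evaluates the Gaussian log-density of K'y where K is an orthonormal
    basis of the null space of X' — the definition of the restricted
    likelihood, computed through scipy's multivariate normal rather than
    the package's Harville-form evaluation.
    """
    from scipy.linalg import null_space
    from scipy.stats import multivariate_normal

    X2 = np.atleast_2d(X)
    if X2.shape[0] != len(y):
        X2 = X2.T
    K = null_space(X2.T)
    return float(
        multivariate_normal(mean=np.zeros(K.shape[1]), cov=K.T @ V @ K).logpdf(K.T @ y)
    )
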
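"""Heritability model: direct genetic + cage + maternal + noise.

Fits, by REML, the mixed model

    y = X b + a + e + W c + W' m,
    a ~ N(0, sigma2_A * A),  c ~ N(0, sigma2_C * I),
    m ~ N(0, sigma2_M * I),  e ~ N(0, sigma2_E * I)

where A is the GRM, W the cage incidence and W' the maternal incidence.
SNP heritability is sigma2_A over the sum of all four variances; its
significance comes from a 1-dof likelihood-ratio test against the model
without the genetic term. A bivariate extension estimates the genetic
correlation of one trait measured in two cohorts, transmitting the
covariance through the cross-cohort block of the joint GRM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import KinshipMatrix, StudyDesign
from .reml import CovarianceTerm, REMLResult, VarianceTerm, reml_fit

__all__ = [
    "VarCompFit",
    "BivariateFit",
    "fit_model1",
    "heritability_lrt",
    "fit_bivariate_gencor",
    "bh_fdr",
]


@dataclass
class VarCompFit:
    """REML estimates of the four-variance heritability model."""

    sigma2_A: float
    sigma2_C: float
    sigma2_M: float
    sigma2_E: float
    beta: np.ndarray
    loglik: float
    converged: bool
    has_genetic: bool = True
    reml: REMLResult | None = field(default=None, repr=False)

    @property
    def h2(self) -> float:
        total = self.sigma2_A + self.sigma2_C + self.sigma2_M + self.sigma2_E
        return self.sigma2_A / total if total > 0 else 0.0


def build_fixed_effects(
    design: StudyDesign, extra_covariates: np.ndarray | None = None
) -> np.ndarray:
    """Intercept plus the cage-size covariate (dropped when constant)."""
    n = design.n_individuals
    cols = [np.ones(n)]
    if np.ptp(design.cage_size) > 0:
        cols.append(design.cage_size.astype(float))
    if extra_covariates is not None:
        extra = np.atleast_2d(np.asarray(extra_covariates, float))
        if extra.shape[0] != n:
            extra = extra.T
        cols.extend(extra.T)
    return np.column_stack(cols)


def fit_model1(
    y: np.ndarray,
    A: KinshipMatrix,
    design: StudyDesign,
    include_genetic: bool = True,
    extra_covariates: np.ndarray | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    start: dict[str, float] | None = None,
) -> VarCompFit:
    """REML fit of the heritability model (or its no-genetics reduction)."""
    y = np.asarray(y, float).ravel()
    n = y.size
    W, Wm = design.W, design.W_mother
    if W.shape[1] < 2 or Wm.shape[1] < 2:
        raise ValueError("need at least 2 cages and 2 mothers")
    X = build_fixed_effects(design, extra_covariates)

    terms = []
    if include_genetic:
        terms.append(VarianceTerm("sigma2_A", A.A))
    terms += [
        VarianceTerm("sigma2_C", W @ W.T),
        VarianceTerm("sigma2_M", Wm @ Wm.T),
        VarianceTerm("sigma2_E", np.eye(n)),
    ]
    res = reml_fit(
        y, X, terms, n_restarts=n_restarts, seed=seed, start=start, compute_se=False
    )
    return VarCompFit(
        sigma2_A=res.params.get("sigma2_A", 0.0),
        sigma2_C=res.params["sigma2_C"],
        sigma2_M=res.params["sigma2_M"],
        sigma2_E=res.params["sigma2_E"],
        beta=res.beta,
        loglik=res.loglik,
        converged=res.converged,
        has_genetic=include_genetic,
        reml=res,
    )


def heritability_lrt(full: VarCompFit, reduced: VarCompFit) -> float:
    """1-dof LRT p-value for sigma2_A = 0.

    The statistic is clamped at zero (the boundary optimum can make the
    reduced likelihood numerically exceed the full one).
    """
    if not full.has_genetic or reduced.has_genetic:
        raise ValueError("expected a full fit with genetics and a reduced fit without")
    lam = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return float(stats.chi2.sf(lam, df=1))


@dataclass
class BivariateFit:
    """Bivariate REML fit for one trait measured in two cohorts."""

    params1: dict[str, float]
    params2: dict[str, float]
    gen_cov: float
    r_G: float
    r_G_se: float
    loglik: float
    loglik_r0: float
    p_gencor: float
    converged: bool


def fit_bivariate_gencor(
    y1: np.ndarray,
    y2: np.ndarray,
    A_joint: KinshipMatrix,
    design1: StudyDesign,
    design2: StudyDesign,
    n_restarts: int = 3,
    seed: int = 0,
) -> BivariateFit:
    """Genetic correlation between two cohorts measuring the same trait.

    ``A_joint`` covers the concatenation (cohort-1 individuals first); the
    genetic covariance travels through its cross-cohort block, while
    residual, cage and maternal covariances across cohorts are fixed to
    zero (the cohorts are disjoint sets of animals). Significance of the
    correlation is a 1-dof LRT against the fit constrained at r_G = 0.
    """
    y1 = np.asarray(y1, float).ravel()
    y2 = np.asarray(y2, float).ravel()
    n1, n2 = y1.size, y2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 individuals per trait")
    n = n1 + n2
    if A_joint.n_individuals != n:
        raise ValueError("A_joint must cover the concatenated individuals")

    y = np.concatenate([y1, y2])
    X1 = build_fixed_effects(design1)
    X2 = build_fixed_effects(design2)
    X = np.zeros((n, X1.shape[1] + X2.shape[1]))
    X[:n1, : X1.shape[1]] = X1
    X[n1:, X1.shape[1]:] = X2

    def block(M11=None, M22=None, M12=None):
        K = np.zeros((n, n))
        if M11 is not None:
            K[:n1, :n1] = M11
        if M22 is not None:
            K[n1:, n1:] = M22
        if M12 is not None:
            K[:n1, n1:] = M12
            K[n1:, :n1] = M12.T
        return K

    A = A_joint.A
    terms = [
        VarianceTerm("g1", block(M11=A[:n1, :n1])),
        VarianceTerm("g2", block(M22=A[n1:, n1:])),
        VarianceTerm("c1", block(M11=design1.W @ design1.W.T)),
        VarianceTerm("c2", block(M22=design2.W @ design2.W.T)),
        VarianceTerm("m1", block(M11=design1.W_mother @ design1.W_mother.T)),
        VarianceTerm("m2", block(M22=design2.W_mother @ design2.W_mother.T)),
        VarianceTerm("e1", block(M11=np.eye(n1))),
        VarianceTerm("e2", block(M22=np.eye(n2))),
    ]
    cov_terms = [CovarianceTerm("g12", block(M12=A[:n1, n1:]), pair=("g1", "g2"))]

    full = reml_fit(y, X, terms, cov_terms, n_restarts=n_restarts, seed=seed)
    null = reml_fit(
        y, X, terms, n_restarts=n_restarts, seed=seed, start=full.params, compute_se=False
    )
    lam = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(lam, df=1))

    r_G = full.correlations["g12"]
    return BivariateFit(
        params1={k: full.params[k] for k in ("g1", "c1", "m1", "e1")},
        params2={k: full.params[k] for k in ("g2", "c2", "m2", "e2")},
        gen_cov=full.params["g12"],
        r_G=r_G,
        r_G_se=full.correlation_se("g12"),
        loglik=full.loglik,
        loglik_r0=null.loglik,
        p_gencor=p,
        converged=full.converged,
    )


def bh_fdr(pvalues: np.ndarray, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up; boolean mask of discoveries at level q."""
    p = np.asarray(pvalues, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
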
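"""Direct + indirect (social) genetic effects on group-housed phenotypes.

An individual's phenotype is modelled as the sum of its own genetic and
environmental effects and of effects contributed by its cage mates:

    y = X b + a_D + Z a_S + e_D + Z e_S + W c + W' m

where Z is the symmetric, zero-diagonal cage-mate indicator. The direct
and indirect genetic effects (a_D, a_S) share the GRM kernel A and are
correlated (parameter sigma_ADS); the environmental pair (e_D, e_S) is
analogous with an identity kernel. The marginal phenotypic covariance is

    V = s2_AD A + s_ADS (AZ + ZA) + s2_AS Z A Z
        + s2_ED I + 2 s_EDS Z + s2_ES Z Z
        + s2_C W W' + s2_M W' W''.

Significance of the indirect genetic terms uses a likelihood-ratio test
against the reduction without Z a_S. Because the tested variance sits on
a boundary and its covariance parameter vanishes with it, the statistic
follows a mixture of chi2(1) and chi2(2); the mixture weight is chosen by
parametric bootstrap so that null p-values are uniform.

The total heritable variance, combining genetic variance in acquiring and
in transmitting the phenotype across a cage of average size n, is

    sigma2_H = s2_AD + 2 (n - 1) s_ADS + (n - 1)^2 s2_AS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import KinshipMatrix, StudyDesign
from .reml import CovarianceTerm, REMLResult, VarianceTerm, reml_fit
from .sim import SimTruth, simulate_phenotype
from .varcomp import build_fixed_effects

__all__ = [
    "SGEFit",
    "MixtureCalibration",
    "marginal_covariance",
    "fit_sge",
    "sge_lrt",
    "mixture_lrt_pvalue",
    "calibrate_mixture",
    "calibrate_from_bootstrap",
    "total_genetic_variance",
    "permute_cagemates",
    "dge_bias_experiment",
]

PARAM_NAMES = (
    "sigma2_AD",
    "sigma2_AS",
    "sigma_ADS",
    "sigma2_ED",
    "sigma2_ES",
    "sigma_EDS",
    "sigma2_C",
    "sigma2_M",
)


@dataclass
class SGEFit:
    """REML estimates of the direct+indirect genetic effects model."""

    params: dict[str, float]
    r_A: float
    r_A_se: float
    r_E: float
    beta: np.ndarray
    loglik: float
    converged: bool
    model: str  # "full" or "null"
    n_bar: float
    notes: list[str] = field(default_factory=list)
    reml: REMLResult | None = field(default=None, repr=False)

    @property
    def sigma2_H(self) -> float:
        """Total heritable variance at the design's average cage size."""
        return total_genetic_variance(self.params, self.n_bar)

    def __getattr__(self, name: str) -> float:
        if name in PARAM_NAMES:
            return self.params.get(name, 0.0)
        raise AttributeError(name)


def marginal_covariance(
    params: dict[str, float],
    A: np.ndarray | KinshipMatrix,
    Z: np.ndarray,
    W: np.ndarray,
    W_mother: np.ndarray,
) -> np.ndarray:
    """Phenotypic covariance implied by the model parameters.

    Accepts any subset of the eight parameters (missing ones are zero).
    """
    A = A.A if isinstance(A, KinshipMatrix) else np.asarray(A, float)
    Z = np.asarray(Z, float)
    if not np.allclose(Z, Z.T):
        raise ValueError("cage-mate matrix Z must be symmetric")
    if np.any(np.diag(Z) != 0):
        raise ValueError("cage-mate matrix Z must have a zero diagonal")
    if not np.allclose(A, A.T):
        raise ValueError("kinship matrix A must be symmetric")
    n = A.shape[0]
    g = {k: params.get(k, 0.0) for k in PARAM_NAMES}
    AZ = A @ Z
    V = (
        g["sigma2_AD"] * A
        + g["sigma_ADS"] * (AZ + AZ.T)
        + g["sigma2_AS"] * (Z @ A @ Z)
        + g["sigma2_ED"] * np.eye(n)
        + 2.0 * g["sigma_EDS"] * Z
        + g["sigma2_ES"] * (Z @ Z)
        + g["sigma2_C"] * (W @ W.T)
        + g["sigma2_M"] * (W_mother @ W_mother.T)
    )
    return 0.5 * (V + V.T)


def _sge_terms(
    A: np.ndarray,
    design: StudyDesign,
    model: str,
    indirect_env: bool = True,
    maternal: bool = True,
):
    n = A.shape[0]
    Z, W, Wm = design.Z, design.W, design.W_mother
    AZ = A @ Z
    terms = [
        VarianceTerm("sigma2_AD", A),
        VarianceTerm("sigma2_ED", np.eye(n)),
        VarianceTerm("sigma2_C", W @ W.T),
    ]
    cov_terms = []
    if indirect_env:
        terms.insert(2, VarianceTerm("sigma2_ES", Z @ Z))
        cov_terms.append(
            CovarianceTerm(
                "sigma_EDS", 2.0 * Z, pair=("sigma2_ED", "sigma2_ES"), free=True
            )
        )
    if maternal:
        terms.append(VarianceTerm("sigma2_M", Wm @ Wm.T))
    if model == "full":
        terms.insert(1, VarianceTerm("sigma2_AS", Z @ A @ Z))
        # free covariance: the hard |r| <= 1 bound biases the paired
        # variances when the true correlation is near 1; validity of the
        # marginal covariance is enforced at evaluation instead
        cov_terms.insert(
            0,
            CovarianceTerm(
                "sigma_ADS", AZ + AZ.T, pair=("sigma2_AD", "sigma2_AS"), free=True
            ),
        )
    elif model != "null":
        raise ValueError("model must be 'full' or 'null'")
    return terms, cov_terms


def fit_sge(
    y: np.ndarray,
    A: KinshipMatrix,
    design: StudyDesign,
    model: str = "full",
    extra_covariates: np.ndarray | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    start: dict[str, float] | None = None,
    compute_se: bool = True,
    indirect_env: bool = True,
    maternal: bool = True,
) -> SGEFit:
    """REML fit of the full (8-parameter) or indirect-genetics-free null model.

    The null model drops Z a_S (sigma2_AS = sigma_ADS = 0) but keeps the
    indirect environmental effects Z e_S. ``indirect_env=False`` and
    ``maternal=False`` drop the corresponding terms entirely — used for
    simulation analyses whose generating model has no such effects, where
    retaining the boundary-constrained components only adds noise (and on
    constant-cage-size designs they are collinear with the identity and
    cage kernels anyway). Individuals housed alone (zero rows of Z) are
    retained and flagged in the fit notes. When every cage has size 2,
    Z Z = I and W W' = I + Z, so the indirect environmental variance is
    statistically confounded with the direct one and the cage term; a
    note records this rather than reparametrizing.
    """
    y = np.asarray(y, float).ravel()
    notes: list[str] = []
    singletons = int(np.sum(design.Z.sum(axis=1) == 0))
    if singletons:
        notes.append(f"{singletons} individuals have no cage mates (Z row of zeros)")
    cage_counts = design.W.sum(axis=0)
    if np.all(cage_counts[cage_counts > 0] == 2):
        notes.append(
            "all cages have size 2: Z*Z = I and W*W' = I + Z, so indirect "
            "environmental variance is confounded with direct environmental "
            "and cage variance"
        )

    X = build_fixed_effects(design, extra_covariates)
    terms, cov_terms = _sge_terms(A.A, design, model, indirect_env, maternal)
    res = reml_fit(
        y,
        X,
        terms,
        cov_terms,
        n_restarts=n_restarts,
        seed=seed,
        start=start,
        compute_se=compute_se and model == "full",
    )
    params = {k: res.params.get(k, 0.0) for k in PARAM_NAMES}
    # the free-covariance fit can push the ratio past 1; report the
    # correlation on its natural range
    r_A = float(np.clip(res.correlations.get("sigma_ADS", 0.0), -1.0, 1.0))
    r_E = float(np.clip(res.correlations.get("sigma_EDS", 0.0), -1.0, 1.0))
    r_A_se = res.correlation_se("sigma_ADS") if model == "full" else float("nan")
    return SGEFit(
        params=params,
        r_A=r_A,
        r_A_se=r_A_se,
        r_E=r_E,
        beta=res.beta,
        loglik=res.loglik,
        converged=res.converged,
        model=model,
        n_bar=design.mean_cage_size,
        notes=notes,
        reml=res,
    )


def sge_lrt(
    y: np.ndarray,
    A: KinshipMatrix,
    design: StudyDesign,
    extra_covariates: np.ndarray | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    start_full: dict[str, float] | None = None,
    start_null: dict[str, float] | None = None,
) -> tuple[float, SGEFit, SGEFit]:
    """Likelihood-ratio statistic for the indirect genetic terms (clamped at 0)."""
    full = fit_sge(
        y, A, design, "full", extra_covariates, n_restarts, seed, start_full,
        compute_se=False,
    )
    null = fit_sge(
        y, A, design, "null", extra_covariates, n_restarts, seed, start_null,
        compute_se=False,
    )
    lam = max(0.0, 2.0 * (full.loglik - null.loglik))
    return lam, full, null


def mixture_lrt_pvalue(lam: float | np.ndarray, m: float) -> float | np.ndarray:
    """P-value of the chi2(1)/chi2(2) mixture LRT.

    ``m`` is the weight on the 2-dof component: m = 0 recovers the plain
    1-dof test (ignoring the covariance parameter), m = 1 the 2-dof test
    (treating variance and covariance as independent).
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("mixture parameter must lie in [0, 1]")
    lam = np.maximum(np.asarray(lam, float), 0.0)
    p = (1.0 - m) * stats.chi2.sf(lam, df=1) + m * stats.chi2.sf(lam, df=2)
    return float(p) if p.ndim == 0 else p


@dataclass
class MixtureCalibration:
    """Outcome of the bootstrap calibration of the mixture weight."""

    m: float
    ks_by_m: dict[float, float]
    statistics: np.ndarray
    pvalues: np.ndarray  # at the chosen m

    @property
    def ks_pvalue(self) -> float:
        return float(stats.kstest(self.pvalues, "uniform").pvalue)


def calibrate_mixture(
    statistics: np.ndarray, m_grid: np.ndarray | None = None
) -> MixtureCalibration:
    """Pick the mixture weight making null LRT statistics' p-values uniform.

    For each candidate weight the statistics are converted to p-values and
    scored by the Kolmogorov-Smirnov distance to Uniform(0, 1); the weight
    with the smallest distance wins.
    """
    stats_arr = np.maximum(np.asarray(statistics, float), 0.0)
    if m_grid is None:
        m_grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
    ks_by_m: dict[float, float] = {}
    for m in m_grid:
        p = mixture_lrt_pvalue(stats_arr, float(m))
        ks_by_m[float(m)] = float(stats.kstest(p, "uniform").statistic)
    m_best = min(ks_by_m, key=ks_by_m.get)
    return MixtureCalibration(
        m=m_best,
        ks_by_m=ks_by_m,
        statistics=stats_arr,
        pvalues=np.asarray(mixture_lrt_pvalue(stats_arr, m_best)),
    )


def calibrate_from_bootstrap(
    null_phenotypes: np.ndarray,
    A: KinshipMatrix,
    design: StudyDesign,
    m_grid: np.ndarray | None = None,
    extra_covariates: np.ndarray | None = None,
    n_restarts: int = 1,
    seed: int = 0,
    warm_start: dict[str, float] | None = None,
) -> MixtureCalibration:
    """Full calibration loop on parametric-bootstrap null phenotypes.

    Each draw is fitted with both the full and the null model (warm-started
    at the data fit's optimum when provided) to form the LRT statistics.
    """
    phenos = np.atleast_2d(np.asarray(null_phenotypes, float))
    if phenos.shape[0] < 100:
        warnings.warn(
            f"only {phenos.shape[0]} bootstrap phenotypes; calibration may be "
            "imprecise (>= 100 recommended)",
            stacklevel=2,
        )
    lams = np.empty(phenos.shape[0])
    for i, yb in enumerate(phenos):
        lam, _, _ = sge_lrt(
            yb,
            A,
            design,
            extra_covariates=extra_covariates,
            n_restarts=n_restarts,
            seed=seed + i,
            start_full=warm_start,
            start_null=warm_start,
        )
        lams[i] = lam
    return calibrate_mixture(lams, m_grid)


def total_genetic_variance(
    fit_or_params: "SGEFit | dict[str, float]", n_bar: float | None = None
) -> float:
    """Total heritable variance for an average cage of n individuals.

    Exact arithmetic: sigma2_AD + 2 (n-1) sigma_ADS + (n-1)^2 sigma2_AS.
    With n = 1 (no cage mates) or no indirect terms it reduces to the
    direct genetic variance.
    """
    if isinstance(fit_or_params, SGEFit):
        params = fit_or_params.params
        if n_bar is None:
            n_bar = fit_or_params.n_bar
    else:
        params = fit_or_params
    if n_bar is None:
        raise ValueError("n_bar required when passing raw parameters")
    if n_bar < 1:
        raise ValueError("average cage size must be >= 1")
    k = n_bar - 1.0
    return float(
        params.get("sigma2_AD", 0.0)
        + 2.0 * k * params.get("sigma_ADS", 0.0)
        + k * k * params.get("sigma2_AS", 0.0)
    )


def permute_cagemates(design: StudyDesign, seed: int = 0) -> StudyDesign:
    """Break the cage-mate structure while keeping the cage random effect.

    Individuals are reassigned to pseudo-cages with the same size multiset
    and a new Z is built from them; W (hence the cage effect) and the
    cage-size covariate are untouched. Under the permutation any genuine
    indirect genetic signal through real cage mates should vanish.
    """
    rng = np.random.default_rng(seed)
    n = design.n_individuals
    sizes = design.W.sum(axis=0).astype(int)
    sizes = sizes[sizes > 0]
    perm = rng.permutation(n)
    Zp = np.zeros((n, n))
    stop = np.cumsum(sizes)
    startidx = np.concatenate([[0], stop[:-1]])
    for s0, s1 in zip(startidx, stop):
        members = perm[s0:s1]
        Zp[np.ix_(members, members)] = 1.0
    np.fill_diagonal(Zp, 0.0)
    return design.with_Z(Zp)


def dge_bias_experiment(
    truth: SimTruth,
    n_phenotypes: int,
    A: KinshipMatrix,
    design: StudyDesign,
    seed: int = 0,
    n_restarts: int = 2,
    include_null_model: bool = True,
) -> pd.DataFrame:
    """Direct-genetic-variance estimation with and without modelling IGE.

    Simulates ``n_phenotypes`` phenotypes from ``truth`` on the given GRM
    and design, fits the model with direct + indirect genetic effects,
    their covariance and cage effects (the terms present in the
    generating model — this experiment simulates no maternal or indirect
    environmental effects) and, optionally, the reduction without any
    indirect terms (direct genetics + cage only, matching how such
    phenotypes are analysed when social effects are ignored). Returns one
    row per phenotype with both estimate sets. With positively correlated
    direct and indirect effects, ignoring IGE drags the direct estimate
    down.
    """
    rows = []
    for i in range(n_phenotypes):
        y, _ = simulate_phenotype(truth, A, design, seed=seed * 100003 + i)
        full = fit_sge(y, A, design, "full", n_restarts=n_restarts, seed=i,
                       compute_se=False, indirect_env=False, maternal=False)
        row = {
            "phenotype": i,
            "full_sigma2_AD": full.sigma2_AD,
            "full_sigma2_AS": full.sigma2_AS,
            "full_sigma_ADS": full.sigma_ADS,
            "full_r_A": full.r_A,
            "full_sigma2_C": full.sigma2_C,
            "full_loglik": full.loglik,
            "full_sigma2_H": full.sigma2_H,
        }
        if include_null_model:
            noige = _fit_dge_cage_only(y, A, design, n_restarts=n_restarts, seed=i)
            row["noige_sigma2_AD"] = noige.params["sigma2_AD"]
            row["noige_loglik"] = noige.loglik
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_dge_cage_only(
    y: np.ndarray,
    A: KinshipMatrix,
    design: StudyDesign,
    n_restarts: int = 2,
    seed: int = 0,
) -> REMLResult:
    """Direct genetics + cage + noise model (no indirect or maternal terms)."""
    n = design.n_individuals
    X = build_fixed_effects(design)
    terms = [
        VarianceTerm("sigma2_AD", A.A),
        VarianceTerm("sigma2_C", design.W @ design.W.T),
        VarianceTerm("sigma2_ED", np.eye(n)),
    ]
    return reml_fit(y, X, terms, n_restarts=n_restarts, seed=seed, compute_se=False)
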
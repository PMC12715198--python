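"""Dense restricted maximum likelihood for linear covariance structures.

The models fitted throughout this package all have marginal covariance

    V(gamma) = sum_k gamma_k K_k

over fixed symmetric kernels ``K_k`` (GRM, cage incidence products,
cage-mate products, identity), where each coefficient is either a variance
(``gamma >= 0``) or a covariance bounded by the geometric mean of two
variances (``gamma_c = rho * sqrt(gamma_i * gamma_j)``, ``|rho| <= 1``).
This keeps the joint covariance of the underlying random effects positive
semi-definite by construction.

Fitting is quasi-Newton (L-BFGS-B) on an unconstrained parametrization
(log variances, atanh correlations) with analytic gradients and random
restarts; the restricted log-likelihood follows Harville's form, which is
identical to the Gaussian log-density of any orthonormal set of error
contrasts:

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| - log|X' X|
                 + y' P y ]

with ``P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = ["VarianceTerm", "CovarianceTerm", "REMLResult", "reml_fit", "restricted_loglik"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VarianceTerm:
    """One variance component: coefficient ``sigma2 >= 0`` times a kernel."""

    name: str
    kernel: np.ndarray


@dataclass
class CovarianceTerm:
    """A covariance coefficient linking two variance terms.

    With ``free=False`` the coefficient is bounded by the geometric mean
    of the paired variances (``gamma = rho * sqrt(sigma2_a * sigma2_b)``,
    ``|rho| <= 1``), which keeps the implied random-effect covariance PSD
    by construction. With ``free=True`` the coefficient is an unbounded
    parameter (positive-definiteness of the marginal covariance is
    enforced at evaluation time instead); this avoids the boundary bias
    the hard |rho| <= 1 constraint induces in the paired variances when
    the true correlation is close to 1.
    """

    name: str
    kernel: np.ndarray
    pair: tuple[str, str]
    free: bool = False


@dataclass
class REMLResult:
    """Outcome of a restricted-likelihood fit."""

    params: dict[str, float]  # natural-scale variances and covariances
    correlations: dict[str, float]  # rho per covariance term
    beta: np.ndarray  # GLS fixed effects at the optimum
    beta_se: np.ndarray
    loglik: float  # restricted log-likelihood (Harville form)
    converged: bool
    n_iter: int
    n_restarts_used: int
    raw: np.ndarray = field(repr=False, default=None)  # optimizer coordinates
    raw_cov: np.ndarray | None = field(repr=False, default=None)
    message: str = ""

    def correlation_se(self, name: str) -> float:
        """Delta-method standard error of a fitted correlation.

        Uses the observed-information covariance of the unconstrained
        coordinates; returns NaN when the information is singular at a
        boundary optimum.
        """
        if self.raw_cov is None or name not in self._cov_meta:
            return float("nan")
        i, j, c, free = self._cov_meta[name]
        rho = self.correlations[name]
        if free:
            # r = gamma_c / sqrt(gamma_i gamma_j) with theta_c = gamma_c,
            # theta_i = log gamma_i: dr/dtheta_c = 1/sqrt(gi gj),
            # dr/dtheta_i = dr/dtheta_j = -r/2
            sqrt_prod = np.exp(0.5 * (self.raw[i] + self.raw[j]))
            g = np.zeros(self.raw.size)
            g[c] = 1.0 / sqrt_prod
            g[i] = -0.5 * rho
            g[j] = -0.5 * rho
            var_r = float(g @ self.raw_cov @ g)
        else:
            var_theta = self.raw_cov[c, c]
            if not np.isfinite(var_theta) or var_theta < 0:
                return float("nan")
            var_r = (1.0 - rho**2) ** 2 * var_theta
        return float(np.sqrt(var_r)) if var_r >= 0 else float("nan")

    # populated by reml_fit: name -> (var_i idx, var_j idx, cov idx, free)
    _cov_meta: dict[str, tuple[int, int, int, bool]] = field(
        default_factory=dict, repr=False
    )


def _natural_params(theta: np.ndarray, var_terms, cov_terms):
    """Map unconstrained coordinates to (variances, covariances, rhos).

    For bounded covariance terms ``rho`` is the tanh of the coordinate;
    for free terms the coordinate IS the covariance and ``rho`` is the
    implied (possibly out-of-unit-interval) ratio.
    """
    n_var = len(var_terms)
    sig2 = np.exp(theta[:n_var])
    var_index = {t.name: i for i, t in enumerate(var_terms)}
    covs = np.empty(len(cov_terms))
    rhos = np.empty(len(cov_terms))
    for c, term in enumerate(cov_terms):
        i, j = var_index[term.pair[0]], var_index[term.pair[1]]
        sqrt_prod = np.sqrt(sig2[i] * sig2[j])
        if term.free:
            covs[c] = theta[n_var + c]
            rhos[c] = covs[c] / sqrt_prod if sqrt_prod > 0 else 0.0
        else:
            rhos[c] = np.tanh(theta[n_var + c])
            covs[c] = rhos[c] * sqrt_prod
    return sig2, covs, rhos


def _neg_loglik_and_grad(theta, y, X, var_terms, cov_terms, logdet_XtX):
    n, p = X.shape
    n_var = len(var_terms)
    sig2, covs, rhos = _natural_params(theta, var_terms, cov_terms)

    V = np.zeros((n, n))
    for g, term in zip(sig2, var_terms):
        V += g * term.kernel
    for g, term in zip(covs, cov_terms):
        V += g * term.kernel

    jitter = 0.0
    scale = max(np.trace(V) / n, 1e-12)
    for _ in range(6):
        try:
            cho = linalg.cho_factor(V + jitter * np.eye(n), lower=True)
            break
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * scale)
    else:  # pragma: no cover - pathological parameters
        return 1e12, np.zeros_like(theta)

    # V^-1 from the Cholesky factor via dpotri (n^3/3, vs n^3 for
    # triangular solves against the identity)
    inv, info = linalg.lapack.dpotri(cho[0], lower=True)
    if info != 0:  # pragma: no cover - dpotri failure after good potrf
        return 1e12, np.zeros_like(theta)
    Vinv = np.tril(inv) + np.tril(inv, -1).T
    Vinv_X = Vinv @ X
    XtViX = X.T @ Vinv_X
    try:
        XtViX_cho = linalg.cho_factor(XtViX)
    except linalg.LinAlgError:
        return 1e12, np.zeros_like(theta)

    Vinv_y = Vinv @ y
    XtVy = X.T @ Vinv_y
    alpha = linalg.cho_solve(XtViX_cho, XtVy)
    Py = Vinv_y - Vinv_X @ alpha
    P = Vinv - Vinv_X @ linalg.cho_solve(XtViX_cho, Vinv_X.T)

    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    logdet_XtViX = 2.0 * np.sum(np.log(np.diag(XtViX_cho[0])))
    quad = float(y @ Py)

    loglik = -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_XtViX - logdet_XtX + quad)

    # dl/dgamma_k = -1/2 [ tr(P K_k) - y' P K_k P y ]
    grad_nat = np.empty(n_var + len(cov_terms))
    for k, term in enumerate(var_terms):
        K = term.kernel
        grad_nat[k] = -0.5 * (np.sum(P * K) - Py @ (K @ Py))
    for c, term in enumerate(cov_terms):
        K = term.kernel
        grad_nat[n_var + c] = -0.5 * (np.sum(P * K) - Py @ (K @ Py))

    # chain rule to unconstrained coordinates
    var_index = {t.name: i for i, t in enumerate(var_terms)}
    grad = np.zeros_like(theta)
    grad[:n_var] = grad_nat[:n_var] * sig2  # d sigma2 / d log sigma2
    for c, term in enumerate(cov_terms):
        g_c = grad_nat[n_var + c]
        if term.free:
            grad[n_var + c] = g_c
            continue
        i, j = var_index[term.pair[0]], var_index[term.pair[1]]
        # bounded covariance depends on both log-variances and atanh(rho)
        grad[i] += g_c * 0.5 * covs[c]
        grad[j] += g_c * 0.5 * covs[c]
        sqrt_prod = np.sqrt(sig2[i] * sig2[j])
        grad[n_var + c] = g_c * (1.0 - rhos[c] ** 2) * sqrt_prod

    return -loglik, -grad


def restricted_loglik(
    y: np.ndarray,
    X: np.ndarray,
    params: dict[str, float],
    var_terms: list[VarianceTerm],
    cov_terms: list[CovarianceTerm] = (),
) -> float:
    """Evaluate the restricted log-likelihood at given natural parameters."""
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    V = np.zeros((n, n))
    for term in var_terms:
        V += params[term.name] * term.kernel
    for term in cov_terms:
        V += params[term.name] * term.kernel
    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)
    cho = linalg.cho_factor(V, lower=True)
    Vinv = linalg.cho_solve(cho, np.eye(n))
    XtViX = X.T @ Vinv @ X
    Vinv_y = Vinv @ y
    beta = np.linalg.solve(XtViX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv @ X @ beta
    logdet_V = 2.0 * np.sum(np.log(np.diag(cho[0])))
    s2, logdet_XtViX = np.linalg.slogdet(XtViX)
    return float(
        -0.5 * ((n - p) * _LOG2PI + logdet_V + logdet_XtViX - logdet_XtX + y @ Py)
    )


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    var_terms: list[VarianceTerm],
    cov_terms: list[CovarianceTerm] = (),
    n_restarts: int = 3,
    gtol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    start: dict[str, float] | None = None,
    compute_se: bool = True,
) -> REMLResult:
    """Fit variance/covariance coefficients by REML.

    Parameters
    ----------
    y, X
        Response and fixed-effect design (n and n x p). A constant column
        must be supplied by the caller if wanted.
    var_terms, cov_terms
        The covariance structure. Every covariance term must name two
        variance terms present in ``var_terms``.
    n_restarts
        Number of random restarts beyond the heuristic start; the best
        optimum is kept.
    start
        Optional natural-scale warm start ``{name: value}``; correlations
        are recovered from covariance entries when present.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")

    # internal scaling: unit-variance response for conditioning
    s = float(np.std(y))
    if s <= 0:
        raise ValueError("response is constant")
    ys = y / s

    sign, logdet_XtX = np.linalg.slogdet(X.T @ X)

    n_var, n_cov = len(var_terms), len(cov_terms)
    var_index = {t.name: i for i, t in enumerate(var_terms)}
    for t in cov_terms:
        if t.pair[0] not in var_index or t.pair[1] not in var_index:
            raise ValueError(f"covariance term {t.name} references unknown variances")

    def theta_from_start(d: dict[str, float]) -> np.ndarray:
        th = np.zeros(n_var + n_cov)
        for i, t in enumerate(var_terms):
            # floor keeps boundary components off the box bound so the
            # optimizer can move them when warm-started from a null fit
            th[i] = np.log(max(d.get(t.name, 1.0 / n_var) / s**2, 1e-3))
        for c, t in enumerate(cov_terms):
            if t.free:
                th[n_var + c] = d.get(t.name, 0.0) / s**2
            else:
                si = d.get(t.pair[0], 1.0)
                sj = d.get(t.pair[1], 1.0)
                denom = np.sqrt(max(si * sj, 1e-16))
                rho = np.clip(d.get(t.name, 0.0) / denom, -0.99, 0.99)
                th[n_var + c] = np.arctanh(rho)
        return th

    # a supplied warm start replaces the heuristic start; extra restarts
    # beyond the first are random either way
    starts = [
        theta_from_start(
            start if start is not None
            else {t.name: 1.0 / n_var for t in var_terms}
        )
    ]
    for _ in range(max(n_restarts - 1, 0)):
        cov_draws = np.array(
            [
                rng.uniform(-0.5, 0.5) if t.free else np.arctanh(rng.uniform(-0.8, 0.8))
                for t in cov_terms
            ]
        )
        th = np.concatenate(
            [np.log(rng.uniform(0.02, 1.5, size=n_var)), cov_draws]
        )
        starts.append(th)

    bounds = [(-16.0, 8.0)] * n_var + [
        (-50.0, 50.0) if t.free else (-6.0, 6.0) for t in cov_terms
    ]
    args = (ys, X, var_terms, cov_terms, logdet_XtX)

    best = None
    total_iter = 0
    for th0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _neg_loglik_and_grad,
                th0,
                args=args,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
            )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    sig2, covs, rhos = _natural_params(theta, var_terms, cov_terms)

    params: dict[str, float] = {}
    for i, t in enumerate(var_terms):
        params[t.name] = float(sig2[i] * s**2)
    for c, t in enumerate(cov_terms):
        params[t.name] = float(covs[c] * s**2)
    correlations = {t.name: float(rhos[c]) for c, t in enumerate(cov_terms)}

    # GLS fixed effects at the optimum, on the original scale
    V = np.zeros((n, n))
    for t in var_terms:
        V += params[t.name] * t.kernel
    for t in cov_terms:
        V += params[t.name] * t.kernel
    cho = linalg.cho_factor(V + 1e-10 * np.trace(V) / n * np.eye(n), lower=True)
    Vinv_X = linalg.cho_solve(cho, X)
    XtViX = X.T @ Vinv_X
    beta_cov = np.linalg.inv(XtViX)
    beta = beta_cov @ (Vinv_X.T @ y)
    beta_se = np.sqrt(np.diag(beta_cov))

    loglik = float(-best.fun - (n - p) * np.log(s))

    raw_cov = None
    if compute_se and (n_var + n_cov) > 0:
        raw_cov = _observed_info_cov(theta, args)

    result = REMLResult(
        params=params,
        correlations=correlations,
        beta=beta,
        beta_se=beta_se,
        loglik=loglik,
        converged=bool(best.success or best.status == 1),
        n_iter=total_iter,
        n_restarts_used=len(starts),
        raw=theta,
        raw_cov=raw_cov,
        message=str(best.message),
    )
    result._cov_meta = {
        t.name: (var_index[t.pair[0]], var_index[t.pair[1]], n_var + c, t.free)
        for c, t in enumerate(cov_terms)
    }
    return result


def _observed_info_cov(theta: np.ndarray, args, eps: float = 1e-4) -> np.ndarray:
    """Finite-difference observed information; pseudo-inverse at boundaries."""
    k = theta.size
    grad0 = _neg_loglik_and_grad(theta, *args)[1]
    H = np.zeros((k, k))
    for i in range(k):
        th = theta.copy()
        th[i] += eps
        H[:, i] = (_neg_loglik_and_grad(th, *args)[1] - grad0) / eps
    H = 0.5 * (H + H.T)
    try:
        return np.linalg.pinv(H)
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full((k, k), np.nan)
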
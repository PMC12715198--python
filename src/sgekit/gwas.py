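"""Mixed-model association scans with LOCO GRMs and permutation thresholds.

Per chromosome, variance components of the null model (direct genetics on
the leave-one-chromosome-out GRM + cage + maternal + noise) are estimated
once by REML; holding them fixed, every variant on that chromosome is
tested by generalized least squares. After whitening by the Cholesky
factor of the fitted covariance the test reduces to a nested linear-model
comparison, with the likelihood-ratio statistic n log(RSS0 / RSS1) on one
degree of freedom.

Genome-wide significance is empirical: genotype rows are permuted
relative to the phenotype, the scan's minimum p-value recorded per
permutation, and the threshold taken as the 95th percentile of the minima
on the -log10 scale. A phenome-wide threshold further Bonferroni-corrects
by the effective number of phenotypes (eigenvalues explaining 99% of the
phenotype covariance trace).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .containers import GenotypeMatrix, KinshipMatrix, StudyDesign
from .kinship import mean_impute
from .reml import VarianceTerm, reml_fit
from .varcomp import build_fixed_effects

__all__ = [
    "GwasScan",
    "lmm_scan",
    "permutation_threshold",
    "adjusted_threshold",
]


@dataclass
class GwasScan:
    """Result of one genome scan."""

    table: pd.DataFrame  # chrom, pos, id, beta, neglog10p
    varcomps: dict[int, dict[str, float]]  # per-chromosome null components
    threshold: float | None = None  # genome-wide -log10 p
    adjusted: float | None = None  # phenome-wide -log10 p
    n_eff: int | None = None
    minima: np.ndarray | None = field(default=None, repr=False)


def _null_varcomp(
    y: np.ndarray,
    A: KinshipMatrix,
    design: StudyDesign,
    extra_covariates: np.ndarray | None,
    n_restarts: int,
    seed: int,
    start: dict[str, float] | None = None,
    gtol: float = 1e-6,
):
    """Null-model REML fit; returns components, whitened (y, X) and L."""
    n = y.size
    X = build_fixed_effects(design, extra_covariates)
    terms = [
        VarianceTerm("sigma2_A", A.A),
        VarianceTerm("sigma2_C", design.W @ design.W.T),
        VarianceTerm("sigma2_M", design.W_mother @ design.W_mother.T),
        VarianceTerm("sigma2_E", np.eye(n)),
    ]
    res = reml_fit(
        y, X, terms, n_restarts=n_restarts, seed=seed, start=start,
        compute_se=False, gtol=gtol,
    )
    V = sum(res.params[t.name] * t.kernel for t in terms)
    L = np.linalg.cholesky(V + 1e-10 * np.trace(V) / n * np.eye(n))
    y_w = linalg.solve_triangular(L, y, lower=True)
    X_w = linalg.solve_triangular(L, X, lower=True)
    return res.params, y_w, X_w, L


def lmm_scan(
    y: np.ndarray,
    G: GenotypeMatrix,
    loco: dict[int, KinshipMatrix],
    design: StudyDesign,
    extra_covariates: np.ndarray | None = None,
    n_restarts: int = 2,
    seed: int = 0,
    warm_start: dict[int, dict[str, float]] | None = None,
    gtol: float = 1e-6,
) -> GwasScan:
    """Single-variant LOCO mixed-model scan across all variants.

    Missing dosages are mean-imputed. Variants constant in the analysis
    sample get a missing p-value. ``loco`` must hold one GRM per
    chromosome present in ``G`` (each excluding that chromosome).
    ``warm_start`` optionally seeds the per-chromosome null REML fits
    (used by the permutation loop, where the unpermuted optimum is a good
    starting point).
    """
    y = np.asarray(y, float).ravel()
    chroms = np.unique(np.asarray(G.variants["chrom"]))
    missing = [int(c) for c in chroms if int(c) not in loco]
    if missing:
        raise ValueError(f"no LOCO GRM supplied for chromosomes {missing}")

    n = y.size
    dos = mean_impute(G.dosages)
    beta = np.full(G.n_variants, np.nan)
    neglogp = np.full(G.n_variants, np.nan)
    varcomps: dict[int, dict[str, float]] = {}

    for c in chroms:
        c = int(c)
        params, y_w, X_w, L = _null_varcomp(
            y, loco[c], design, extra_covariates, n_restarts, seed,
            start=None if warm_start is None else warm_start.get(c),
            gtol=gtol,
        )
        varcomps[c] = params
        # residualize whitened phenotype and genotypes on whitened covariates
        Q, _ = np.linalg.qr(X_w)
        r_y = y_w - Q @ (Q.T @ y_w)
        rss0 = float(r_y @ r_y)

        idx = np.flatnonzero(np.asarray(G.variants["chrom"]) == c)
        Gc = linalg.solve_triangular(L, dos[:, idx], lower=True)
        R_g = Gc - Q @ (Q.T @ Gc)
        gg = np.einsum("ij,ij->j", R_g, R_g)
        gy = r_y @ R_g
        ok = gg > 1e-12 * n
        b = np.zeros(idx.size)
        b[ok] = gy[ok] / gg[ok]
        rss1 = rss0 - np.where(ok, gy**2 / np.where(ok, gg, 1.0), 0.0)
        rss1 = np.maximum(rss1, 1e-300)
        lam = n * (np.log(rss0) - np.log(rss1))
        p = stats.chi2.sf(np.maximum(lam, 0.0), df=1)
        beta[idx[ok]] = b[ok]
        neglogp[idx[ok]] = -np.log10(np.maximum(p[ok], 1e-300))

    table = G.variants.copy()
    table["beta"] = beta
    table["neglog10p"] = neglogp
    return GwasScan(table=table, varcomps=varcomps)


def permutation_threshold(
    y: np.ndarray,
    G: GenotypeMatrix,
    loco: dict[int, KinshipMatrix],
    design: StudyDesign,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    extra_covariates: np.ndarray | None = None,
    n_restarts: int = 1,
) -> tuple[float, np.ndarray]:
    """Empirical genome-wide significance threshold on the -log10 p scale.

    Each permutation reindexes the genotype rows relative to the phenotype
    and design, preserving LD. This is implemented by relabelling the
    individuals — permuting the phenotype and design rows while leaving
    the genotype matrix and the (individual-indexed) GRMs in place — which
    yields the identical scan without rebuilding the genotype containers.
    Variance components are re-estimated per permutation (at a slightly
    looser gradient tolerance; the whitening is insensitive at that
    level). The threshold is the (1 - alpha) quantile of the permutation
    minima of p (equivalently of the maxima of -log10 p). Returns the
    threshold and the per-permutation -log10 minimum p-values.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)
    n = G.n_individuals
    # warm-start each permutation's null fits at the unpermuted optimum
    base = lmm_scan(
        y, G, loco, design, extra_covariates, n_restarts=n_restarts, seed=seed
    )
    warm = base.varcomps
    extra = None if extra_covariates is None else np.atleast_2d(extra_covariates)
    if extra is not None and extra.shape[0] != n:
        extra = extra.T
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        design_p = StudyDesign(
            design.W[perm],
            design.W_mother[perm],
            design.Z[np.ix_(perm, perm)],
            design.cage_size[perm],
        )
        scan = lmm_scan(
            y[perm], G, loco, design_p,
            None if extra is None else extra[perm],
            n_restarts=n_restarts, seed=seed + b, warm_start=warm, gtol=1e-4,
        )
        maxima[b] = np.nanmax(scan.table["neglog10p"].to_numpy())
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    return threshold, maxima


def adjusted_threshold(
    genomewide_logp: float, Y: np.ndarray
) -> tuple[float, int]:
    """Phenome-wide threshold via the effective number of phenotypes.

    ``n_eff`` is the smallest number of principal components of the
    phenotype matrix whose eigenvalues sum to at least 99% of the total
    variance; the genome-wide -log10 threshold is raised by log10(n_eff)
    (a Bonferroni correction on the p scale).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    if Y.shape[1] == 1:
        return float(genomewide_logp), 1
    Yc = Y - Y.mean(axis=0, keepdims=True)
    svals = np.linalg.svd(Yc, compute_uv=False)
    eig = svals**2
    total = eig.sum()
    if total <= 0:
        return float(genomewide_logp), 1
    frac = np.cumsum(eig) / total
    n_eff = int(np.searchsorted(frac, 0.99 - 1e-12) + 1)
    return float(genomewide_logp + np.log10(n_eff)), n_eff
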
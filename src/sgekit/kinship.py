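"""Variant QC, LD pruning and genetic relatedness matrices.

The GRM is the standardized (Yang-style) estimator

    A_ij = (1/M) sum_m (g_im - 2 p_m)(g_jm - 2 p_m) / (2 p_m (1 - p_m))

over QC'd, LD-pruned variants, with missing dosages mean-imputed per
variant and allele frequencies computed on the analysis sample. For
mixed-model GWAS a leave-one-chromosome-out (LOCO) GRM excludes the tested
variant's chromosome, avoiding proximal contamination.
"""

from __future__ import annotations

import warnings

import numpy as np

from .containers import GenotypeMatrix, KinshipMatrix

__all__ = ["qc_filter", "ld_prune", "compute_grm", "loco_grms", "mean_impute"]


def qc_filter(
    G: GenotypeMatrix, max_missing: float = 0.1, min_maf: float = 0.05
) -> np.ndarray:
    """Boolean mask of variants passing missingness and MAF filters.

    Variants with missing rate strictly above ``max_missing`` or minor
    allele frequency strictly below ``min_maf`` are removed (so MAF exactly
    at the threshold is kept). Monomorphic variants never pass.
    """
    miss = np.isnan(G.dosages).mean(axis=0)
    p = G.allele_freq
    maf = np.minimum(p, 1.0 - p)
    return (miss <= max_missing) & (maf >= min_maf) & (maf > 0)


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages with the per-variant mean."""
    out = np.array(dosages, dtype=float, copy=True)
    means = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = means[idx[1]]
    return out


def ld_prune(
    G: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_threshold: float = 0.5,
) -> np.ndarray:
    """Sliding-window pairwise-r2 pruning; returns a boolean keep-mask.

    Within each window of ``window`` variants (advancing by ``step``),
    variants whose squared correlation with an earlier retained variant
    exceeds the threshold are dropped. Windows are evaluated per
    chromosome on position-sorted variants.
    """
    dos = mean_impute(G.dosages)
    chrom = np.asarray(G.variants["chrom"])
    pos = np.asarray(G.variants["pos"])
    M = dos.shape[1]
    keep = np.ones(M, dtype=bool)

    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        m = idx.size
        start = 0
        while start < m:
            win = idx[start : start + window]
            live = win[keep[win]]
            if live.size > 1:
                X = dos[:, live]
                sd = X.std(axis=0)
                ok = sd > 0
                keep[live[~ok]] = False
                live = live[ok]
                if live.size > 1:
                    R = np.corrcoef(dos[:, live], rowvar=False)
                    r2 = R**2
                    for a in range(1, live.size):
                        if not keep[live[a]]:
                            continue
                        earlier = [b for b in range(a) if keep[live[b]]]
                        if earlier and np.any(r2[a, earlier] > r2_threshold):
                            keep[live[a]] = False
            if start + window >= m:
                break
            start += step
    return keep


def compute_grm(
    G: GenotypeMatrix,
    loco_chrom: int | None = None,
    variant_mask: np.ndarray | None = None,
) -> KinshipMatrix:
    """Standardized GRM, optionally leaving one chromosome out.

    Variants that are monomorphic after imputation are excluded with a
    warning (their standardization would divide by zero).
    """
    mask = np.ones(G.n_variants, dtype=bool) if variant_mask is None else np.array(variant_mask, dtype=bool)
    if loco_chrom is not None:
        if not 1 <= loco_chrom <= 20:
            raise ValueError("loco_chrom must be an autosome 1-20")
        mask &= np.asarray(G.variants["chrom"]) != loco_chrom

    dos = mean_impute(G.dosages[:, mask])
    p = dos.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic variants from the GRM",
            stacklevel=2,
        )
        dos = dos[:, poly]
        p = p[poly]
    M = dos.shape[1]
    if M == 0:
        raise ValueError("no variants left for GRM construction")
    Xs = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    A = (Xs @ Xs.T) / M
    A = 0.5 * (A + A.T)
    return KinshipMatrix(A, loco_chrom=loco_chrom, n_variants=M, samples=list(G.samples))


def loco_grms(
    G: GenotypeMatrix, variant_mask: np.ndarray | None = None
) -> dict[int, KinshipMatrix]:
    """One GRM per chromosome present, each excluding that chromosome."""
    chroms = np.unique(np.asarray(G.variants["chrom"]))
    return {int(c): compute_grm(G, loco_chrom=int(c), variant_mask=variant_mask) for c in chroms}
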
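"""Synthetic populations, housing designs, counts and phenotypes.

Everything downstream — GRM construction, REML variance components, the
direct + indirect (social) genetic effects model, GWAS — is exercised on
data generated here, so the generators reproduce the structures the models
assume: a two-generation pedigree (families of full sibs), cage assignments
with or without sibling co-housing, overdispersed sparse count tables, and
phenotypes drawn from the exact joint covariance of the direct+indirect
effects model

    y = X b + a_D + Z a_S + e_D + Z e_S + W c + W' m

with (a_D, a_S) jointly normal with kernel A (the GRM) and 2x2 parameter
matrix [[s2_AD, s_ADS], [s_ADS, s2_AS]], (e_D, e_S) analogous with identity
kernel, iid cage effects c and maternal effects m.

Reproducibility: each logical draw (genotypes, design, phenotype, counts)
consumes its own RNG stream derived from the master seed, so regenerating
one piece never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceTable, GenotypeMatrix, KinshipMatrix, StudyDesign

__all__ = [
    "SimTruth",
    "simulate_genotypes",
    "make_design",
    "simulate_phenotype",
    "simulate_counts",
    "parametric_bootstrap_null",
]

# stream offsets for the per-draw RNGs
_STREAM_GENO, _STREAM_DESIGN, _STREAM_PHENO, _STREAM_COUNTS, _STREAM_BOOT = range(5)


def _stream(seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(which)])


@dataclass
class SimTruth:
    """True parameter values for one simulated study.

    Variances are on the scale of the (unit-diagonal-GRM) phenotype, so a
    value of 0.4 for ``var_dge`` means direct genetic effects contribute a
    variance of 0.4 per individual. They need not sum to 1: the total
    heritable variance combines them through the cage-size expansion of
    sigma2_H.
    """

    n_families: int = 150
    offspring_per_family: int = 3
    n_snps: int = 4000
    maf_range: tuple[float, float] = (0.05, 0.5)
    cage_size: int | dict[int, float] = 3
    cohousing: bool = False
    var_dge: float = 0.4
    var_ige: float = 0.2
    cor_dge_ige: float = 0.9
    var_env_direct: float = 0.4
    var_env_indirect: float = 0.0
    cor_env: float = 0.0
    var_cage: float = 0.2
    var_maternal: float = 0.0
    fixed_cage_size_effect: float = 0.0
    dams_per_sire: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "var_dge",
            "var_ige",
            "var_env_direct",
            "var_env_indirect",
            "var_cage",
            "var_maternal",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.cor_dge_ige) > 1 or abs(self.cor_env) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    @property
    def n_offspring(self) -> int:
        return self.n_families * self.offspring_per_family

    @property
    def cov_dge_ige(self) -> float:
        return self.cor_dge_ige * np.sqrt(self.var_dge * self.var_ige)

    @property
    def cov_env(self) -> float:
        return self.cor_env * np.sqrt(self.var_env_direct * self.var_env_indirect)


def simulate_genotypes(truth: SimTruth) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw a two-generation pedigree of biallelic SNP dosages.

    Parents are sampled under Hardy-Weinberg equilibrium with per-SNP
    allele frequency uniform in ``truth.maf_range``; offspring receive one
    allele from each parent by Mendelian transmission. Each sire serves
    ``truth.dams_per_sire`` consecutive dams (outbred-colony style), so
    litters come in half-sib groups and relatedness spans families — the
    gradation (full sibs 0.5, half sibs 0.25, unrelated ~0) that
    identifies direct against indirect genetic effects when relatives end
    up as cage mates. Only the offspring generation (the phenotyped
    individuals) is returned, together with a pedigree table (sample,
    family, mother, father, sex).

    SNPs are assigned evenly to the 20 autosomes with consecutive
    positions, mirroring a common-variant panel.
    """
    if truth.n_families < 2 or truth.offspring_per_family < 2:
        raise ValueError("need >= 2 families with >= 2 offspring each")
    rng = _stream(truth.seed, _STREAM_GENO)
    F, K, M = truth.n_families, truth.offspring_per_family, truth.n_snps
    lo, hi = truth.maf_range
    p = rng.uniform(lo, hi, size=M)

    # parental genotypes under HWE: dosage ~ Binomial(2, p)
    dams = rng.binomial(2, p, size=(F, M)).astype(float)
    n_sires = int(np.ceil(F / max(truth.dams_per_sire, 1)))
    sire_pool = rng.binomial(2, p, size=(n_sires, M)).astype(float)
    sire_of_family = np.arange(F) // max(truth.dams_per_sire, 1)
    sires = sire_pool[sire_of_family]

    def transmit(parent: np.ndarray, n_off: int) -> np.ndarray:
        # per-offspring transmitted allele: 0 if parent 0, 1 if parent 2,
        # Bernoulli(1/2) if heterozygous
        out = np.repeat(parent[:, None, :] / 2.0, n_off, axis=1)
        het = parent == 1
        draws = rng.random(size=(F, n_off, M)) < 0.5
        out = np.where(het[:, None, :], draws.astype(float), out)
        return out

    offspring = transmit(dams, K) + transmit(sires, K)
    dosages = offspring.reshape(F * K, M)

    per_chrom = int(np.ceil(M / 20))
    chrom = (np.arange(M) // per_chrom) + 1
    chrom = np.minimum(chrom, 20)
    pos = np.concatenate(
        [np.arange(np.sum(chrom == c)) * 1000 + 1000 for c in range(1, 21) if np.any(chrom == c)]
    )
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": [f"snp{c}_{q}" for c, q in zip(chrom, pos)]}
    )

    samples = [f"F{f}_O{k}" for f in range(F) for k in range(K)]
    sex = rng.choice(["F", "M"], size=F * K)
    pedigree = pd.DataFrame(
        {
            "sample": samples,
            "family": np.repeat(np.arange(F), K),
            "mother": [f"dam{f}" for f in np.repeat(np.arange(F), K)],
            "father": [f"sire{s}" for s in np.repeat(sire_of_family, K)],
            "sex": sex,
        }
    )
    return GenotypeMatrix(dosages, variants, samples=samples), pedigree


def _draw_cage_sizes(n: int, cage_size, rng: np.random.Generator) -> list[int]:
    if isinstance(cage_size, int):
        sizes = []
        while sum(sizes) + cage_size <= n:
            sizes.append(cage_size)
    else:
        opts = np.array(sorted(cage_size))
        probs = np.array([cage_size[k] for k in opts], dtype=float)
        probs /= probs.sum()
        sizes = []
        while sum(sizes) < n:
            sizes.append(int(rng.choice(opts, p=probs)))
        if sum(sizes) > n:
            sizes[-1] -= sum(sizes) - n
    rem = n - sum(sizes)
    if rem == 1 and sizes:
        sizes[-1] += 1
        rem = 0
    elif rem >= 2:
        sizes.append(rem)
        rem = 0
    if any(s < 2 for s in sizes):
        raise ValueError("cannot partition individuals into cages of size >= 2")
    return sizes


def _random_feasible_assignment(
    mothers: np.ndarray,
    fam_sizes: pd.Series,
    sizes: list[int],
    rng: np.random.Generator,
    max_tries: int = 50,
) -> np.ndarray:
    """Uniform-at-random cage assignment avoiding sibling co-housing.

    Greedy with restarts: families largest-first, each member placed in a
    cage drawn uniformly among those with a free slot and no member of the
    same family. Greedy dead-ends are rare at these occupancy levels; the
    loop restarts with fresh randomness and gives up only after
    ``max_tries`` failures.
    """
    n = mothers.size
    n_cages = len(sizes)
    fam_order = fam_sizes.index.to_numpy()  # largest families first
    for _ in range(max_tries):
        assignment = np.full(n, -1, dtype=int)
        slots = np.asarray(sizes, dtype=int).copy()
        cage_families: list[set] = [set() for _ in range(n_cages)]
        ok = True
        for fam in fam_order:
            members = rng.permutation(np.flatnonzero(mothers == fam))
            for ind in members:
                feasible = [
                    c for c in range(n_cages)
                    if slots[c] > 0 and fam not in cage_families[c]
                ]
                if not feasible:
                    ok = False
                    break
                c = int(rng.choice(feasible))
                assignment[ind] = c
                slots[c] -= 1
                cage_families[c].add(fam)
            if not ok:
                break
        if ok:
            return assignment
    raise ValueError("no-cohousing constraint infeasible for this design")


def make_design(
    pedigree: pd.DataFrame,
    cage_size: int | dict[int, float] = 3,
    cohousing: bool = False,
    seed: int = 0,
) -> StudyDesign:
    """Assign individuals to cages and build the incidence structure.

    With ``cohousing=False`` no two siblings (same mother) ever share a
    cage, mirroring designs where relatedness and shared housing are
    deliberately decoupled; with ``cohousing=True`` siblings are placed
    together preferentially. Returns cage incidence ``W``, maternal
    incidence ``W'``, the symmetric zero-diagonal cage-mate matrix ``Z``
    and the per-individual cage-size covariate.
    """
    rng = _stream(seed, _STREAM_DESIGN)
    n = len(pedigree)
    sizes = _draw_cage_sizes(n, cage_size, rng)
    n_cages = len(sizes)

    mothers = pedigree["mother"].to_numpy()
    order = np.arange(n)

    if cohousing:
        # keep families contiguous so siblings land in shared cages
        fam_order = rng.permutation(pd.unique(mothers))
        order = np.concatenate([np.flatnonzero(mothers == m) for m in fam_order])
        assignment = np.repeat(np.arange(n_cages), sizes)
    else:
        # deal family members round-robin across cages: cage c receives at
        # most one member of any family as long as no family exceeds the
        # cage count
        fam_sizes = pd.Series(mothers).value_counts()
        if fam_sizes.max() > n_cages:
            raise ValueError(
                "no-cohousing design infeasible: a family has more members than cages"
            )
        # place each animal in a cage drawn uniformly among the feasible
        # ones (free slot, no family member already inside): a sequential
        # scheme would sweep families through adjacent cages, making cage
        # mates of siblings siblings themselves and collinearizing the
        # direct and indirect genetic kernels
        assignment = _random_feasible_assignment(mothers, fam_sizes, sizes, rng)
        order = np.arange(n)

    if cohousing:
        full_assignment = np.empty(n, dtype=int)
        full_assignment[order] = assignment
        assignment = full_assignment

    W = np.zeros((n, n_cages))
    W[np.arange(n), assignment] = 1.0
    Z = W @ W.T
    np.fill_diagonal(Z, 0.0)
    cage_counts = W.sum(axis=0)
    cage_size_cov = cage_counts[assignment]

    mother_ids = pd.unique(mothers)
    mother_index = {m: j for j, m in enumerate(mother_ids)}
    Wm = np.zeros((n, len(mother_ids)))
    Wm[np.arange(n), [mother_index[m] for m in mothers]] = 1.0

    metadata = pedigree.copy()
    metadata["cage"] = assignment
    metadata["cage_size"] = cage_size_cov
    return StudyDesign(W, Wm, Z, cage_size_cov, metadata)


def _psd_chol2(var1: float, var2: float, cov: float) -> np.ndarray:
    """Cholesky-like factor of a 2x2 PSD matrix, robust to rank deficiency."""
    B = np.array([[var1, cov], [cov, var2]])
    det = var1 * var2 - cov * cov
    if det < -1e-12 * max(var1 * var2, 1.0):
        raise ValueError("joint covariance of direct/indirect effects is not PSD")
    w, U = np.linalg.eigh(B)
    w = np.clip(w, 0.0, None)
    return U @ np.diag(np.sqrt(w)) @ U.T


def simulate_phenotype(
    truth: SimTruth,
    A: KinshipMatrix,
    design: StudyDesign,
    seed: int | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw one phenotype from the exact model covariance.

    Returns the phenotype vector and every additive component (fixed,
    direct genetic, indirect genetic, direct environment, indirect
    environment, cage, maternal), whose sum reproduces the phenotype
    exactly — useful as an oracle for the marginal covariance.
    """
    rng = _stream(truth.seed if seed is None else seed, _STREAM_PHENO)
    n = design.n_individuals
    if A.n_individuals != n:
        raise ValueError("GRM and design cover different individuals")

    L_A = np.linalg.cholesky(A.A + 1e-8 * np.eye(n))

    L_g = _psd_chol2(truth.var_dge, truth.var_ige, truth.cov_dge_ige)
    G = L_A @ rng.standard_normal((n, 2)) @ L_g.T
    a_D, a_S = G[:, 0], G[:, 1]

    L_e = _psd_chol2(truth.var_env_direct, truth.var_env_indirect, truth.cov_env)
    E = rng.standard_normal((n, 2)) @ L_e.T
    e_D, e_S = E[:, 0], E[:, 1]

    c = rng.normal(0.0, np.sqrt(truth.var_cage), size=design.W.shape[1])
    m = rng.normal(0.0, np.sqrt(truth.var_maternal), size=design.W_mother.shape[1])

    components = {
        "fixed": truth.fixed_cage_size_effect * design.cage_size,
        "dge": a_D,
        "ige": design.Z @ a_S,
        "env_direct": e_D,
        "env_indirect": design.Z @ e_S,
        "cage": design.W @ c,
        "maternal": design.W_mother @ m,
    }
    y = np.sum(list(components.values()), axis=0)
    return y, components


def simulate_counts(
    n_samples: int,
    n_taxa: int,
    seed: int = 0,
    mean_depth: float = 20000.0,
    depth_log_sd: float = 0.25,
    abundance_log_sd: float = 2.0,
    occupancy: float | np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> AbundanceTable:
    """Sparse overdispersed count table with nested taxonomy strings.

    Per-taxon base relative abundances are log-normal; per sample, each
    taxon is present with its occupancy probability and its abundance gets
    an extra log-normal perturbation; the per-sample sequencing depth is
    log-normal around ``mean_depth`` and reads are drawn multinomially.
    Taxa are grouped into genera (pairs) nested within families (groups of
    four) so taxonomy collapsing is exercised.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = _stream(seed, _STREAM_COUNTS)
    base = rng.lognormal(0.0, abundance_log_sd, size=n_taxa)
    if occupancy is None:
        occ = rng.uniform(0.3, 1.0, size=n_taxa)
    else:
        occ = np.broadcast_to(np.asarray(occupancy, float), (n_taxa,)).copy()
    if ((occ < 0) | (occ > 1)).any():
        raise ValueError("occupancy probabilities must lie in [0, 1]")

    present = rng.random((n_samples, n_taxa)) < occ
    noise = rng.lognormal(0.0, 0.5, size=(n_samples, n_taxa))
    rel = present * base * noise
    empty = rel.sum(axis=1) == 0
    if empty.any():
        # guarantee a non-degenerate composition for every sample
        rel[empty, np.argmax(base)] = base.max()
    rel = rel / rel.sum(axis=1, keepdims=True)

    depth = np.maximum(
        rng.lognormal(np.log(mean_depth), depth_log_sd, size=n_samples), 1.0
    ).astype(np.int64)
    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depth, rel)])

    taxa = [f"ASV_{t}" for t in range(n_taxa)]
    taxonomy = pd.Series(
        [
            "k__Bacteria; p__P0; c__C0; o__O0; "
            f"f__Fam{t // 4}; g__Gen{t // 2}; s__Sp{t}"
            for t in range(n_taxa)
        ],
        index=taxa,
    )
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=taxa)
    return AbundanceTable(counts_df, taxonomy)


def parametric_bootstrap_null(
    params: dict[str, float],
    A: KinshipMatrix,
    design: StudyDesign,
    n_boot: int,
    seed: int = 0,
    X: np.ndarray | None = None,
    beta: np.ndarray | None = None,
) -> np.ndarray:
    """Draw phenotypes from a fitted indirect-effect-free null model.

    ``params`` must describe a null fit: direct genetic variance, cage,
    maternal, direct and (optionally) indirect environmental terms, but no
    genetic indirect variance or covariance (``sigma2_AS = sigma_ADS = 0``).
    Returns an ``(n_boot, n)`` array of draws from N(X beta, V_null).
    """
    if params.get("sigma2_AS", 0.0) != 0.0 or params.get("sigma_ADS", 0.0) != 0.0:
        raise ValueError("null bootstrap requires sigma2_AS = sigma_ADS = 0")
    rng = _stream(seed, _STREAM_BOOT)
    n = design.n_individuals
    Z, W, Wm = design.Z, design.W, design.W_mother
    V = (
        params.get("sigma2_AD", 0.0) * A.A
        + params.get("sigma2_ED", 0.0) * np.eye(n)
        + 2.0 * params.get("sigma_EDS", 0.0) * Z
        + params.get("sigma2_ES", 0.0) * (Z @ Z)
        + params.get("sigma2_C", 0.0) * (W @ W.T)
        + params.get("sigma2_M", 0.0) * (Wm @ Wm.T)
    )
    L = np.linalg.cholesky(V + 1e-10 * max(np.trace(V) / n, 1.0) * np.eye(n))
    mean = np.zeros(n)
    if X is not None and beta is not None:
        mean = np.atleast_2d(X) @ np.asarray(beta)
        mean = np.asarray(mean).ravel()
    draws = mean + rng.standard_normal((n_boot, n)) @ L.T
    return draws
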
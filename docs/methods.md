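# Methods

`sgekit` quantifies host genetic effects on microbiome phenotypes in
group-housed animal studies, separating what an animal's own genotype does
to its phenotype (direct genetic effects, DGE) from what its cage mates'
genotypes do (indirect, or social, genetic effects, IGE — in the
microbiome setting mediated by horizontal transmission of microbes between
co-housed animals). Everything runs on synthetic data produced by the
package's own generators, so every stage is testable without any download.

## Models

### Heritability model

For a phenotype vector *y* over *n* animals:

    y = Xb + a + e + Wc + W'm

with `a ~ N(0, σ²_A A)` (A the SNP-based genetic relatedness matrix),
iid cage effects `c ~ N(0, σ²_C I)` through the cage incidence `W`,
iid maternal effects `m ~ N(0, σ²_M I)` through the maternal incidence
`W'`, and iid noise `e ~ N(0, σ²_E I)`. The fixed effects `X` are an
intercept plus the cage-size covariate (dropped automatically when all
cages have the same size). SNP heritability is
`h² = σ²_A / (σ²_A + σ²_C + σ²_M + σ²_E)`; its significance is a 1-dof
likelihood-ratio test against the reduction without `a`. Because the null
value sits on the boundary of the parameter space this test is
conservative; we keep the 1-dof reference as is standard.

The bivariate extension stacks one trait measured in two disjoint cohorts
and transmits genetic covariance through the cross-cohort block of the
joint GRM, parametrized as `r_G √(σ²_A1 σ²_A2)`. Cross-cohort cage,
maternal and residual covariances are fixed at zero: the cohorts house
disjoint animals, so these terms are unidentifiable from the data and
fixing them is the parsimonious choice (litters split across cohorts could
in principle correlate maternal effects; we accept that risk).

### Direct + indirect genetic effects model

    y = Xb + a_D + Z a_S + e_D + Z e_S + Wc + W'm

`Z` is the symmetric, zero-diagonal cage-mate indicator. `(a_D, a_S)` are
jointly normal with kernel `A` and 2×2 parameter matrix
`[[σ²_AD, σ_ADS], [σ_ADS, σ²_AS]]`; `(e_D, e_S)` are analogous with an
identity kernel. The marginal covariance, used both to fit and to
simulate, is

    V = σ²_AD A + σ_ADS (AZ + ZA) + σ²_AS ZAZ
        + σ²_ED I + 2 σ_EDS Z + σ²_ES Z²
        + σ²_C WWᵀ + σ²_M W'W'ᵀ.

When *simulating*, covariances are specified as correlation × geometric
mean of the two variances (|r| ≤ 1 keeps the joint effect covariance PSD
by construction). When *fitting* this model, σ_ADS and σ_EDS are free
coefficients: the hard |r| ≤ 1 bound binds in roughly half the fits when
the true correlation is near 1, and the binding constraint propagates
into a downward bias of the paired variances (verified against an
unconstrained method-of-moments estimator, which is unbiased on the same
data). Positive-definiteness of the marginal covariance is enforced at
evaluation time instead, and the reported correlation is the ratio
σ_ADS/√(σ²_AD σ²_AS) clipped to [−1, 1]. The bivariate cross-cohort
model keeps the bounded parametrization (its correlation is the estimand
itself).

The **total heritable variance** for an average cage of *n* animals is

    σ²_H = σ²_AD + 2(n−1) σ_ADS + (n−1)² σ²_AS

computed by exact arithmetic (no tolerance); with *n* = 1 or no indirect
terms it reduces to σ²_AD.

### Testing for indirect genetic effects

The null model drops `Z a_S` (σ²_AS = σ_ADS = 0) but keeps the indirect
environmental effects `Z e_S` — the test isolates the *genetic* part of
the social signal. The null model also retains σ_EDS: the environmental
covariance belongs to the retained `Z e_S` term, not to the dropped one.
The LRT statistic (clamped at 0) tests one boundary variance together
with a covariance that exists only when that variance is positive, so its
null distribution is a mixture of χ²(1) and χ²(2):

    p(Λ) = (1 − m) S₁(Λ) + m S₂(Λ),

`S_k` the χ²(k) survival function. `m = 0` is the plain 1-dof test,
`m = 1` the 2-dof test. The weight `m` is chosen by parametric bootstrap:
phenotypes are drawn from the null model fitted to the data, full and
null models are fitted to each draw, and `m` is scanned over
{0, 0.1, …, 1} for the value minimizing the Kolmogorov–Smirnov distance
of the null p-values to Uniform(0, 1). "Calibrated" is operationalized
as that minimum; the selected weight is design-dependent (the classical
independent-parameter result is m = 0.5, and fitted designs typically
select somewhat higher weights).

### Cage-mate permutations

To show that an indirect-genetic signal really travels through cage
mates, the cage-mate matrix `Z` is rebuilt from a random reassignment of
animals to pseudo-cages with the same size multiset, while `W` — hence
the cage random effect — keeps the real cages. Under permutation the
indirect variance estimates collapse toward zero and the unpermuted total
genetic variance exceeds every permuted value.

### Mixed-model GWAS

Per chromosome, the heritability model is fitted once by REML with the
leave-one-chromosome-out (LOCO) GRM — the tested chromosome contributes
no weight to the relatedness kernel, avoiding proximal contamination.
Holding the variance components fixed, each (mean-imputed) variant is
tested by generalized least squares: after whitening by the Cholesky
factor of the fitted covariance the test is a nested linear-model
comparison with statistic `n log(RSS₀/RSS₁)` on 1 dof. The genome-wide
threshold is empirical: genotype rows (and the GRM index, consistently)
are permuted relative to the phenotype, components re-estimated per
permutation (re-estimation keeps the procedure valid under the
permutation null), the scan's minimum p recorded, and the threshold taken
as the 95th percentile of −log10(min p) over (by default) 1000
permutations. The phenome-wide threshold adds log10(n_eff), where n_eff
is the number of principal components explaining 99% of the phenotype
matrix's variance.

## Preprocessing

Count tables are filtered on library size (samples outside mean ± 2 sd of
depth dropped), optionally collapsed by taxonomy rank (unassigned taxa
pooled explicitly), CLR-transformed, prevalence-filtered, and normalised:

- **CLR**: counts are closed to relative abundances per sample, zeros are
  replaced by 1e-5, and each value is logged against the geometric mean
  of the sample's values. The replacement is applied on the
  relative-abundance scale — the CLR is scale-invariant, so this makes
  the replacement independent of sequencing depth. Rows with no replaced
  zeros sum to zero exactly.
- **Prevalence**: a taxon is kept in a group when it has a nonzero raw
  count in at least 50% of that group's samples ("at least": 5/10
  passes). Presence is judged on raw counts, never on CLR values.
- **Normalisation**: rank-based inverse-normal transform with ties broken
  by a seeded random permutation (the seed is recorded in the phenotype's
  provenance — the procedure is stochastic and reproducibility demands
  it), followed by OLS residualization on technical covariates (sex,
  batches, library size; categorical covariates one-hot encoded,
  rank-deficient encodings pruned with a warning). Residualization
  follows normalisation, in that order.

## Synthetic data

The generator produces what the models assume, not what a sequencer
produces:

- **Genotypes**: a two-generation pedigree — per-SNP allele frequency
  uniform in (0.05, 0.5], parents drawn under Hardy–Weinberg, offspring
  by Mendelian transmission, each sire bred to two dams (outbred-colony
  style); SNPs spread evenly over 20 autosomes. This creates the graded
  GRM structure the models need (full sibs ≈ 0.5, half sibs ≈ 0.25,
  unrelated ≈ 0) without modelling founder haplotypes, linkage or
  genotyping error. The cross-family relatedness matters: when all
  relatedness is confined to full-sib litters that are never co-housed,
  the direct and indirect genetic kernels are weakly separated and REML
  point estimates of the direct variance skew low at a few hundred
  animals; half-sib ties across litters (relatives as cage mates) restore
  identification, mirroring the pervasive relatedness of real outbred
  colonies.
- **Designs**: cages of fixed size or mixed {2, 3, 4}, with siblings
  either never co-housed (each animal placed in a cage drawn uniformly
  among the feasible ones; a sequential scheme would correlate cage-mate
  relatedness with sib structure; infeasible designs raise) or
  preferentially co-housed.
- **Phenotypes**: drawn from the exact joint covariance of the
  direct+indirect model, with every additive component returned
  separately so the marginal covariance can be verified entrywise against
  Monte-Carlo replicates.
- **Counts**: per-taxon log-normal base abundances, per-taxon occupancy,
  per-sample log-normal perturbations and depths, multinomial sampling,
  with genus/family-nested taxonomy strings. No sequencing error, no
  chimeras, no phylogenetic signal: passing tests demonstrate the
  statistical machinery, not robustness to real amplicon artefacts.

One RNG stream per logical draw (genotypes, design, phenotype, counts,
bootstrap), all derived from the master seed, so regenerating one piece
never perturbs the others, and a fixed seed reproduces byte-identical
output.

## Fitting

All models are fitted by REML on the dense covariance: log-parametrized
variances, covariances either atanh-bounded (bivariate model) or free
(SGE model, see above), analytic gradients, L-BFGS-B with (by default)
three random restarts keeping the best optimum, and a gradient tolerance
of 1e-6. The headline experiments use two restarts per fit — their
estimates average over many phenotypes, and spot checks with eight
restarts found no better optima. The restricted log-likelihood follows
Harville's form including the `log|XᵀX|` term, making it identical to the
Gaussian log-density of orthonormal error contrasts — which is exactly how
the test suite's independent oracle evaluates it. Standard errors of
correlations come from a finite-difference observed information and the
delta method; at boundary optima the information is singular and the s.e.
is reported as NaN rather than a fabricated number. Bootstrap refits are
warm-started at the data fit's optimum (with boundary components floored
at 0.1% of the phenotypic variance so the optimizer can move them) and
use a single start.

Identifiability caveat recorded by the fitter rather than reparametrized:
when every cage has size 2, `Z² = I` and `WWᵀ = I + Z`, so the indirect
environmental variance is confounded with the direct one and the cage
term; fits on such designs carry a note. The same model is nevertheless
fitted on all designs, mirroring multi-cohort practice.

## Problem sizes and defaults

The headline experiments run at desk scale, chosen once:

| experiment | size | key parameters |
|---|---|---|
| IGE recovery / DGE bias | 100 phenotypes, 150 families × 3 sibs (n = 450), cages of 3, 4000 SNPs | DGE 0.4, IGE 0.2, correlation 0.9, cage 0.2, direct environment 0.4; analysis models: DGE+IGE+cage vs DGE+cage, mirroring the generating terms |
| mixture calibration | 200 bootstrap draws, 100 families (n = 300), cages 2–4, 3000 SNPs | null: DGE 0.4, cage 0.2, maternal 0.1, environment 0.3 |
| cage-mate permutations | 1 phenotype, 20 permutations, 100 families (n = 300) | as recovery |
| GWAS machinery | 300 sib-pair animals, 1000 scan variants, 1000 permutations | QTL at 10% of phenotypic variance |

The recovery experiment's generating values (0.4/0.2/0.9) are the
"strong IGE" setting; cage variance defaults to 0.2 and the direct
environmental variance to 0.4 so the direct components sum near 1 —
neither is dictated by the scenario and both are configurable. Maternal
effects are omitted from that experiment for simplicity and included
(0.1) in the calibration design.

## Known limitations

- Dense O(n³) likelihood evaluations cap practical sample sizes at a few
  thousand; no low-rank or AI-REML shortcuts are implemented.
- The full model's non-negativity constraint on σ²_AS inflates it
  slightly under a null truth, depressing σ̂²_AD by a few hundredths at
  n ≈ 300; this boundary effect shrinks with n and is visible in the
  null-equivalence test's tolerance.
- Even with the matched analysis model, REML means of the direct genetic
  variance retain a small negative skew (~0.01–0.03) at a few hundred
  animals; an unconstrained method-of-moments estimator on the same data
  is unbiased but far noisier. The skew vanishes as n grows.
- The bivariate model fixes cross-cohort maternal covariance at zero
  (see above).
- LD pruning uses pairwise r² in sliding windows (threshold 0.5 ≈ VIF 2)
  rather than a variance-inflation criterion; at these scales the GRM is
  insensitive to the exact pruned set.
- GRM standardization uses allele frequencies from the analysis sample,
  not an external reference.
- The permutation-threshold procedure re-estimates variance components
  per permutation; with hundreds of permutations and chromosomes this is
  the dominant cost of the GWAS stage.
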
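"""End-to-end simulation experiments used by the analysis drivers.

Each function builds a synthetic study from scratch (genotypes, housing
design, GRM), runs one of the package's headline analyses, and returns
plain data structures ready to be tabulated. Problem sizes default to
desk scale: a few hundred animals, a few thousand SNPs — large enough for
the variance-component machinery to be well conditioned, small enough to
run on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .containers import KinshipMatrix, StudyDesign
from .kinship import compute_grm
from .sge import (
    MixtureCalibration,
    calibrate_from_bootstrap,
    dge_bias_experiment,
    fit_sge,
    permute_cagemates,
)
from .sim import (
    SimTruth,
    make_design,
    parametric_bootstrap_null,
    simulate_genotypes,
    simulate_phenotype,
)

__all__ = [
    "build_population",
    "ige_recovery_experiment",
    "calibration_experiment",
    "cagemate_permutation_experiment",
]


def build_population(
    truth: SimTruth,
) -> tuple[SimTruth, StudyDesign, KinshipMatrix]:
    """Genotypes, housing design and GRM for one synthetic study."""
    G, ped = simulate_genotypes(truth)
    design = make_design(
        ped, cage_size=truth.cage_size, cohousing=truth.cohousing, seed=truth.seed
    )
    A = compute_grm(G)
    return truth, design, A


def ige_recovery_experiment(
    n_phenotypes: int = 100,
    n_families: int = 150,
    offspring_per_family: int = 3,
    n_snps: int = 4000,
    var_dge: float = 0.4,
    var_ige: float = 0.2,
    cor_dge_ige: float = 0.9,
    var_cage: float = 0.2,
    var_env_direct: float = 0.4,
    seed: int = 0,
    n_restarts: int = 2,
) -> pd.DataFrame:
    """Recovery of direct/indirect genetic variances and their correlation.

    Simulates phenotypes with strong indirect genetic effects (defaults:
    direct variance 0.4, indirect 0.2, correlation 0.9, cage variance 0.2)
    on a no-cohousing design with cages of 3, then fits both the full
    model and the reduction ignoring indirect effects. The returned frame
    has one row per phenotype with both models' estimates; comparing the
    two direct-variance columns exhibits the underestimation incurred by
    ignoring social genetic effects.
    """
    truth = SimTruth(
        n_families=n_families,
        offspring_per_family=offspring_per_family,
        n_snps=n_snps,
        cage_size=3,
        cohousing=False,
        var_dge=var_dge,
        var_ige=var_ige,
        cor_dge_ige=cor_dge_ige,
        var_cage=var_cage,
        var_env_direct=var_env_direct,
        var_maternal=0.0,
        seed=seed,
    )
    _, design, A = build_population(truth)
    return dge_bias_experiment(
        truth, n_phenotypes, A, design, seed=seed, n_restarts=n_restarts
    )


@dataclass
class CalibrationExperiment:
    """Null-simulation calibration of the mixture LRT weight."""

    calibration: MixtureCalibration
    null_params: dict[str, float]
    n_boot: int
    seed: int
    truth: SimTruth = field(repr=False, default=None)


def calibration_experiment(
    n_boot: int = 200,
    n_families: int = 100,
    offspring_per_family: int = 3,
    n_snps: int = 3000,
    seed: int = 0,
    n_restarts_boot: int = 1,
) -> CalibrationExperiment:
    """Parametric-bootstrap calibration on a pooled-style mixed-cage design.

    One heritable phenotype (direct genetics + cage + maternal, no
    indirect genetic effects) is simulated on a design with cages of 2-4
    and fitted with the null model; ``n_boot`` phenotypes are then drawn
    from the fitted null covariance and each is fitted with the full and
    the null model (warm-started at the data fit) to form the null LRT
    distribution. The mixture weight minimizing the KS distance of the
    p-values to Uniform(0, 1) is returned with its per-weight diagnostics.
    """
    truth = SimTruth(
        n_families=n_families,
        offspring_per_family=offspring_per_family,
        n_snps=n_snps,
        cage_size={2: 1 / 3, 3: 1 / 3, 4: 1 / 3},
        cohousing=False,
        var_dge=0.4,
        var_ige=0.0,
        cor_dge_ige=0.0,
        var_cage=0.2,
        var_maternal=0.1,
        var_env_direct=0.3,
        seed=seed,
    )
    _, design, A = build_population(truth)
    y, _ = simulate_phenotype(truth, A, design, seed=seed)
    data_fit = fit_sge(y, A, design, model="null", n_restarts=2, seed=seed,
                       compute_se=False)
    null_params = dict(data_fit.params)
    null_params["sigma2_AS"] = 0.0
    null_params["sigma_ADS"] = 0.0
    draws = parametric_bootstrap_null(
        null_params, A, design, n_boot, seed=seed,
    )
    calib = calibrate_from_bootstrap(
        draws, A, design,
        n_restarts=n_restarts_boot, seed=seed, warm_start=data_fit.params,
    )
    return CalibrationExperiment(
        calibration=calib, null_params=null_params, n_boot=n_boot, seed=seed,
        truth=truth,
    )


def cagemate_permutation_experiment(
    n_perm: int = 20,
    n_families: int = 100,
    offspring_per_family: int = 3,
    n_snps: int = 3000,
    seed: int = 0,
    n_restarts: int = 2,
) -> pd.DataFrame:
    """Total genetic variance on real versus permuted cage-mate assignments.

    Simulates one phenotype with substantial indirect genetic effects,
    fits the full model on the true cage-mate matrix, then on ``n_perm``
    permutations of the cage-mate assignments (cage effects keep the real
    cages). Returns a long-format frame keyed by permutation (-1 for the
    unpermuted data) with the indirect variance and total genetic variance
    per fit.
    """
    truth = SimTruth(
        n_families=n_families,
        offspring_per_family=offspring_per_family,
        n_snps=n_snps,
        cage_size=3,
        cohousing=False,
        var_dge=0.4,
        var_ige=0.2,
        cor_dge_ige=0.9,
        var_cage=0.2,
        var_env_direct=0.4,
        seed=seed,
    )
    _, design, A = build_population(truth)
    y, _ = simulate_phenotype(truth, A, design, seed=seed)

    rows = []
    fit = fit_sge(y, A, design, "full", n_restarts=n_restarts, seed=seed,
                  compute_se=False)
    rows.append(
        {
            "permutation": -1,
            "sigma2_AD": fit.sigma2_AD,
            "sigma2_AS": fit.sigma2_AS,
            "sigma_ADS": fit.sigma_ADS,
            "sigma2_H": fit.sigma2_H,
        }
    )
    for b in range(n_perm):
        permuted = permute_cagemates(design, seed=seed * 1009 + b + 1)
        pfit = fit_sge(y, A, permuted, "full", n_restarts=n_restarts,
                       seed=seed + b, compute_se=False)
        rows.append(
            {
                "permutation": b,
                "sigma2_AD": pfit.sigma2_AD,
                "sigma2_AS": pfit.sigma2_AS,
                "sigma_ADS": pfit.sigma_ADS,
                "sigma2_H": pfit.sigma2_H,
            }
        )
    return pd.DataFrame(rows)
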
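"""Core in-memory containers shared across the package.

All heavy numerical work operates on plain numpy arrays held by small
dataclasses; sample/variant annotations are pandas objects so they can be
round-tripped through the TSV interfaces in :mod:`sgekit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "StudyDesign",
    "KinshipMatrix",
    "AbundanceTable",
]


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with a variant map.

    Dosages are 0/1/2 counts of the alternate allele; missing values are
    encoded as NaN. The variant map carries chromosome (1-20, autosomes),
    position and ID per variant. ``allele_freq`` is the alternate-allele
    frequency computed on the non-missing entries of this sample.
    """

    dosages: np.ndarray  # (n_individuals, n_variants), float with NaN missing
    variants: pd.DataFrame  # columns: chrom, pos, id
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x variants array")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError("variant map length does not match dosage columns")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (NaN)")
        chrom = np.asarray(self.variants["chrom"])
        if chrom.size and ((chrom < 1) | (chrom > 20)).any():
            raise ValueError("chromosomes must be autosomes 1-20")
        if not self.samples:
            self.samples = [f"S{i}" for i in range(self.dosages.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.dosages[:, mask],
            self.variants.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask]
            .reset_index(drop=True),
            samples=list(self.samples),
        )


@dataclass
class StudyDesign:
    """Cage/maternal incidence structure for group-housed individuals.

    Attributes
    ----------
    W
        Individual x cage incidence (0/1, one cage per individual).
    W_mother
        Individual x mother incidence (0/1).
    Z
        Symmetric cage-mate indicator with zero diagonal: ``Z[i, j] = 1``
        iff i and j share a cage and ``i != j``. Used to model indirect
        (social) effects; may be permuted independently of ``W``.
    cage_size
        Per-individual covariate: number of individuals in own cage.
    metadata
        Per-sample table (sample, cage, mother, cohort, sex, batch,
        library_size, ... whatever the analysis carries along).
    """

    W: np.ndarray
    W_mother: np.ndarray
    Z: np.ndarray
    cage_size: np.ndarray
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.W_mother = np.asarray(self.W_mother, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.cage_size = np.asarray(self.cage_size, dtype=float)
        n = self.W.shape[0]
        if self.Z.shape != (n, n):
            raise ValueError("Z must be square over the same individuals as W")
        if not np.allclose(self.Z, self.Z.T):
            raise ValueError("cage-mate matrix Z must be symmetric")
        if np.any(np.diag(self.Z) != 0):
            raise ValueError("cage-mate matrix Z must have a zero diagonal")

    @property
    def n_individuals(self) -> int:
        return self.W.shape[0]

    @property
    def mean_cage_size(self) -> float:
        """Average number of individuals per cage (the n of sigma2_H)."""
        return float(self.W.sum(axis=0)[self.W.sum(axis=0) > 0].mean())

    def with_Z(self, Z_new: np.ndarray) -> "StudyDesign":
        """Return a copy with a replacement cage-mate matrix (W untouched)."""
        return StudyDesign(self.W, self.W_mother, Z_new, self.cage_size, self.metadata)


@dataclass
class KinshipMatrix:
    """SNP-based genetic relatedness matrix (GRM).

    ``loco_chrom`` records the chromosome left out (None for the
    whole-genome GRM); ``n_variants`` the number of variants averaged.
    """

    A: np.ndarray
    loco_chrom: int | None = None
    n_variants: int = 0
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.A, self.A.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")
        n = self.A.shape[0]
        # PSD within numerical tolerance of the estimator
        w_min = float(np.linalg.eigvalsh(self.A)[0])
        if w_min < -1e-8 * max(np.trace(self.A), 1.0) / n:
            raise ValueError(f"GRM is not PSD (min eigenvalue {w_min:.3e})")
        if not self.samples:
            self.samples = [f"S{i}" for i in range(n)]

    @property
    def n_individuals(self) -> int:
        return self.A.shape[0]


@dataclass
class AbundanceTable:
    """Samples x taxa count table with taxonomy lineages.

    Counts are non-negative integers; ``taxonomy`` maps each taxon column
    to a Greengenes-style lineage string ("k__...; p__...; ...").
    """

    counts: pd.DataFrame  # samples x taxa, integer
    taxonomy: pd.Series  # index = taxa, values = lineage strings

    def __post_init__(self) -> None:
        counts = self.counts
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.counts = counts.astype(np.int64)
        self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    @property
    def depth(self) -> pd.Series:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]
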
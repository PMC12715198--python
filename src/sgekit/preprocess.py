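"""From raw count tables to analysis-ready phenotype vectors.

The pipeline: depth-based sample filtering, taxonomy collapsing, the
centred log-ratio (CLR) transform for compositionality, prevalence
filtering per cohort, then rank-based inverse-normal transformation with
random tie-breaking and residualization on technical covariates. The
residuals are the phenotypes fed to the variance-component models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable

__all__ = [
    "filter_by_depth",
    "clr_transform",
    "collapse_taxonomy",
    "prevalence_filter",
    "normalize_and_residualize",
    "PhenotypeVector",
]

_RANKS = {"kingdom": "k", "phylum": "p", "class": "c", "order": "o",
          "family": "f", "genus": "g", "species": "s"}


@dataclass
class PhenotypeVector:
    """A per-sample phenotype with its provenance.

    ``values`` is indexed by sample; ``provenance`` records the taxon, the
    transformation chain applied and the seed used for random tie-breaks,
    so the stochastic normalisation step is reproducible.
    """

    values: pd.Series
    taxon: str = ""
    cohort: str = ""
    transform_chain: list[str] = field(default_factory=list)
    seed: int | None = None
    n_dropped: int = 0


def filter_by_depth(table: AbundanceTable, k: float = 2.0) -> pd.Index:
    """Samples whose depth lies within mean +/- k standard deviations.

    Library-size outliers in either direction distort compositional
    analyses; the mean and (population) standard deviation are computed on
    all input samples.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate the depth spread")
    depth = table.depth.astype(float)
    mu, sd = depth.mean(), depth.std(ddof=1)
    keep = (depth >= mu - k * sd) & (depth <= mu + k * sd)
    return table.counts.index[keep]


def clr_transform(
    table: AbundanceTable, zero_replacement: float = 1e-5
) -> pd.DataFrame:
    """Centred log-ratio transform of each sample's composition.

    Counts are closed to relative abundances per sample; zeros are then
    replaced by ``zero_replacement`` (on the relative-abundance scale,
    making the replacement depth-independent) and each value is logged
    against the geometric mean of the sample's values. Rows with no
    replaced zeros sum to 0 exactly.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = table.counts.index[totals == 0].tolist()
        raise ValueError(f"all-zero samples cannot be CLR-transformed: {bad}")
    rel = counts / totals[:, None]
    rel = np.where(rel == 0.0, zero_replacement, rel)
    log_rel = np.log(rel)
    clr = log_rel - log_rel.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)


def _lineage_at(lineage: str, level: str) -> str | None:
    prefix = _RANKS[level] + "__"
    fields = [f.strip() for f in str(lineage).split(";")]
    for i, f in enumerate(fields):
        if f.startswith(prefix):
            name = f[len(prefix):]
            if name:
                # full lineage up to the requested rank keeps groups unique
                return "; ".join(fields[: i + 1])
    return None


def collapse_taxonomy(table: AbundanceTable, level: str) -> AbundanceTable:
    """Sum counts of taxa sharing a lineage at the requested rank.

    Taxa whose lineage has no assignment at that rank are pooled into an
    explicit ``unassigned`` group. Per-sample totals are conserved.
    """
    if level not in _RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}; one of {sorted(_RANKS)}")
    groups = {
        taxon: (_lineage_at(table.taxonomy[taxon], level) or "unassigned")
        for taxon in table.counts.columns
    }
    collapsed = table.counts.T.groupby(pd.Series(groups)).sum().T
    taxonomy = pd.Series(
        {g: (g if g != "unassigned" else "unassigned") for g in collapsed.columns}
    )
    return AbundanceTable(collapsed, taxonomy)


def prevalence_filter(
    table: AbundanceTable,
    threshold: float = 0.5,
    group: pd.Series | None = None,
) -> dict[str, pd.Index]:
    """Taxa present (nonzero raw count) in at least ``threshold`` of a group.

    Presence is judged on raw counts, never on CLR values (whose zero
    replacement would make every taxon "present"). Returns the retained
    taxa per group label; with no grouping all samples form one group.
    """
    counts = table.counts
    if group is None:
        group = pd.Series("all", index=counts.index)
    group = group.reindex(counts.index)
    out: dict[str, pd.Index] = {}
    for label, idx in counts.groupby(group).groups.items():
        sub = counts.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"group {label!r} contains no samples")
        prevalence = (sub > 0).mean(axis=0)
        out[str(label)] = counts.columns[prevalence >= threshold]
    return out


def rank_inverse_normal(
    y: pd.Series, seed: int = 0, offset: float = 0.5
) -> pd.Series:
    """Rank-based inverse-normal transform with random tie-breaking.

    Ranks use the Blom-type offset (rank - offset) / n; ties are resolved
    by a seeded random permutation so repeated values receive distinct
    normal quantiles.
    """
    rng = np.random.default_rng(seed)
    vals = y.to_numpy(dtype=float)
    n = vals.size
    shuffle = rng.permutation(n)
    order = shuffle[np.argsort(vals[shuffle], kind="stable")]
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    z = stats.norm.ppf((ranks - offset) / n)
    return pd.Series(z, index=y.index)


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def normalize_and_residualize(
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    seed: int = 0,
    taxon: str = "",
    cohort: str = "",
) -> PhenotypeVector:
    """Quantile-normalise then regress out technical covariates.

    Samples with any missing covariate are dropped (and counted in the
    returned provenance). Categorical covariates are one-hot encoded;
    redundant columns in a rank-deficient encoded design are dropped with
    a warning. Returns the OLS residuals of the normalised phenotype.
    """
    y = y.dropna()
    chain = ["rank_inverse_normal"]
    if covariates is not None:
        covariates = covariates.reindex(y.index)
        complete = covariates.notna().all(axis=1)
        n_dropped = int((~complete).sum())
        y = y[complete]
        covariates = covariates[complete]
    else:
        n_dropped = 0

    z = rank_inverse_normal(y, seed=seed)

    if covariates is not None and covariates.shape[1] > 0:
        Xdf = _encode_covariates(covariates)
        X = Xdf.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # drop dependent columns via pivoted QR
            from scipy.linalg import qr as _qr

            _, _, piv = _qr(X, pivoting=True)
            keep = np.sort(piv[:rank])
            dropped_cols = [Xdf.columns[j] for j in range(X.shape[1]) if j not in keep]
            warnings.warn(
                f"covariate design rank-deficient; dropping columns {dropped_cols}",
                stacklevel=2,
            )
            X = X[:, keep]
        beta, *_ = np.linalg.lstsq(X, z.to_numpy(), rcond=None)
        resid = z.to_numpy() - X @ beta
        z = pd.Series(resid, index=z.index)
        chain.append("ols_residualize")

    return PhenotypeVector(
        values=z,
        taxon=taxon,
        cohort=cohort,
        transform_chain=chain,
        seed=seed,
        n_dropped=n_dropped,
    )
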
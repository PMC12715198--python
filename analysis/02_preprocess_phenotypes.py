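"""Turn the simulated count table into analysis-ready phenotypes.

Reads the study written by 01_simulate_study.py and applies the
preprocessing chain: depth-based sample filtering (mean +/- 2 sd of
library size), family-level taxonomy collapsing for the profile table,
centred log-ratio transformation (zeros replaced by 1e-5 on the
relative-abundance scale), prevalence filtering (taxa present in at
least 50% of samples), then rank-based inverse-normal transformation
with seeded random tie-breaking and residualization on sex, batch and
library size. Writes the phenotype matrix and its provenance.
"""

from pathlib import Path

import pandas as pd

import sgekit as sk
from sgekit import io as skio

BASE = Path(__file__).resolve().parents[1] / "results" / "synthetic_study"
OUT = Path(__file__).resolve().parents[1] / "results"

counts = skio.read_counts(BASE / "counts.tsv", BASE / "taxonomy.tsv")
metadata = skio.read_design_metadata(BASE / "design.tsv").set_index("sample")

kept_samples = sk.filter_by_depth(counts, k=2.0)
print(f"depth filter: kept {len(kept_samples)}/{counts.n_samples} samples")
counts = sk.AbundanceTable(counts.counts.loc[kept_samples], counts.taxonomy)

kept_taxa = sk.prevalence_filter(counts, threshold=0.5)["all"]
print(f"prevalence filter (>=50%): kept {len(kept_taxa)}/{counts.n_taxa} taxa")
counts = sk.AbundanceTable(counts.counts[kept_taxa], counts.taxonomy[kept_taxa])

clr = sk.clr_transform(counts, zero_replacement=1e-5)

metadata = metadata.loc[clr.index]
covariates = pd.DataFrame(
    {
        "sex": metadata["sex"],
        "batch": (pd.util.hash_pandas_object(metadata.index.to_series()) % 3).map(
            {0: "b0", 1: "b1", 2: "b2"}
        ),
        "library_size": counts.depth.astype(float),
    }
)

phenos = {}
for taxon in clr.columns:
    phe = sk.normalize_and_residualize(
        clr[taxon], covariates, seed=17, taxon=taxon
    )
    phenos[taxon] = phe.values
pheno_df = pd.DataFrame(phenos)
pheno_df.to_csv(OUT / "phenotypes.tsv", sep="\t", index_label="sample")

with open(OUT / "phenotypes.provenance.txt", "w") as fh:
    fh.write(
        "transform chain: relative abundance -> CLR(zero_replacement=1e-5) "
        "-> rank inverse normal (seed=17, random tie-break) -> OLS residuals "
        "on sex + batch + library_size\n"
        f"samples kept after depth filter: {len(kept_samples)}\n"
        f"taxa kept after prevalence filter: {len(kept_taxa)}\n"
    )
print(f"wrote {pheno_df.shape[1]} phenotypes x {pheno_df.shape[0]} samples "
      f"to {OUT / 'phenotypes.tsv'}")
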
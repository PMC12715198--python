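"""Plain-text interchange: VCF, transposed dosage tables, TSV, GRM files.

Everything round-trips through uncompressed text so simulated studies can
be inspected, versioned and re-read by standard tools (bcftools, PLINK,
R). The GRM writer mirrors the square whitespace-delimited matrix plus
``.id`` sidecar convention of ``plink --make-rel square``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceTable, GenotypeMatrix, KinshipMatrix, StudyDesign
from .sim import SimTruth

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_traw",
    "read_traw",
    "write_design",
    "read_design_metadata",
    "write_counts",
    "read_counts",
    "write_grm",
    "read_grm",
    "write_truth",
    "read_truth",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal GT-only VCF over the 20 autosomes."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in range(1, 21):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        dosages = G.dosages
        for j, row in enumerate(G.variants.itertuples(index=False)):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in dosages[:, j]
            )
            fh.write(
                f"{int(row.chrom)}\t{int(row.pos)}\t{row.id}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-coded VCF back into a dosage matrix.

    Uses cyvcf2 when importable (the robust general reader); falls back
    to a minimal parser good for files this package writes.
    """
    path = str(path)
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is normally present
        return _read_vcf_text(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, poss, ids, cols = [], [], [], []
    for var in vcf:
        chroms.append(int(var.CHROM))
        poss.append(int(var.POS))
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        gts = np.asarray(var.genotype.array())[:, :2].astype(float)
        gts[gts < 0] = np.nan
        cols.append(gts.sum(axis=1))
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})
    return GenotypeMatrix(dosages, variants, samples=samples)


def _read_vcf_text(path: str) -> GenotypeMatrix:
    samples: list[str] = []
    chroms, poss, ids, cols = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chroms.append(int(fields[0]))
            poss.append(int(fields[1]))
            ids.append(fields[2])
            col = []
            for call in fields[9:]:
                gt = call.split(":")[0]
                if "." in gt:
                    col.append(np.nan)
                else:
                    col.append(float(sum(int(a) for a in gt.replace("|", "/").split("/"))))
            cols.append(col)
    dosages = np.array(cols, dtype=float).T if cols else np.empty((len(samples), 0))
    variants = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})
    return GenotypeMatrix(dosages, variants, samples=samples)


def write_traw(G: GenotypeMatrix, path: str | Path) -> None:
    """PLINK-style transposed dosage text table (one row per variant)."""
    df = pd.DataFrame(
        {
            "CHR": G.variants["chrom"].to_numpy(),
            "SNP": G.variants["id"].to_numpy(),
            "CM": 0,
            "POS": G.variants["pos"].to_numpy(),
            "COUNTED": "G",
            "ALT": "A",
        }
    )
    dos = pd.DataFrame(G.dosages.T, columns=G.samples)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_traw(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["CHR", "SNP", "CM", "POS", "COUNTED", "ALT"]
    samples = [c for c in df.columns if c not in meta_cols]
    variants = pd.DataFrame(
        {"chrom": df["CHR"].to_numpy(), "pos": df["POS"].to_numpy(), "id": df["SNP"].to_numpy()}
    )
    return GenotypeMatrix(df[samples].to_numpy(float).T, variants, samples=samples)


def write_design(design: StudyDesign, path: str | Path) -> None:
    """Sample metadata TSV (sample, cage, mother, cohort, sex, ...)."""
    md = design.metadata
    if md is None:
        raise ValueError("design carries no metadata table")
    md.to_csv(path, sep="\t", index=False)


def read_design_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(table: AbundanceTable, counts_path: str | Path, taxonomy_path: str | Path) -> None:
    """Counts as samples x taxa TSV plus a taxonomy sidecar TSV."""
    table.counts.to_csv(counts_path, sep="\t", index_label="sample")
    table.taxonomy.rename("lineage").to_csv(taxonomy_path, sep="\t", index_label="taxon")


def read_counts(counts_path: str | Path, taxonomy_path: str | Path) -> AbundanceTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample").rename_axis(None)
    taxonomy = (
        pd.read_csv(taxonomy_path, sep="\t", index_col="taxon")["lineage"]
        .rename_axis(None)
        .rename(None)
    )
    return AbundanceTable(counts, taxonomy)


def write_grm(K: KinshipMatrix, path: str | Path) -> None:
    """Square whitespace-delimited matrix plus an ``.id`` sidecar."""
    path = Path(path)
    np.savetxt(path, K.A, fmt="%.10g", delimiter="\t")
    with path.with_suffix(path.suffix + ".id").open("w") as fh:
        for s in K.samples:
            fh.write(f"{s}\t{s}\n")


def read_grm(path: str | Path, loco_chrom: int | None = None) -> KinshipMatrix:
    path = Path(path)
    A = np.loadtxt(path, delimiter="\t")
    id_path = path.with_suffix(path.suffix + ".id")
    samples = []
    if id_path.exists():
        samples = [line.split("\t")[0] for line in id_path.read_text().splitlines()]
    return KinshipMatrix(A, loco_chrom=loco_chrom, samples=samples)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Plain-text snapshot of the generating parameters."""
    d = asdict(truth)
    d["maf_range"] = list(d["maf_range"])
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_truth(path: str | Path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    d["maf_range"] = tuple(d["maf_range"])
    if isinstance(d["cage_size"], dict):
        d["cage_size"] = {int(k): v for k, v in d["cage_size"].items()}
    return SimTruth(**d)
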
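"""Readers and writers for the pipeline's plain-text exchange formats.

Genotypes travel as a minimal VCF v4.2 (GT-only, diploid, unphased) or as a
dosage TSV (individuals x variants, with a variant-metadata sidecar);
summary-statistic weights as TSV with the conventional column header;
phenotypes as CSV with treatment histories JSON-encoded in one column.
VCF reading goes through cyvcf2.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_weights_tsv",
    "read_weights_tsv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
]

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}

WEIGHT_COLUMNS = ["variant_id", "chr", "pos", "effect_allele", "other_allele", "beta", "p"]


def write_vcf(genotypes: GenotypeMatrix, path: str | Path, header_comment: str | None = None) -> None:
    """Write a minimal VCF v4.2 with unphased GT calls only."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=psygrs\n")
        if header_comment:
            fh.write(f"##{header_comment}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n##contig=<ID=2>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.samples) + "\n")
        for j, var in genotypes.variants.iterrows():
            calls = [
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{var.chrom}\t{int(var.pos)}\t{var.variant_id}\t{var.ref}\t{var.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (possibly minimal) VCF into a dosage matrix via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    mapping = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        rows.append(mapping[var.gt_types])
    variants = pd.DataFrame(
        {"variant_id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path, variants_path: str | Path | None = None) -> None:
    """Write dosages as individuals x variants TSV plus a metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.samples, name="individual_id"),
        columns=genotypes.variants["variant_id"],
    )
    df.to_csv(path, sep="\t")
    if variants_path is None:
        variants_path = path.with_suffix(".variants.tsv")
    genotypes.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path, variants_path: str | Path | None = None) -> GenotypeMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if variants_path is None:
        variants_path = path.with_suffix(".variants.tsv")
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    return GenotypeMatrix(samples=list(df.index), variants=variants, dosages=df.to_numpy(dtype=float))


def write_weights_tsv(stats_table: pd.DataFrame, path: str | Path) -> None:
    """Write summary statistics with the conventional 7-column header."""
    out = stats_table.rename(columns={"chrom": "chr", "p_value": "p"})[WEIGHT_COLUMNS]
    out.to_csv(path, sep="\t", index=False)


def read_weights_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weights file missing columns: {sorted(missing)}")
    return df.rename(columns={"chr": "chrom", "p": "p_value"})


def write_phenotypes_csv(phenotypes: pd.DataFrame, path: str | Path) -> None:
    out = phenotypes.copy()
    if "treatment_history" in out.columns:
        out["treatment_history"] = out["treatment_history"].map(json.dumps)
    out.to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"treatment_arm": str})
    if "treatment_history" in df.columns:
        df["treatment_history"] = df["treatment_history"].map(json.loads)
    return df
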
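"""Readers and writers for the plain-text interchange formats.

Per-position read counts travel as a TSV with header
``chrom  pos  sample_1 ... sample_n`` (1-based inclusive positions);
genotypes as VCF (read through cyvcf2, written as minimal uncompressed
VCF 4.2) or as a samples-by-SNPs TSV whose header row carries the SNP
positions; gene regions as BED (0-based half-open, converted to the
package's 1-based inclusive convention on read).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .curves import PositionCurve
from .genotypes import GenotypeMatrix

__all__ = [
    "read_position_counts",
    "write_position_counts",
    "read_bed",
    "read_covariates",
    "read_genotype_table",
    "write_genotype_table",
    "write_vcf",
]


def read_position_counts(
    path: str, region: tuple[str, int, int] | None = None
) -> PositionCurve:
    """Read a per-position count TSV into a curve (samples as rows)."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "chrom" or df.columns[1] != "pos":
        raise ValueError("expected header starting with 'chrom\\tpos'")
    chrom = str(df["chrom"].iloc[0])
    positions = df["pos"].to_numpy(dtype=float)
    values = df.iloc[:, 2:].to_numpy(dtype=float).T
    if region is None:
        region = (chrom, int(positions[0]), int(positions[-1]))
    return PositionCurve(positions, values, region=region)


def write_position_counts(
    curve: PositionCurve, path: str, sample_names: list[str] | None = None
) -> None:
    n = curve.n_samples
    names = sample_names or [f"sample_{i + 1}" for i in range(n)]
    chrom = curve.region[0] if curve.region else "."
    df = pd.DataFrame({"chrom": chrom, "pos": curve.positions})
    for name, row in zip(names, curve.values):
        df[name] = row
    df.to_csv(path, sep="\t", index=False)


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """BED regions as (chrom, start_1based, end, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            out.append((chrom, start + 1, end, name))
    return out


def read_covariates(path: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float)


def read_genotype_table(path: str, region: tuple[str, int, int] | None = None) -> GenotypeMatrix:
    """Samples-by-SNPs TSV of minor-allele counts; header = positions."""
    df = pd.read_csv(path, sep="\t")
    positions = np.array([int(c) for c in df.columns])
    counts = df.to_numpy(dtype=int)
    if region is None:
        region = (".", int(positions[0]), int(positions[-1]))
    return GenotypeMatrix(counts, positions, region=region)


def write_genotype_table(g: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(g.counts, columns=[str(p) for p in g.positions])
    df.to_csv(path, sep="\t", index=False)


def write_vcf(
    g: GenotypeMatrix, path: str, sample_names: list[str] | None = None
) -> None:
    """Write counts as a minimal uncompressed VCF 4.2 (GT field only).

    The minor allele is written as ALT, so a re-read reproduces the counts.
    """
    n = g.n_samples
    names = sample_names or [f"S{i + 1}" for i in range(n)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    chrom = g.region[0]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for j in range(g.n_snps):
            gts = "\t".join(gt_map[int(c)] for c in g.counts[:, j])
            fh.write(
                f"{chrom}\t{int(g.positions[j])}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )
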
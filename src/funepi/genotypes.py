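"""Genotype ingestion, QC, frequency-centered encoding, scores and LD.

Genotypes for a gene region are minor-allele counts in {0, 1, 2}.  For the
functional tests each SNP column is recoded by the frequency-centered map

    MM (0 copies of the minor allele m) -> 2 * P_m
    Mm (1 copy)                         -> P_m - P_M
    mm (2 copies)                       -> -2 * P_M

whose population mean is exactly zero under Hardy-Weinberg equilibrium.  A
sample's encoded vector, indexed by the SNP positions remapped into [0, 1],
is treated as a genotype "function" and expanded by FPCA to give the score
matrices entering the regression design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy import stats

from .curves import PositionCurve, ScoreMatrix, fit_fpca

__all__ = [
    "GenotypeMatrix",
    "EncodedGenotypes",
    "QCReport",
    "read_vcf_region",
    "hwe_exact_pvalue",
    "qc_filter",
    "encode",
    "genotype_scores",
    "max_r2",
]


@dataclass
class GenotypeMatrix:
    """n x p minor-allele counts with 1-based positions and sample MAFs."""

    counts: np.ndarray
    positions: np.ndarray
    region: tuple[str, int, int]
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        self.positions = np.asarray(self.positions)
        if self.counts.shape[1] != self.positions.size:
            raise ValueError("one position per SNP column required")
        if self.counts.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.maf is None:
            self.maf = (
                self.counts.mean(axis=0) / 2.0
                if self.counts.size
                else np.empty(0)
            )
        self.maf = np.asarray(self.maf, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.n_snps == 0


@dataclass
class EncodedGenotypes:
    """Frequency-centered genotype values, one column per SNP."""

    values: np.ndarray
    source: GenotypeMatrix
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class QCReport:
    """Per-SNP removal record from :func:`qc_filter`."""

    removed: list[tuple[int, str]] = field(default_factory=list)  # (pos, why)
    n_in: int = 0
    n_out: int = 0

    def count(self, reason: str) -> int:
        return sum(1 for _, why in self.removed if why == reason)


def read_vcf_region(
    path: str, region: tuple[str, int, int]
) -> GenotypeMatrix:
    """Read diploid biallelic SNP genotypes from a VCF region.

    Non-biallelic records are skipped.  Missing genotypes are imputed to the
    per-SNP mean allele count (rounded when building the count matrix would
    lose the {0,1,2} invariant is avoided by keeping floats only internally:
    imputed entries are rounded to the nearest count).  The minor allele is
    oriented so every column has maf <= 0.5.
    """
    from cyvcf2 import VCF

    chrom, start, end = region
    vcf = VCF(path)
    cols: list[np.ndarray] = []
    pos: list[int] = []
    # linear scan: works on plain uncompressed VCF without a tabix index
    for rec in vcf:
        if rec.CHROM != chrom or not start <= rec.POS <= end:
            continue
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(cyvcf2: 3), 2=unknown
        g = np.asarray(rec.genotypes, dtype=object)
        alt = np.full(len(g), -1, dtype=float)
        for i, call in enumerate(g):
            a = [x for x in call[:-1] if x is not None and x >= 0]
            if len(a) != 2:
                continue
            if any(x > 1 for x in a):
                raise ValueError(
                    f"malformed GT at {rec.CHROM}:{rec.POS}: {call}"
                )
            alt[i] = sum(a)
        miss = alt < 0
        if miss.all():
            continue
        if miss.any():
            alt[miss] = np.round(alt[~miss].mean())
        cols.append(alt)
        pos.append(rec.POS)
    if not cols:
        return GenotypeMatrix(
            np.empty((0, 0), dtype=int), np.empty(0, dtype=int), region
        )
    counts = np.column_stack(cols).astype(int)
    positions = np.asarray(pos, dtype=int)
    order = np.argsort(positions, kind="stable")
    counts, positions = counts[:, order], positions[order]
    # keep the first record at a duplicated position (qc_filter's rule);
    # the container requires strictly increasing positions
    keep = np.concatenate(([True], np.diff(positions) > 0))
    counts, positions = counts[:, keep], positions[keep]
    # orient to minor allele
    freq = counts.mean(axis=0) / 2.0
    flip = freq > 0.5
    counts[:, flip] = 2 - counts[:, flip]
    return GenotypeMatrix(counts, positions, region)


def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value for one biallelic SNP.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the conditional probabilities not exceeding that of the
    observed table (the standard exact HWE test used for sequencing QC).
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0 or n_minor == 0 or n_minor == 2 * n:
        return 1.0

    def logprob(h: int) -> float:
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        return (
            lgamma(n + 1)
            - lgamma(h + 1)
            - lgamma(hom_min + 1)
            - lgamma(hom_maj + 1)
            + h * np.log(2.0)
            + lgamma(n_minor + 1)
            + lgamma(2 * n - n_minor + 1)
            - lgamma(2 * n + 1)
        )

    hs = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logps = np.array([logprob(int(h)) for h in hs])
    obs = logprob(n_het)
    p = float(np.exp(logps[logps <= obs + 1e-12]).sum())
    return min(p, 1.0)


def qc_filter(
    g: GenotypeMatrix,
    hwe_alpha: float = 1e-9,
    drop_singletons: bool = True,
    drop_duplicates: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove singleton SNPs, duplicated positions and HWE-violating SNPs.

    A singleton carries its minor allele exactly once in the sample.  SNPs at
    a previously seen position are dropped (first kept).  The exact HWE test
    removes SNPs with p < ``hwe_alpha`` (default 1e-9).
    """
    if g.n_samples < 2:
        raise ValueError("qc_filter needs at least two samples")
    report = QCReport(n_in=g.n_snps)
    keep = np.ones(g.n_snps, dtype=bool)
    seen: set[int] = set()
    for j in range(g.n_snps):
        pos = int(g.positions[j])
        col = g.counts[:, j]
        minor_count = int(col.sum())
        if minor_count > g.n_samples:  # oriented: should not happen, guard
            minor_count = 2 * g.n_samples - minor_count
        if drop_duplicates and pos in seen:
            keep[j] = False
            report.removed.append((pos, "duplicate"))
            continue
        seen.add(pos)
        if drop_singletons and minor_count == 1:
            keep[j] = False
            report.removed.append((pos, "singleton"))
            continue
        n_het = int(np.sum(col == 1))
        n_hom_minor = int(np.sum(col == 2))
        n_hom_major = int(np.sum(col == 0))
        if hwe_exact_pvalue(n_het, n_hom_minor, n_hom_major) < hwe_alpha:
            keep[j] = False
            report.removed.append((pos, "hwe"))
    out = GenotypeMatrix(
        g.counts[:, keep], g.positions[keep], g.region, maf=g.maf[keep]
    )
    report.n_out = out.n_snps
    return out, report


def encode(g: GenotypeMatrix) -> EncodedGenotypes:
    """Frequency-centered genotype encoding {2P_m, P_m - P_M, -2P_M}.

    Allele frequencies are estimated from the sample itself.  Monomorphic
    columns encode to all zeros and are flagged.
    """
    p_m = g.maf
    p_M = 1.0 - p_m
    counts = g.counts
    values = np.empty(counts.shape, dtype=float)
    values[counts == 0] = np.broadcast_to(2.0 * p_m, counts.shape)[counts == 0]
    values[counts == 1] = np.broadcast_to(p_m - p_M, counts.shape)[counts == 1]
    values[counts == 2] = np.broadcast_to(-2.0 * p_M, counts.shape)[counts == 2]
    mono = p_m == 0.0
    values[:, mono] = 0.0
    return EncodedGenotypes(values, g, monomorphic=mono)


def genotype_scores(
    e: EncodedGenotypes,
    n_components: int | None = None,
    var_threshold: float | None = None,
) -> ScoreMatrix:
    """FPCA scores of the genotype functions.

    SNP positions are mapped affinely into [0, 1] over the gene region and
    each sample's encoded vector is treated as function values at those
    (generally non-uniform) points; trapezoid weights at the SNP positions
    serve as the quadrature rule.
    """
    g = e.source
    if g.n_snps < 1:
        raise ValueError("no SNPs to score")
    curve = PositionCurve(
        g.positions.astype(float), e.values, region=g.region
    )
    curve = PositionCurve(
        curve.normalized_positions(), e.values, region=(g.region[0], 0, 1)
    )
    _, scores = fit_fpca(
        curve, n_components=n_components, var_threshold=var_threshold
    )
    return scores


def max_r2(
    g1: GenotypeMatrix, g2: GenotypeMatrix
) -> tuple[float, tuple[int, int], float]:
    """Maximum squared Pearson correlation over all cross-gene SNP pairs.

    Returns (r2_max, (pos1, pos2), p_value) where the p-value is the
    correlation test at the maximizing pair.  Monomorphic columns are
    skipped; if everything is skipped, (nan, (-1, -1), nan) is returned.
    """
    if g1.n_samples != g2.n_samples:
        raise ValueError("sample sets differ")
    a = g1.counts.astype(float)
    b = g2.counts.astype(float)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    ok1, ok2 = sa > 0, sb > 0
    if not ok1.any() or not ok2.any():
        return float("nan"), (-1, -1), float("nan")
    ac = (a[:, ok1] - a[:, ok1].mean(axis=0)) / sa[ok1]
    bc = (b[:, ok2] - b[:, ok2].mean(axis=0)) / sb[ok2]
    n = a.shape[0]
    r = (ac.T @ bc) / n
    r2 = r**2
    i, j = np.unravel_index(np.argmax(r2), r2.shape)
    pos1 = int(g1.positions[np.flatnonzero(ok1)[i]])
    pos2 = int(g2.positions[np.flatnonzero(ok2)[j]])
    rbest = float(np.clip(r[i, j], -1.0, 1.0))
    if abs(rbest) >= 1.0:
        pval = 0.0
    else:
        tstat = rbest * np.sqrt((n - 2) / (1.0 - rbest**2))
        pval = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return float(r2[i, j]), (pos1, pos2), pval
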
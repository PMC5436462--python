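"""RNA-seq normalization and scalar expression summaries.

Median-of-ratios size factors, RPKM, the expressing-rate gene filter and the
rank-based inverse normal transform.  These supply the scalar response used
by the scalar-trait comparator test and the optional depth normalization of
per-position curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .curves import PositionCurve

__all__ = [
    "CountTable",
    "ScalarTrait",
    "size_factors",
    "rpkm",
    "expressing_rate_filter",
    "inverse_normal",
]


@dataclass
class CountTable:
    """n samples x G genes of nonnegative integer read counts."""

    counts: np.ndarray
    gene_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("gene lengths must be positive")
        if self.counts.shape[1] != self.gene_lengths.size:
            raise ValueError("one length per gene required")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ScalarTrait:
    """Per-sample scalar phenotype with a record of the transform applied."""

    values: np.ndarray
    transform_applied: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")


def size_factors(ct: CountTable) -> np.ndarray:
    """Median-of-ratios per-sample size factors.

    The reference for each gene is the geometric mean of its counts across
    samples; genes with any zero count are excluded from the reference set.
    s_i is the median over reference genes of counts[i, g] / geomean_g, with
    no global rescaling.
    """
    counts = ct.counts
    ref = np.all(counts > 0, axis=0)
    if not ref.any():
        raise ValueError(
            "no gene has all-positive counts; size factors undefined "
            "(consider a pseudo-reference fallback)"
        )
    sub = counts[:, ref]
    geo = np.exp(np.mean(np.log(sub), axis=0))
    return np.median(sub / geo, axis=1)


def rpkm(ct: CountTable) -> np.ndarray:
    """Reads per kilobase per million mapped reads: 1e9 * c / (len * lib)."""
    lib = ct.library_sizes
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    return 1e9 * ct.counts / (ct.gene_lengths[None, :] * lib[:, None])


def expressing_rate_filter(
    curves: list[PositionCurve], min_rate: float = 0.30
) -> tuple[list[int], list[tuple[int, float]]]:
    """Retain genes whose expressing rate reaches ``min_rate`` (inclusive).

    A sample "expresses" a gene when its total count over the gene's
    positions is nonzero.  Returns (retained gene indices, per-gene report of
    (index, rate)).
    """
    retained: list[int] = []
    report: list[tuple[int, float]] = []
    for k, c in enumerate(curves):
        rate = float(np.mean(c.values.sum(axis=1) != 0))
        report.append((k, rate))
        if rate >= min_rate:
            retained.append(k)
    return retained, report


def inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> ScalarTrait:
    """Rank-based inverse normal transform with Blom offset by default.

    value_i -> Phi^{-1}((rank_i - c) / (n - 2c + 1)) with average ranks on
    ties.  Undefined (raises) when all values are identical.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.all(values == values[0]):
        raise ValueError("all values identical: transform undefined")
    ranks = stats.rankdata(values, method="average")
    q = (ranks - offset) / (n - 2.0 * offset + 1.0)
    return ScalarTrait(stats.norm.ppf(q), transform_applied="inverse-normal")
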
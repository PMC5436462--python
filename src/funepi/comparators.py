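"""Baseline interaction tests the functional-response test is compared to.

* ``sfgm_test`` — scalar response (an overall expression summary), functional
  genotype predictors; the design is identical to the functional-response
  test with K = 1.
* ``rnamin_test`` — the scalar-response test run at every grid position of
  the curve, reporting the raw minimum p-value.
* ``minp_pairwise`` — the functional-response model fitted for every
  cross-gene SNP pair with the two encoded SNPs and their product as scalar
  predictors, reporting the raw minimum p-value over pairs.
* ``pca_regression_test`` — ordinary PCA of the position-by-sample count
  matrix (components to 80% variance) as the multivariate response, with the
  same genotype-score predictors.
"""

from __future__ import annotations

import numpy as np

from .bfgm import (
    BfgmConfig,
    InteractionResult,
    _select_components,
    build_design,
    fit,
    interaction_test,
    response_scores,
    trailing_block_test,
)
from .curves import PositionCurve
from .expression import ScalarTrait, inverse_normal
from .genotypes import GenotypeMatrix, encode, genotype_scores

__all__ = [
    "sfgm_test",
    "rnamin_test",
    "minp_pairwise",
    "pca_regression_test",
    "scalar_trait_from_curves",
]


def _genotype_design_scores(
    gene1: GenotypeMatrix,
    gene2: GenotypeMatrix,
    config: BfgmConfig,
    extra_evals: np.ndarray | None = None,
):
    """Genotype score matrices plus (J, L[, K]) chosen by explained variance."""
    xi_full = genotype_scores(encode(gene1))
    eta_full = genotype_scores(encode(gene2))
    evs = [xi_full.basis.eigenvalues, eta_full.basis.eigenvalues]
    if extra_evals is not None:
        evs.append(extra_evals)
    ks = _select_components(
        evs, config.var_explained, config.max_components, gene1.n_samples
    )
    return xi_full, eta_full, ks


def scalar_trait_from_curves(
    trait_curves: PositionCurve,
    sample_scale: np.ndarray | None = None,
    transform: bool = True,
) -> ScalarTrait:
    """Overall expression per sample: (normalized) total count over the gene.

    The default scalar trait is the size-factor-normalized total, passed
    through the rank-based inverse normal transform.
    """
    totals = trait_curves.values.sum(axis=1)
    if sample_scale is not None:
        totals = totals / np.asarray(sample_scale, dtype=float)
    if transform:
        return inverse_normal(totals)
    return ScalarTrait(totals)


def sfgm_test(
    gene1: GenotypeMatrix,
    gene2: GenotypeMatrix,
    trait: ScalarTrait,
    W: np.ndarray | None = None,
    config: BfgmConfig | None = None,
) -> InteractionResult:
    """Scalar-response interaction test (identical design, K forced to 1)."""
    config = config or BfgmConfig()
    xi_full, eta_full, (J, L) = _genotype_design_scores(gene1, gene2, config)
    design = build_design(
        xi_full.scores[:, :J], eta_full.scores[:, :L], W
    )
    fit_result = fit(design, trait.values[:, None])
    res = interaction_test(fit_result, design)
    res.J, res.L, res.K = J, L, 1
    return res


def rnamin_test(
    gene1: GenotypeMatrix,
    gene2: GenotypeMatrix,
    trait_curves: PositionCurve,
    W: np.ndarray | None = None,
    config: BfgmConfig | None = None,
) -> tuple[float, float]:
    """Minimum scalar-response interaction p over grid positions (raw).

    Returns (min_p, argmin position).  Positions whose read counts do not
    vary across samples are skipped; no multiplicity correction is applied.
    """
    config = config or BfgmConfig()
    xi_full, eta_full, (J, L) = _genotype_design_scores(gene1, gene2, config)
    design = build_design(xi_full.scores[:, :J], eta_full.scores[:, :L], W)
    best_p, best_pos = np.inf, float("nan")
    for g in range(trait_curves.positions.size):
        y = trait_curves.values[:, g]
        if np.std(y) == 0:
            continue
        fit_result = fit(design, y[:, None])
        res = trailing_block_test(fit_result, J * L)
        if res.p_value < best_p:
            best_p, best_pos = res.p_value, float(trait_curves.positions[g])
    if not np.isfinite(best_p):
        raise ValueError("every position has zero variance")
    return float(best_p), best_pos


def minp_pairwise(
    gene1: GenotypeMatrix,
    gene2: GenotypeMatrix,
    trait_curves: PositionCurve,
    W: np.ndarray | None = None,
    config: BfgmConfig | None = None,
    sample_scale: np.ndarray | None = None,
) -> tuple[float, tuple[int, int]]:
    """Minimum functional-response p over all cross-gene SNP pairs (raw).

    Each pair is tested with the two frequency-centered SNP codes and their
    product as scalar predictors; the Wald test on the product term has
    df = K.  Monomorphic SNPs are skipped.
    """
    config = config or BfgmConfig()
    scale = sample_scale if config.normalize_curves else None
    y_full, y_evals = response_scores(trait_curves, config, scale)
    total = y_evals.sum()
    frac = np.cumsum(y_evals) / total if total > 0 else np.ones(1)
    K = int(np.searchsorted(frac, config.var_explained - 1e-12) + 1)
    K = min(K, y_evals.size)
    Y = y_full.scores[:, :K]
    e1, e2 = encode(gene1), encode(gene2)
    best_p, best_pair = np.inf, (-1, -1)
    for a in range(gene1.n_snps):
        if e1.monomorphic[a]:
            continue
        x = e1.values[:, a : a + 1]
        for b in range(gene2.n_snps):
            if e2.monomorphic[b]:
                continue
            z = e2.values[:, b : b + 1]
            design = build_design(x, z, W)
            fit_result = fit(design, Y)
            res = trailing_block_test(fit_result, 1)
            if res.p_value < best_p:
                best_p = res.p_value
                best_pair = (int(gene1.positions[a]), int(gene2.positions[b]))
    if not np.isfinite(best_p):
        raise ValueError("all SNP pairs monomorphic")
    return float(best_p), best_pair


def pca_regression_test(
    gene1: GenotypeMatrix,
    gene2: GenotypeMatrix,
    trait_curves: PositionCurve,
    W: np.ndarray | None = None,
    var_explained: float = 0.8,
    config: BfgmConfig | None = None,
    sample_scale: np.ndarray | None = None,
) -> InteractionResult:
    """Regression on principal components of the read-count matrix.

    The response is the matrix of PC scores retaining the smallest number of
    components whose cumulative variance reaches ``var_explained``; the
    genotype predictors and the interaction Wald test are shared with the
    functional-response pipeline.
    """
    config = config or BfgmConfig()
    X = trait_curves.values
    if config.normalize_curves and sample_scale is not None:
        X = X / np.asarray(sample_scale)[:, None]
    Xc = X - X.mean(axis=0)
    # plain (unweighted) PCA of the sample x position matrix
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    evals = svals**2 / (X.shape[0] - 1)
    xi_full, eta_full, (J, L) = _genotype_design_scores(gene1, gene2, config)
    total = evals.sum()
    if total > 0:
        frac = np.cumsum(evals) / total
        K = int(np.searchsorted(frac, var_explained - 1e-12) + 1)
        K = min(K, int(np.sum(evals > evals[0] * 1e-12)))
    else:
        K = 1
    while J * L * K > gene1.n_samples // 2 and max(J, L, K) > 1:
        if K >= max(J, L):
            K -= 1
        elif J >= L:
            J -= 1
        else:
            L -= 1
    Y = Xc @ vt[:K].T
    design = build_design(xi_full.scores[:, :J], eta_full.scores[:, :L], W)
    fit_result = fit(design, Y)
    res = interaction_test(fit_result, design)
    res.J, res.L, res.K = J, L, K
    res.flags["method"] = "pca"
    return res
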
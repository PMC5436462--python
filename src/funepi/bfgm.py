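"""Functional-response / functional-predictor interaction regression.

The gene-gene interaction test works on expansion coefficients.  With xi
(n x J) and eta (n x L) the FPCA scores of the two genes' genotype
functions, Y (n x K) the FPCA scores of the read-count curves, and W
optional covariates, the model is the multivariate multiple regression

    Y = E mu + W omega + xi alpha + eta beta + Gamma gamma + eps,

where row i of Gamma is the Kronecker product xi_i^T (x) eta_i^T.  Ordinary
least squares gives b_hat = (A^T A)^+ A^T Y with A = [E W xi eta Gamma];
under var(vec(eps)) = Sigma (x) I_n the covariance of the interaction block
is Lambda = Sigma_hat (x) G with G the trailing JL x JL block of (A^T A)^+.
The Wald statistic

    T_I = vec(gamma_hat)^T Lambda^+ vec(gamma_hat)

is asymptotically chi-square with df = rank(Lambda) (JLK in the regular
case) under the no-interaction null; vec() stacks gamma_hat column-wise
(K-major), which makes the Kronecker form of Lambda exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import stats

from .curves import (
    CommonGrid,
    PositionCurve,
    ScoreMatrix,
    fit_fpca,
    regrid_loess,
)
from .genotypes import GenotypeMatrix, encode, genotype_scores

__all__ = [
    "BfgmConfig",
    "DesignBundle",
    "FitResult",
    "InteractionResult",
    "build_design",
    "fit",
    "interaction_test",
    "run_bfgm",
]


@dataclass
class BfgmConfig:
    """Tuning knobs of the interaction-test pipeline.

    var_explained selects the smallest numbers of components J, L, K whose
    eigenvalues explain at least that fraction of variance (0.8 by default);
    max_components caps each of them, and J*L*K is additionally capped at
    n/2 to keep the degrees of freedom well below the sample size.
    """

    var_explained: float = 0.8
    max_components: int | None = None
    grid_m: int = 256
    loess_span: float = 0.3
    loess_degree: int = 2
    hwe_alpha: float = 1e-9
    normalize_curves: bool = True
    seed: int | None = None


@dataclass
class DesignBundle:
    """Assembled regression design A = [E W xi eta Gamma]."""

    E: np.ndarray
    W: np.ndarray | None
    xi: np.ndarray
    eta: np.ndarray
    Gamma: np.ndarray
    A: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return 0 if self.W is None else self.W.shape[1]

    @property
    def J(self) -> int:
        return self.xi.shape[1]

    @property
    def L(self) -> int:
        return self.eta.shape[1]

    @property
    def dims(self) -> tuple[int, int, int, int, int]:
        return (self.n, self.d, self.J, self.L, self.J * self.L)


@dataclass
class FitResult:
    """Least-squares fit of the multivariate regression Y = A b + eps."""

    b_hat: np.ndarray  # (1 + d + J + L + JL) x K
    Sigma_hat: np.ndarray  # K x K
    AtA_inv: np.ndarray  # Moore-Penrose inverse of A^T A
    rank: int
    dims: tuple[int, int, int, int, int]  # (n, d, J, L, JL)

    @property
    def K(self) -> int:
        return self.b_hat.shape[1]

    @property
    def gamma_hat(self) -> np.ndarray:
        jl = self.dims[4]
        return self.b_hat[-jl:, :]


@dataclass
class InteractionResult:
    """Wald chi-square test of the interaction coefficient block."""

    T_I: float
    df: int
    p_value: float
    gamma_hat: np.ndarray
    Lambda: np.ndarray
    J: int = 0
    L: int = 0
    K: int = 0
    flags: dict = field(default_factory=dict)


def _as_array(scores: ScoreMatrix | np.ndarray) -> np.ndarray:
    if isinstance(scores, ScoreMatrix):
        return scores.scores
    return np.atleast_2d(np.asarray(scores, dtype=float))


def build_design(
    xi: ScoreMatrix | np.ndarray,
    eta: ScoreMatrix | np.ndarray,
    W: np.ndarray | None = None,
) -> DesignBundle:
    """Assemble A = [E W xi eta Gamma] with Gamma rows xi_i^T (x) eta_i^T.

    Gamma column (j, l) sits at index j * L + l (0-based), i.e. row-major
    over the (gene-1 component, gene-2 component) pairs.
    """
    x = _as_array(xi)
    z = _as_array(eta)
    n = x.shape[0]
    if z.shape[0] != n:
        raise ValueError("xi and eta row counts disagree")
    if x.shape[1] < 1 or z.shape[1] < 1:
        raise ValueError("need at least one component per gene")
    if W is not None:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] != n:
            raise ValueError("covariate row count disagrees")
    gamma = np.einsum("ij,il->ijl", x, z).reshape(n, -1)
    E = np.ones((n, 1))
    blocks = [E] + ([W] if W is not None else []) + [x, z, gamma]
    A = np.hstack(blocks)
    return DesignBundle(E=E, W=W, xi=x, eta=z, Gamma=gamma, A=A)


def fit(
    design: DesignBundle,
    Y: ScoreMatrix | np.ndarray,
    allow_rank_deficient: bool = True,
) -> FitResult:
    """Multivariate least squares with the Moore-Penrose pseudo-inverse.

    b_hat = (A^T A)^+ A^T Y.  The residual covariance is
    Sigma_hat = R^T R / (n - rank(A)), the standard unbiased multivariate-OLS
    estimator (n - rank equals n - (1 + d + J + L + JL) in the full-rank
    case).
    """
    A = design.A
    Ymat = _as_array(Y)
    n, q = A.shape
    if Ymat.shape[0] != n:
        raise ValueError("response row count disagrees with the design")
    AtA = A.T @ A
    G, rank = _pinv_psd(AtA, return_rank=True)
    if n <= rank:
        raise ValueError(
            f"too few samples: n={n} must exceed the design rank {rank}"
        )
    if rank < q and not allow_rank_deficient:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {q} columns); "
            f"need n > {q} independent rows or enable the generalized inverse"
        )
    b_hat = G @ (A.T @ Ymat)
    R = Ymat - A @ b_hat
    Sigma_hat = (R.T @ R) / (n - rank)
    return FitResult(
        b_hat=b_hat,
        Sigma_hat=Sigma_hat,
        AtA_inv=G,
        rank=rank,
        dims=design.dims,
    )


def _pinv_psd(
    mat: np.ndarray, rcond: float = 1e-10, return_rank: bool = False
):
    """Pseudo-inverse of a symmetric PSD matrix via eigendecomposition.

    Eigenvalues below ``rcond`` times the largest are treated as zero.
    """
    evals, evecs = scipy.linalg.eigh(mat)
    cutoff = max(evals.max(), 0.0) * rcond
    inv = np.where(evals > cutoff, 1.0 / np.where(evals > cutoff, evals, 1.0), 0.0)
    out = (evecs * inv[None, :]) @ evecs.T
    if return_rank:
        return out, int(np.sum(evals > cutoff))
    return out


def trailing_block_test(fit_result: FitResult, n_cols: int) -> InteractionResult:
    """Wald chi-square test that the last ``n_cols`` coefficient rows vanish.

    The tested block's covariance is Sigma_hat (x) G with G the trailing
    n_cols x n_cols block of (A^T A)^+; the coefficient block is stacked
    column-wise (K-major) to match that Kronecker ordering.
    """
    K = fit_result.K
    coef = fit_result.b_hat[-n_cols:, :]
    G = fit_result.AtA_inv[-n_cols:, -n_cols:]
    Lambda = np.kron(fit_result.Sigma_hat, G)
    v = coef.flatten(order="F")
    Linv, rank = _pinv_psd(Lambda, return_rank=True)
    T = float(v @ Linv @ v)
    T = max(T, 0.0)
    df = rank
    p = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
    flags = {}
    if rank < n_cols * K:
        flags["lambda_singular"] = True
    return InteractionResult(
        T_I=T, df=df, p_value=p, gamma_hat=coef, Lambda=Lambda,
        K=K, flags=flags,
    )


def interaction_test(
    fit_result: FitResult, design: DesignBundle
) -> InteractionResult:
    """Test H0: gamma = 0 on the interaction block of a fitted model."""
    res = trailing_block_test(fit_result, design.J * design.L)
    res.J, res.L = design.J, design.L
    return res


def _select_components(
    eigenvalues_list: list[np.ndarray], var_explained: float,
    max_components: int | None, n: int,
) -> list[int]:
    """Smallest counts explaining >= var_explained, capped at prod <= n/2."""
    ks = []
    for ev in eigenvalues_list:
        total = ev.sum()
        if total <= 0:
            ks.append(1)
            continue
        frac = np.cumsum(ev) / total
        k = int(np.searchsorted(frac, var_explained - 1e-12) + 1)
        k = min(k, ev.size)
        if max_components is not None:
            k = min(k, max_components)
        ks.append(max(k, 1))
    # enforce J*L*K <= n/2 by trimming the largest count first
    while int(np.prod(ks)) > n // 2 and max(ks) > 1:
        ks[int(np.argmax(ks))] -= 1
    return ks


def response_scores(
    trait_curves: PositionCurve,
    config: BfgmConfig,
    sample_scale: np.ndarray | None = None,
) -> tuple[ScoreMatrix, np.ndarray]:
    """Regrid (if needed) and FPCA-expand the read-count curves.

    Returns the full-rank score matrix plus the eigenvalue spectrum, so the
    caller can pick K.  ``sample_scale`` optionally divides each sample's
    curve by its size factor before the expansion.
    """
    grid = CommonGrid(config.grid_m)
    curves = trait_curves
    if sample_scale is not None:
        curves = PositionCurve(
            curves.positions, curves.values / np.asarray(sample_scale)[:, None],
            region=curves.region,
        )
    on_grid = (
        curves.positions.size == grid.points.size
        and np.allclose(curves.positions, grid.points)
    )
    if not on_grid:
        curves = regrid_loess(
            curves, grid, span=config.loess_span, degree=config.loess_degree
        )
    basis, scores = fit_fpca(curves)
    return scores, basis.eigenvalues


def run_bfgm(
    gene1: GenotypeMatrix,
    gene2: GenotypeMatrix,
    trait_curves: PositionCurve,
    W: np.ndarray | None = None,
    config: BfgmConfig | None = None,
    sample_scale: np.ndarray | None = None,
) -> InteractionResult:
    """Full pipeline: encode, score, expand response, fit, test.

    ``sample_scale`` (per-sample size factors) is applied to the curves when
    ``config.normalize_curves`` is on and factors are supplied.
    """
    config = config or BfgmConfig()
    n = gene1.n_samples
    if gene2.n_samples != n or trait_curves.n_samples != n:
        raise ValueError("stage 'inputs': sample counts disagree")
    xi_full = genotype_scores(encode(gene1))
    eta_full = genotype_scores(encode(gene2))
    scale = sample_scale if config.normalize_curves else None
    y_full, y_evals = response_scores(trait_curves, config, scale)
    J, L, K = _select_components(
        [
            xi_full.basis.eigenvalues,
            eta_full.basis.eigenvalues,
            y_evals,
        ],
        config.var_explained,
        config.max_components,
        n,
    )
    xi = xi_full.scores[:, :J]
    eta = eta_full.scores[:, :L]
    Y = y_full.scores[:, :K]
    design = build_design(xi, eta, W)
    fit_result = fit(design, Y)
    res = interaction_test(fit_result, design)
    res.J, res.L, res.K = J, L, K
    res.flags["n"] = n
    return res
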
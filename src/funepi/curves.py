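"""Functional-data engine: common grids, LOESS regridding, FPCA, expansions.

Read-count profiles and genotype profiles are both treated as functions of
genomic position.  A raw per-position observation is held in a
:class:`PositionCurve`; after affine remapping of its positions into [0, 1]
and (for read counts) LOESS smoothing onto a :class:`CommonGrid`, functional
principal component analysis (FPCA) yields an orthonormal
:class:`EigenBasis` and per-sample expansion coefficients
(:class:`ScoreMatrix`).  All integrals are approximated by the trapezoid
rule, which is exact for the piecewise-linear representation used on the
grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "CommonGrid",
    "PositionCurve",
    "EigenBasis",
    "ScoreMatrix",
    "loess_smooth",
    "regrid_loess",
    "trapezoid_weights",
    "fit_fpca",
    "expand_coefficients",
]


@dataclass(frozen=True)
class CommonGrid:
    """Uniform grid 0, 1/m, 2/m, ..., 1 shared by all regridded curves."""

    m: int

    def __post_init__(self) -> None:
        if self.m < 4:
            raise ValueError("grid too coarse: need m >= 4 sub-intervals")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.m + 1)


@dataclass
class PositionCurve:
    """Function-valued observations: one value per (sample, genomic position).

    ``values`` has one row per sample; ``positions`` are strictly increasing
    coordinates in bp (or already normalized to [0, 1] after regridding).
    ``region`` is the (chrom, start, end) interval the positions live in.
    """

    positions: np.ndarray
    values: np.ndarray
    region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.positions.ndim != 1:
            raise ValueError("positions must be one-dimensional")
        if self.values.shape[1] != self.positions.size:
            raise ValueError(
                f"values has {self.values.shape[1]} columns but there are "
                f"{self.positions.size} positions"
            )
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("curve values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def normalized_positions(self) -> np.ndarray:
        """Positions mapped affinely onto [0, 1] via (p - a) / (b - a)."""
        if self.region is not None:
            _, a, b = self.region
        else:
            a, b = self.positions[0], self.positions[-1]
        if b <= a:
            raise ValueError("degenerate region: end <= start")
        return (self.positions - a) / (b - a)


@dataclass
class EigenBasis:
    """Orthonormal eigenfunctions on a common point set with their spectrum.

    Orthonormality is with respect to the trapezoid quadrature rule on
    ``points``: sum_g w_g * phi_j(t_g) * phi_k(t_g) = delta_jk.
    ``var_explained`` holds cumulative fractions of the covariance-operator
    trace captured by the leading components.
    """

    points: np.ndarray
    mean_fn: np.ndarray
    eigenfunctions: np.ndarray  # (n_components, n_points)
    eigenvalues: np.ndarray
    var_explained: np.ndarray
    truncated: bool = False

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return trapezoid_weights(self.points)


@dataclass
class ScoreMatrix:
    """n x J matrix of expansion coefficients in an :class:`EigenBasis`."""

    scores: np.ndarray
    basis: EigenBasis = field(repr=False)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.3,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression of every row of ``y`` on ``x``.

    For each evaluation point the ``ceil(span * len(x))`` nearest data points
    (never fewer than ``degree + 2``) receive tricube weights scaled by the
    distance to the farthest neighbour, and a weighted polynomial of the given
    degree is fitted.  The fit is shared across rows: the weights depend only
    on ``x``, so a single weighted least-squares factorization per evaluation
    point serves all samples.

    Returns an array of shape ``(y.shape[0], len(x_eval))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    x_eval = np.asarray(x_eval, dtype=float)
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if degree < 0:
        raise ValueError("degree must be nonnegative")
    n_pts = x.size
    if np.unique(x).size < degree + 2:
        raise ValueError(
            "insufficient support: need at least degree + 2 distinct positions"
        )
    k = min(n_pts, max(degree + 2, int(np.ceil(span * n_pts))))
    out = np.empty((y.shape[0], x_eval.size))
    order = np.argsort(x)
    xs, ys = x[order], y[:, order]
    for g, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0.0:
            out[:, g] = ys[:, idx].mean(axis=1)
            continue
        w = _tricube(d[idx] / dmax)
        pos = w > 0
        idx, w = idx[pos], w[pos]
        deg = min(degree, np.unique(xs[idx]).size - 1)
        sw = np.sqrt(w)
        # Vandermonde in (x - x0): the fitted value at x0 is the intercept.
        u = xs[idx] - x0
        scale = max(np.abs(u).max(), 1.0)
        design = np.vander(u / scale, deg + 1, increasing=True) * sw[:, None]
        rhs = ys[:, idx] * sw[None, :]
        coef, *_ = np.linalg.lstsq(design, rhs.T, rcond=None)
        out[:, g] = coef[0]
    return out


def regrid_loess(
    curve: PositionCurve,
    grid: CommonGrid,
    span: float = 0.3,
    degree: int = 2,
) -> PositionCurve:
    """LOESS-smooth a raw curve onto the common [0, 1] grid.

    Original positions are first mapped affinely onto [0, 1] via
    (p - a) / (b - a) over the curve's region, then every sample's values are
    smoothed by local polynomial regression and evaluated at the grid points.
    """
    t = curve.normalized_positions()
    smoothed = loess_smooth(t, curve.values, grid.points, span=span, degree=degree)
    chrom = curve.region[0] if curve.region is not None else "."
    return PositionCurve(grid.points, smoothed, region=(chrom, 0, 1))


def trapezoid_weights(points: np.ndarray) -> np.ndarray:
    """Trapezoid-rule quadrature weights for an increasing point set.

    A single point gets weight 1 so that inner products degenerate to the
    plain Euclidean product (used for single-SNP genotype "functions").
    """
    points = np.asarray(points, dtype=float)
    if points.size == 1:
        return np.ones(1)
    w = np.empty_like(points)
    w[0] = (points[1] - points[0]) / 2.0
    w[-1] = (points[-1] - points[-2]) / 2.0
    w[1:-1] = (points[2:] - points[:-2]) / 2.0
    return w


def _fix_signs(eigenfunctions: np.ndarray) -> np.ndarray:
    """Deterministic sign: the entry of largest |value| (first on ties) > 0."""
    out = eigenfunctions.copy()
    for j in range(out.shape[0]):
        i = int(np.argmax(np.abs(out[j])))
        if out[j, i] < 0:
            out[j] = -out[j]
    return out


def fit_fpca(
    curves_on_grid: PositionCurve,
    n_components: int | None = None,
    var_threshold: float | None = None,
) -> tuple[EigenBasis, ScoreMatrix]:
    """FPCA of curves sharing a point set, via the weighted covariance matrix.

    The sample covariance operator is discretized with trapezoid quadrature
    weights W: the symmetric eigenproblem W^{1/2} C W^{1/2} u = lambda u is
    solved densely, eigenfunctions are phi = W^{-1/2} u, and scores are
    quadrature inner products of the centered rows with the eigenfunctions.
    With this scaling the sample variance of score column j equals the j-th
    eigenvalue.

    Exactly one of ``n_components`` / ``var_threshold`` selects the retained
    components; if neither is given all positive-eigenvalue components are
    kept.  Requests beyond the numerical rank truncate with
    ``basis.truncated = True`` rather than failing.
    """
    X = curves_on_grid.values
    n = X.shape[0]
    if n < 2:
        raise ValueError("FPCA needs at least two samples")
    pts = curves_on_grid.positions
    w = trapezoid_weights(pts)
    mean_fn = X.mean(axis=0)
    Xc = X - mean_fn
    cov = (Xc.T @ Xc) / (n - 1)
    sqw = np.sqrt(w)
    sym = cov * sqw[:, None] * sqw[None, :]
    evals, evecs = scipy.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    tol = max(evals[0], 0.0) * 1e-12
    rank = int(np.sum(evals > tol))
    truncated = False
    if n_components is not None:
        if n_components > rank:
            truncated = True
        keep = min(n_components, rank)
    elif var_threshold is not None:
        if not 0.0 < var_threshold <= 1.0:
            raise ValueError("var_threshold must be in (0, 1]")
        if rank == 0:
            keep = 0
        else:
            frac = np.cumsum(evals[:rank]) / total
            keep = int(np.searchsorted(frac, var_threshold - 1e-12) + 1)
            keep = min(keep, rank)
    else:
        keep = rank
    keep = max(keep, 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(sqw[None, :] > 0, evecs[:, :keep].T / sqw[None, :], 0.0)
    phi = _fix_signs(phi)
    var_explained = (
        np.cumsum(evals[:keep]) / total if total > 0 else np.zeros(keep)
    )
    basis = EigenBasis(
        points=pts,
        mean_fn=mean_fn,
        eigenfunctions=phi,
        eigenvalues=evals[:keep],
        var_explained=var_explained,
        truncated=truncated,
    )
    scores = Xc @ (w[:, None] * phi.T)
    return basis, ScoreMatrix(scores, basis)


def expand_coefficients(
    curves_on_grid: PositionCurve,
    basis: EigenBasis,
    center: bool = True,
) -> ScoreMatrix:
    """Quadrature expansion coefficients of curves in a fitted basis.

    ``score[i, j]`` approximates the inner product of sample i's (optionally
    mean-centered) curve with eigenfunction j by the trapezoid rule on the
    shared point set.
    """
    if curves_on_grid.positions.size != basis.points.size or not np.allclose(
        curves_on_grid.positions, basis.points
    ):
        raise ValueError("curve points do not match the basis points")
    X = curves_on_grid.values
    if center:
        X = X - basis.mean_fn
    w = basis.weights
    scores = X @ (w[:, None] * basis.eigenfunctions.T)
    return ScoreMatrix(scores, basis)
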
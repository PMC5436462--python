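"""Synthetic-data engine: genotypes, null trait models and power generators.

The trait generators reproduce the study's simulation design.  Read-count
curves under the null are built from a library of template genes: every
template gene is LOESS-regridded onto [0, 1], the per-sample average over
genes defines the pooled matrix, its pointwise mean gives the overall mean
function mu(tau), and FPCA of the centered pooled matrix yields error
eigenfunctions phi_t with a score covariance Sigma.  Simulated residual
curves are eps_i(tau) = sum_t eps_it phi_t(tau) with eps_i ~ N(0, Sigma),
so the errors are a correlated stochastic process with the template's
second-order structure.

Three null models are available: no marginal effect; a marginal effect at
the first gene (per-SNP effect functions r_j * alpha(tau), r_j ~ U(0.5,
1.5)); marginal effects at both genes.  The power generator adds, for every
causal cross-gene SNP pair, a genotypic value lambda * g(tau) where lambda
is 0 or the risk parameter r according to a two-locus penetrance pattern
(Dominant-OR-Dominant, Dominant-AND-Dominant, Recessive-OR-Recessive or
Threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bfgm import BfgmConfig, run_bfgm
from .comparators import pca_regression_test, scalar_trait_from_curves, sfgm_test
from .curves import CommonGrid, PositionCurve, fit_fpca, regrid_loess
from .genotypes import GenotypeMatrix, encode

__all__ = [
    "GenotypeSimSpec",
    "GenotypeSim",
    "NullModelSpec",
    "InteractionModelSpec",
    "INTERACTION_PATTERNS",
    "simulate_genotypes",
    "resample_individuals",
    "make_template_curves",
    "build_null_spec",
    "generate_null_traits",
    "generate_power_traits",
    "type1_experiment",
    "power_experiment",
]

RARE_MAF = (0.001, 0.05)
COMMON_MAF = (0.05, 0.5)


@dataclass
class GenotypeSimSpec:
    """Sampling plan for two independent gene regions of HWE genotypes."""

    n: int
    p: int = 10
    spectrum: str = "rare"  # "rare" | "mixed"
    causal_fraction: float = 0.1
    region_length: int = 10_000

    def __post_init__(self) -> None:
        if self.spectrum not in ("rare", "mixed"):
            raise ValueError("spectrum must be 'rare' or 'mixed'")


@dataclass
class GenotypeSim:
    """Two simulated gene regions with their causal-SNP masks.

    ``maf1``/``maf2`` are the population minor-allele frequencies the
    genotype counts were drawn from; :func:`resample_individuals` redraws a
    fresh sample of individuals from the same population, as when each
    simulation replicate samples new individuals from a fixed pool of
    chromosomes.
    """

    gene1: GenotypeMatrix
    gene2: GenotypeMatrix
    causal1: np.ndarray
    causal2: np.ndarray
    maf1: np.ndarray | None = None
    maf2: np.ndarray | None = None


def _draw_mafs(spec: GenotypeSimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.spectrum == "rare":
        return rng.uniform(*RARE_MAF, size=spec.p)
    common = rng.random(spec.p) < 0.5
    maf = rng.uniform(*RARE_MAF, size=spec.p)
    maf[common] = rng.uniform(*COMMON_MAF, size=int(common.sum()))
    return maf


def _draw_counts(
    maf: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """HWE genotype counts, redrawing columns QC would discard.

    Monomorphic and singleton columns are resampled (the real genotypes
    being emulated pass QC by design).
    """
    counts = np.empty((n, maf.size), dtype=int)
    for j in range(maf.size):
        col = rng.binomial(2, maf[j], size=n)
        for _ in range(1000):
            if col.sum() >= 2:
                break
            col = rng.binomial(2, maf[j], size=n)
        counts[:, j] = col
    # orient to minor allele (common draws can exceed 0.5 in-sample)
    freq = counts.mean(axis=0) / 2.0
    flip = freq > 0.5
    counts[:, flip] = 2 - counts[:, flip]
    return counts


def _simulate_gene(
    spec: GenotypeSimSpec, chrom: str, rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray]:
    positions = np.sort(
        rng.choice(np.arange(1, spec.region_length + 1), size=spec.p, replace=False)
    )
    maf = _draw_mafs(spec, rng)
    counts = _draw_counts(maf, spec.n, rng)
    gm = GenotypeMatrix(counts, positions, region=(chrom, 1, spec.region_length))
    return gm, maf


def simulate_genotypes(
    spec: GenotypeSimSpec, rng: np.random.Generator | int | None = None
) -> GenotypeSim:
    """Independent HWE genotypes for two gene regions, causal SNPs flagged."""
    rng = np.random.default_rng(rng)
    g1, maf1 = _simulate_gene(spec, "1", rng)
    g2, maf2 = _simulate_gene(spec, "2", rng)
    n_causal = max(1, int(round(spec.causal_fraction * spec.p)))
    causal1 = np.zeros(spec.p, dtype=bool)
    causal2 = np.zeros(spec.p, dtype=bool)
    causal1[rng.choice(spec.p, size=n_causal, replace=False)] = True
    causal2[rng.choice(spec.p, size=n_causal, replace=False)] = True
    return GenotypeSim(g1, g2, causal1, causal2, maf1=maf1, maf2=maf2)


def resample_individuals(
    sim: GenotypeSim, rng: np.random.Generator | int | None = None
) -> GenotypeSim:
    """Fresh individuals from the same genotype population.

    Positions, population frequencies and causal flags are kept; only the
    genotype counts are redrawn, as when every simulation replicate samples
    a new cohort from a fixed pool of chromosomes.
    """
    if sim.maf1 is None or sim.maf2 is None:
        raise ValueError("population frequencies unknown; cannot resample")
    rng = np.random.default_rng(rng)
    n = sim.gene1.n_samples
    g1 = GenotypeMatrix(
        _draw_counts(sim.maf1, n, rng), sim.gene1.positions, sim.gene1.region
    )
    g2 = GenotypeMatrix(
        _draw_counts(sim.maf2, n, rng), sim.gene2.positions, sim.gene2.region
    )
    return GenotypeSim(g1, g2, sim.causal1, sim.causal2, sim.maf1, sim.maf2)


def make_template_curves(
    n: int,
    n_genes: int = 10,
    rng: np.random.Generator | int | None = None,
    base_scale: float = 50.0,
) -> list[PositionCurve]:
    """Parametric template gene library standing in for real RNA-seq curves.

    Each gene has a smooth baseline of 2-4 Gaussian bumps over its region and
    per-sample variation from two smooth modes: an amplitude mode (samples
    express the whole gene more or less strongly) and a shape mode (coverage
    shifts within the gene), mimicking the between-sample variability of real
    per-position coverage.  Genes have unequal lengths and position counts so
    the LOESS regridding step is exercised.
    """
    rng = np.random.default_rng(rng)
    curves: list[PositionCurve] = []
    for k in range(n_genes):
        length = int(rng.integers(1500, 4000))
        n_pos = int(rng.integers(150, 400))
        pos = np.sort(
            rng.choice(np.arange(1, length + 1), size=n_pos, replace=False)
        )
        t = (pos - 1) / (length - 1)
        n_bumps = int(rng.integers(2, 5))
        centers = rng.uniform(0, 1, n_bumps)
        widths = rng.uniform(0.05, 0.2, n_bumps)
        heights = rng.uniform(1.0, 5.0, n_bumps)
        base = np.zeros_like(t)
        shape = np.zeros_like(t)
        for c, wdt, h in zip(centers, widths, heights):
            base += h * np.exp(-0.5 * ((t - c) / wdt) ** 2)
        c2, w2 = rng.uniform(0, 1), rng.uniform(0.05, 0.2)
        shape = np.exp(-0.5 * ((t - c2) / w2) ** 2)
        amp = rng.normal(0.0, 0.3, size=n)
        sh = rng.normal(0.0, 0.5, size=n)
        values = base_scale * (
            (1.0 + amp)[:, None] * base[None, :] + sh[:, None] * shape[None, :]
        )
        curves.append(PositionCurve(pos.astype(float), values, region=("T", 1, length)))
    return curves


@dataclass
class NullModelSpec:
    """Mean function, effect functions and error structure for null traits."""

    model_id: int
    grid: CommonGrid
    mu: np.ndarray
    error_eigenfunctions: np.ndarray  # T x (m + 1)
    error_cov: np.ndarray  # T x T score covariance
    alpha_fn: np.ndarray | None = None
    beta_fn: np.ndarray | None = None
    r_multipliers: np.ndarray | None = None
    s_multipliers: np.ndarray | None = None
    causal1: np.ndarray | None = None
    causal2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        if self.model_id == 1 and (
            self.alpha_fn is not None or self.beta_fn is not None
        ):
            raise ValueError("model 1 has no effect functions")


def build_null_spec(
    template_curves: list[PositionCurve],
    model_id: int = 1,
    genotypes: GenotypeSim | None = None,
    grid: CommonGrid | None = None,
    rng: np.random.Generator | int | None = None,
    effect_size: float | None = None,
    loess_span: float = 0.3,
    loess_degree: int = 2,
    max_error_components: int | None = None,
) -> NullModelSpec:
    """Estimate the null trait model from a library of template genes.

    Every template gene is regridded onto the common grid by LOESS, the
    per-sample average over genes is pooled, its pointwise mean defines
    mu(tau) (the average FPC score construction collapses to the pointwise
    mean because centered scores average to zero), and FPCA of the centered
    pooled matrix provides the error eigenfunctions and score covariance.

    For models 2-3 the marginal effect functions are proportional to the
    leading error eigenfunctions, scaled by ``effect_size`` (default: the
    standard deviation of the first error score), and per-causal-SNP
    multipliers are drawn uniformly from [0.5, 1.5].
    """
    if len(template_curves) < 2:
        raise ValueError("need at least two template genes")
    rng = np.random.default_rng(rng)
    grid = grid or CommonGrid(256)
    regridded = [
        regrid_loess(c, grid, span=loess_span, degree=loess_degree).values
        for c in template_curves
    ]
    pooled = np.mean(regridded, axis=0)  # n x (m + 1): mean over genes
    mu = pooled.mean(axis=0)
    centered = PositionCurve(grid.points, pooled - mu, region=("T", 0, 1))
    basis, scores = fit_fpca(centered, n_components=max_error_components)
    if basis.n_components == 0:
        phi = np.zeros((0, grid.points.size))
        cov = np.zeros((0, 0))
    else:
        phi = basis.eigenfunctions
        cov = np.atleast_2d(np.cov(scores.scores, rowvar=False))
    alpha_fn = beta_fn = None
    r_mult = s_mult = None
    causal1 = causal2 = None
    if model_id >= 2:
        if genotypes is None:
            raise ValueError("models 2-3 need genotypes for marginal effects")
        if phi.shape[0] == 0:
            raise ValueError("degenerate templates: no error modes for effects")
        if effect_size is None:
            effect_size = float(np.sqrt(cov[0, 0]))
        alpha_fn = effect_size * phi[0]
        causal1 = genotypes.causal1
        r_mult = rng.uniform(0.5, 1.5, size=int(causal1.sum()))
    if model_id == 3:
        k = 1 if phi.shape[0] > 1 else 0
        beta_fn = effect_size * phi[k]
        causal2 = genotypes.causal2
        s_mult = rng.uniform(0.5, 1.5, size=int(causal2.sum()))
    return NullModelSpec(
        model_id=model_id,
        grid=grid,
        mu=mu,
        error_eigenfunctions=phi,
        error_cov=cov,
        alpha_fn=alpha_fn,
        beta_fn=beta_fn,
        r_multipliers=r_mult,
        s_multipliers=s_mult,
        causal1=causal1,
        causal2=causal2,
    )


def _draw_errors(
    spec: NullModelSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    T = spec.error_cov.shape[0]
    if T == 0:
        return np.zeros((n, spec.grid.points.size))
    # symmetric square root handles semidefinite score covariances
    evals, evecs = np.linalg.eigh(spec.error_cov)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))[None, :]
    eps_scores = rng.standard_normal((n, T)) @ root.T
    return eps_scores @ spec.error_eigenfunctions


def _marginal_term(
    encoded: np.ndarray,
    causal: np.ndarray,
    multipliers: np.ndarray,
    effect_fn: np.ndarray,
) -> np.ndarray:
    x = encoded[:, causal]
    return (x @ multipliers)[:, None] * effect_fn[None, :]


def generate_null_traits(
    spec: NullModelSpec,
    genotypes: GenotypeSim | None = None,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> PositionCurve:
    """Simulate trait curves with no interaction term (Models 1-3)."""
    rng = np.random.default_rng(rng)
    if spec.model_id >= 2 and genotypes is None:
        raise ValueError("models 2-3 need genotypes")
    if n is None:
        if genotypes is None:
            raise ValueError("n required when no genotypes are given")
        n = genotypes.gene1.n_samples
    values = np.tile(spec.mu, (n, 1)) + _draw_errors(spec, n, rng)
    if spec.model_id >= 2:
        values += _marginal_term(
            encode(genotypes.gene1).values,
            spec.causal1,
            spec.r_multipliers,
            spec.alpha_fn,
        )
    if spec.model_id == 3:
        values += _marginal_term(
            encode(genotypes.gene2).values,
            spec.causal2,
            spec.s_multipliers,
            spec.beta_fn,
        )
    return PositionCurve(spec.grid.points, values, region=("sim", 0, 1))


# unit penetrance patterns over minor-allele counts (rows: gene-1 locus
# 0/1/2 copies; columns: gene-2 locus 0/1/2 copies); scaled by the risk r
INTERACTION_PATTERNS: dict[str, np.ndarray] = {
    "dom_or_dom": np.array(
        [[0, 1, 1], [1, 1, 1], [1, 1, 1]], dtype=float
    ),
    "dom_and_dom": np.array(
        [[0, 0, 0], [0, 1, 1], [0, 1, 1]], dtype=float
    ),
    "rec_or_rec": np.array(
        [[0, 0, 1], [0, 0, 1], [1, 1, 1]], dtype=float
    ),
    "threshold": np.array(
        [[0, 0, 0], [0, 0, 1], [0, 1, 1]], dtype=float
    ),
}


@dataclass
class InteractionModelSpec:
    """Two-locus penetrance model scaled by the risk parameter r.

    ``g_fn`` is the common genotype coefficient function on the grid; the
    default built by :func:`interaction_model` is the leading template
    eigenfunction with its positional mean removed, so the signal lives in
    the shape of the curve rather than in overall expression.
    """

    name: str
    r: float
    g_fn: np.ndarray
    table: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("risk parameter r must be in [0, 1]")
        if self.table is None:
            if self.name not in INTERACTION_PATTERNS:
                raise ValueError(f"unknown interaction model '{self.name}'")
            self.table = INTERACTION_PATTERNS[self.name]
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")

    @property
    def lam(self) -> np.ndarray:
        """3x3 lambda table: pattern entries scaled by r."""
        return self.r * self.table


def interaction_model(
    name: str,
    r: float,
    null_spec: NullModelSpec,
    g_scale: float = 2.0,
) -> InteractionModelSpec:
    """Build an interaction model with the default genotype coefficient g.

    g(tau) is the first error eigenfunction, demeaned over the grid and
    rescaled so its L2 norm equals ``g_scale`` times the first error-score
    standard deviation — a positional signal of moderate size relative to
    the noise.
    """
    phi = null_spec.error_eigenfunctions
    if phi.shape[0] == 0:
        raise ValueError("null spec has no error modes to shape g from")
    g = phi[0] - phi[0].mean()
    norm = np.sqrt(np.trapezoid(g**2, null_spec.grid.points))
    if norm > 0:
        g = g / norm
    g = g * g_scale * float(np.sqrt(null_spec.error_cov[0, 0]))
    return InteractionModelSpec(name=name, r=r, g_fn=g)


def generate_power_traits(
    im: InteractionModelSpec,
    genotypes: GenotypeSim,
    null_spec: NullModelSpec,
    rng: np.random.Generator | int | None = None,
) -> PositionCurve:
    """Simulate trait curves with a two-locus interaction signal.

    For every causal cross-gene SNP pair the genotypic value
    lambda(class) * g(tau) is added to the mean function, with lambda from
    the model's table scaled by r; the errors reuse the null model's
    correlated structure.  At r = 0 this reduces exactly to the
    no-marginal-effect null generator.
    """
    rng = np.random.default_rng(rng)
    n = genotypes.gene1.n_samples
    lam = im.lam
    c1 = np.flatnonzero(genotypes.causal1)
    c2 = np.flatnonzero(genotypes.causal2)
    if c1.size == 0 or c2.size == 0:
        raise ValueError("causal SNP sets must be nonempty")
    trigger = np.zeros(n)
    for a in c1:
        ga = genotypes.gene1.counts[:, a]
        for b in c2:
            gb = genotypes.gene2.counts[:, b]
            trigger = trigger + lam[ga, gb]
    values = (
        np.tile(null_spec.mu, (n, 1))
        + trigger[:, None] * im.g_fn[None, :]
        + _draw_errors(null_spec, n, rng)
    )
    return PositionCurve(null_spec.grid.points, values, region=("sim", 0, 1))


def _binomial_se(rate: float, reps: int) -> float:
    return float(np.sqrt(max(rate * (1.0 - rate), 0.0) / reps))


def type1_experiment(
    model_id: int,
    n_grid: list[int],
    alphas: list[float] = (0.05, 0.01),
    reps: int = 2000,
    n_pairs: int = 10,
    genotype_spec: GenotypeSimSpec | None = None,
    n_template_genes: int = 10,
    config: BfgmConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical type-1 error of the interaction test under a null model.

    For each sample size, ``reps`` replicates are spread over ``n_pairs``
    independently simulated gene pairs (genotypes fixed within a pair,
    traits redrawn each replicate), and the rejection fraction is reported
    per nominal level with its binomial standard error.
    """
    if reps < 100:
        raise ValueError("reps must be at least 100")
    config = config or BfgmConfig()
    rng = np.random.default_rng(seed)
    grid = CommonGrid(config.grid_m)
    rows = []
    for n in n_grid:
        templates = make_template_curves(n, n_template_genes, rng)
        pvals = np.empty(reps)
        reps_per_pair = int(np.ceil(reps / n_pairs))
        i = 0
        for _ in range(n_pairs):
            if i >= reps:
                break
            gspec = genotype_spec or GenotypeSimSpec(n=n)
            if gspec.n != n:
                gspec = GenotypeSimSpec(
                    n=n, p=gspec.p, spectrum=gspec.spectrum,
                    causal_fraction=gspec.causal_fraction,
                    region_length=gspec.region_length,
                )
            sim = simulate_genotypes(gspec, rng)
            spec = build_null_spec(
                templates, model_id, sim if model_id >= 2 else None,
                grid=grid, rng=rng,
                loess_span=config.loess_span, loess_degree=config.loess_degree,
            )
            for _ in range(min(reps_per_pair, reps - i)):
                rep = resample_individuals(sim, rng)
                curves = generate_null_traits(spec, rep, n=n, rng=rng)
                res = run_bfgm(rep.gene1, rep.gene2, curves, config=config)
                pvals[i] = res.p_value
                i += 1
        for alpha in alphas:
            rate = float(np.mean(pvals[:i] < alpha))
            rows.append(
                {
                    "model": model_id,
                    "n": n,
                    "alpha": alpha,
                    "rate": rate,
                    "se": _binomial_se(rate, i),
                    "reps": i,
                }
            )
    return pd.DataFrame(rows)


def _method_pvalue(
    method: str,
    sim: GenotypeSim,
    curves: PositionCurve,
    config: BfgmConfig,
) -> float:
    if method == "bfgm":
        return run_bfgm(sim.gene1, sim.gene2, curves, config=config).p_value
    if method == "sfgm":
        trait = scalar_trait_from_curves(curves)
        return sfgm_test(sim.gene1, sim.gene2, trait, config=config).p_value
    if method == "pca":
        return pca_regression_test(
            sim.gene1, sim.gene2, curves, config=config
        ).p_value
    raise ValueError(f"unknown method '{method}'")


def power_experiment(
    model_names: list[str],
    n: int = 2000,
    r_grid: list[float] = (0.0, 0.2, 0.5, 0.8),
    reps: int = 500,
    alpha: float = 0.05,
    methods: list[str] = ("bfgm", "pca", "sfgm"),
    genotype_spec: GenotypeSimSpec | None = None,
    n_pairs: int = 5,
    n_template_genes: int = 10,
    g_scale: float = 2.0,
    config: BfgmConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical power per method over a grid of risk-parameter values.

    Replicates are spread over ``n_pairs`` independently drawn genotype
    populations (causal sets fixed within a population); each replicate
    samples a fresh cohort of individuals and fresh trait curves.
    """
    config = config or BfgmConfig()
    rng = np.random.default_rng(seed)
    grid = CommonGrid(config.grid_m)
    gspec = genotype_spec or GenotypeSimSpec(n=n, p=20, causal_fraction=0.2)
    templates = make_template_curves(n, n_template_genes, rng)
    pops = [simulate_genotypes(gspec, rng) for _ in range(n_pairs)]
    null_spec = build_null_spec(
        templates, 1, grid=grid, rng=rng,
        loess_span=config.loess_span, loess_degree=config.loess_degree,
    )
    reps_per_pop = int(np.ceil(reps / n_pairs))
    rows = []
    for name in model_names:
        for r in r_grid:
            im = interaction_model(name, r, null_spec, g_scale=g_scale)
            hits = {m: 0 for m in methods}
            done = 0
            for sim in pops:
                for _ in range(min(reps_per_pop, reps - done)):
                    rep = resample_individuals(sim, rng)
                    curves = generate_power_traits(im, rep, null_spec, rng)
                    for m in methods:
                        if _method_pvalue(m, rep, curves, config) < alpha:
                            hits[m] += 1
                    done += 1
            for m in methods:
                power = hits[m] / done
                rows.append(
                    {
                        "model": name,
                        "r": r,
                        "method": m,
                        "power": power,
                        "se": _binomial_se(power, done),
                        "reps": done,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)
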
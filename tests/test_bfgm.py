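"""Design assembly, multivariate least squares and the Wald chi-square test."""

import numpy as np
import pytest
from scipy import stats

from funepi.bfgm import (
    BfgmConfig,
    DesignBundle,
    FitResult,
    build_design,
    fit,
    interaction_test,
    run_bfgm,
    trailing_block_test,
)
from funepi.curves import CommonGrid, PositionCurve
from funepi.genotypes import GenotypeMatrix


def random_problem(rng, n=40, d=1, J=2, L=2, K=2):
    xi = rng.normal(size=(n, J))
    eta = rng.normal(size=(n, L))
    W = rng.normal(size=(n, d)) if d else None
    design = build_design(xi, eta, W)
    q = design.A.shape[1]
    b = rng.normal(size=(q, K))
    return design, b


class TestBuildDesign:
    def test_unit_vector_kronecker(self):
        design = build_design(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        assert np.array_equal(design.Gamma[0], [0.0, 1.0, 0.0, 0.0])

    def test_shapes_and_indexing_rule(self, rng):
        xi = rng.normal(size=(5, 3))
        eta = rng.normal(size=(5, 2))
        design = build_design(xi, eta)
        assert design.Gamma.shape == (5, 6)
        # 1-based (j=2, l=1) lives at column (2-1)*L + 1
        assert design.Gamma[3, (2 - 1) * 2 + 1 - 1] == pytest.approx(
            xi[3, 1] * eta[3, 0]
        )
        assert design.A.shape[1] == 1 + 3 + 2 + 6

    def test_gamma_matches_double_loop_oracle(self, rng):
        xi = rng.normal(size=(7, 3))
        eta = rng.normal(size=(7, 4))
        design = build_design(xi, eta)
        for i in range(7):
            for j in range(3):
                for l in range(4):
                    assert design.Gamma[i, j * 4 + l] == xi[i, j] * eta[i, l]

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="disagree"):
            build_design(rng.normal(size=(5, 2)), rng.normal(size=(4, 2)))


class TestFit:
    def test_noiseless_recovery(self, rng):
        design, b = random_problem(rng)
        Y = design.A @ b
        res = fit(design, Y)
        assert np.max(np.abs(res.b_hat - b)) < 1e-8
        assert np.max(np.abs(res.Sigma_hat)) < 1e-12

    def test_matches_pseudoinverse_oracle(self, rng):
        design, b = random_problem(rng, n=30, d=1, J=2, L=1, K=2)
        Y = design.A @ b + rng.normal(size=(30, 2))
        res = fit(design, Y)
        oracle = np.column_stack(
            [np.linalg.pinv(design.A) @ Y[:, k] for k in range(2)]
        )
        assert np.max(np.abs(res.b_hat - oracle)) < 1e-10

    def test_projection_identity(self, rng):
        design, b = random_problem(rng, n=50, K=3)
        Y = design.A @ b + rng.normal(size=(50, 3))
        res = fit(design, Y)
        R = Y - design.A @ res.b_hat
        assert np.max(np.abs(design.A.T @ R)) < 1e-8

    def test_sigma_uses_residual_degrees_of_freedom(self, rng):
        design, b = random_problem(rng, n=60, K=2)
        Y = design.A @ b + rng.normal(size=(60, 2))
        res = fit(design, Y)
        R = Y - design.A @ res.b_hat
        q = design.A.shape[1]
        assert np.allclose(res.Sigma_hat, R.T @ R / (60 - q))

    def test_duplicated_column_leaves_projection_unchanged(self, rng):
        n = 40
        xi = rng.normal(size=(n, 2))
        eta = rng.normal(size=(n, 1))
        Y = rng.normal(size=(n, 2))
        base = build_design(xi, eta)
        dup = build_design(np.column_stack([xi, xi[:, 1]]), eta)
        f1 = fit(base, Y)
        f2 = fit(dup, Y, allow_rank_deficient=True)
        assert f2.rank < dup.A.shape[1]
        assert np.max(np.abs(dup.A @ f2.b_hat - base.A @ f1.b_hat)) < 1e-8

    def test_too_few_samples_message(self, rng):
        design, b = random_problem(rng, n=40)
        small = build_design(design.xi[:5], design.eta[:5])
        with pytest.raises(ValueError, match="too few samples"):
            fit(small, np.zeros((5, 1)))


class TestInteractionTest:
    def test_null_value_when_gamma_zero(self, rng):
        # orthonormal design, response orthogonal to the interaction columns
        n, q = 30, 6
        Q, _ = np.linalg.qr(rng.normal(size=(n, q + 3)))
        A = Q[:, :q]
        design = DesignBundle(
            E=A[:, :1], W=None, xi=A[:, 1:2], eta=A[:, 2:4],
            Gamma=A[:, 4:6], A=A,
        )
        Y = A[:, :4] @ rng.normal(size=(4, 2)) + Q[:, q:] @ rng.normal(size=(3, 2))
        res = interaction_test(fit(design, Y), design)
        assert res.T_I == pytest.approx(0.0, abs=1e-16)
        assert res.p_value == pytest.approx(1.0)

    def test_identity_lambda_sum_of_squares(self):
        f = FitResult(
            b_hat=np.array([[0.5], [1.0], [2.0], [2.0]]),
            Sigma_hat=np.eye(1),
            AtA_inv=np.eye(4),
            rank=4,
            dims=(10, 0, 1, 3, 3),
        )
        res = trailing_block_test(f, 3)
        assert res.T_I == pytest.approx(9.0)
        assert res.df == 3

    def test_scalar_case_matches_chi2_oracle(self, rng):
        n = 200
        xi = rng.normal(size=(n, 1))
        eta = rng.normal(size=(n, 1))
        design = build_design(xi, eta)
        Y = rng.normal(size=(n, 1))
        f = fit(design, Y)
        res = interaction_test(f, design)
        se2 = f.Sigma_hat[0, 0] * f.AtA_inv[-1, -1]
        t2 = float(f.b_hat[-1, 0] ** 2 / se2)
        assert res.T_I == pytest.approx(t2, rel=1e-10)
        assert res.p_value == pytest.approx(stats.chi2.sf(t2, 1), rel=1e-10)

    def test_p_at_chi2_quantile(self):
        q95 = stats.chi2.ppf(0.95, 1)
        f = FitResult(
            b_hat=np.array([[np.sqrt(q95)]]),
            Sigma_hat=np.eye(1),
            AtA_inv=np.eye(1),
            rank=1,
            dims=(10, 0, 1, 1, 1),
        )
        res = trailing_block_test(f, 1)
        assert res.p_value == pytest.approx(0.05, abs=1e-6)

    def test_block_extraction_identity(self, rng):
        # Lambda = Sigma (x) G equals the gamma-row/column submatrix of
        # Sigma (x) (A^T A)^+ under column-stacked (K-major) vec ordering
        design, b = random_problem(rng, n=50, d=0, J=2, L=2, K=3)
        Y = design.A @ b + rng.normal(size=(50, 3))
        f = fit(design, Y)
        res = interaction_test(f, design)
        q = design.A.shape[1]
        jl = design.J * design.L
        full = np.kron(f.Sigma_hat, f.AtA_inv)
        idx = np.concatenate(
            [k * q + np.arange(q - jl, q) for k in range(3)]
        )
        assert np.array_equal(res.Lambda, full[np.ix_(idx, idx)])

    def test_quadratic_scaling_in_gamma(self, rng):
        design, b = random_problem(rng, n=50)
        Y = design.A @ b + rng.normal(size=(50, 2))
        f = fit(design, Y)
        base = interaction_test(f, design)
        scaled = FitResult(
            b_hat=np.vstack(
                [f.b_hat[:-4], 3.0 * f.b_hat[-4:]]
            ),
            Sigma_hat=f.Sigma_hat,
            AtA_inv=f.AtA_inv,
            rank=f.rank,
            dims=f.dims,
        )
        res = trailing_block_test(scaled, 4)
        assert res.T_I == pytest.approx(9.0 * base.T_I, rel=1e-8)

    def test_singular_lambda_uses_rank(self):
        f = FitResult(
            b_hat=np.array([[1.0], [1.0]]),
            Sigma_hat=np.eye(1),
            AtA_inv=np.array([[1.0, 1.0], [1.0, 1.0]]),
            rank=1,
            dims=(10, 0, 1, 2, 2),
        )
        res = trailing_block_test(f, 2)
        assert res.df == 1
        assert res.flags.get("lambda_singular")


class TestRunBfgm:
    def test_permutation_equivariance(self, rng):
        n = 60
        g1 = GenotypeMatrix(
            rng.binomial(2, 0.3, (n, 4)), [10, 20, 30, 40], ("1", 1, 100)
        )
        g2 = GenotypeMatrix(
            rng.binomial(2, 0.25, (n, 3)), [5, 15, 25], ("2", 1, 100)
        )
        grid = CommonGrid(16)
        vals = rng.normal(5.0, 1.0, size=(n, 17)).cumsum(axis=1)
        curve = PositionCurve(grid.points, vals, ("T", 0, 1))
        cfg = BfgmConfig(grid_m=16)
        base = run_bfgm(g1, g2, curve, config=cfg)
        perm = rng.permutation(n)
        res = run_bfgm(
            GenotypeMatrix(g1.counts[perm], g1.positions, g1.region),
            GenotypeMatrix(g2.counts[perm], g2.positions, g2.region),
            PositionCurve(grid.points, vals[perm], ("T", 0, 1)),
            config=cfg,
        )
        assert res.T_I == pytest.approx(base.T_I, abs=1e-8)
        assert (res.J, res.L, res.K) == (base.J, base.L, base.K)

    def test_sample_mismatch_names_stage(self, rng):
        g1 = GenotypeMatrix(rng.binomial(2, 0.3, (10, 2)), [1, 2], ("1", 1, 9))
        g2 = GenotypeMatrix(rng.binomial(2, 0.3, (11, 2)), [1, 2], ("2", 1, 9))
        curve = PositionCurve(
            CommonGrid(8).points, rng.normal(size=(10, 9)), ("T", 0, 1)
        )
        with pytest.raises(ValueError, match="inputs"):
            run_bfgm(g1, g2, curve)
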
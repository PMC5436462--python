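"""Baseline tests: scalar-response, per-position minimum, pairwise minimum, PCA."""

import numpy as np
import pytest

from funepi.bfgm import BfgmConfig, build_design, fit, run_bfgm, trailing_block_test
from funepi.comparators import (
    minp_pairwise,
    pca_regression_test,
    rnamin_test,
    sfgm_test,
)
from funepi.curves import CommonGrid, PositionCurve
from funepi.expression import ScalarTrait
from funepi.genotypes import GenotypeMatrix, encode


@pytest.fixture
def toy(rng):
    n = 120
    g1 = GenotypeMatrix(
        rng.binomial(2, rng.uniform(0.1, 0.4, 3), (n, 3)),
        [10, 20, 30], ("1", 1, 100),
    )
    g2 = GenotypeMatrix(
        rng.binomial(2, rng.uniform(0.1, 0.4, 2), (n, 2)),
        [40, 60], ("2", 1, 100),
    )
    grid = CommonGrid(8)
    vals = 5.0 + rng.normal(size=(n, 9)) + rng.normal(size=(n, 1))
    curve = PositionCurve(grid.points, vals, ("T", 0, 1))
    return g1, g2, curve


class TestSfgm:
    def test_equals_functional_test_on_flat_curves(self, rng):
        n = 100
        g1 = GenotypeMatrix(
            rng.binomial(2, 0.3, (n, 3)), [10, 20, 30], ("1", 1, 100)
        )
        g2 = GenotypeMatrix(
            rng.binomial(2, 0.2, (n, 2)), [40, 60], ("2", 1, 100)
        )
        levels = rng.normal(10.0, 2.0, size=n)
        grid = CommonGrid(8)
        curve = PositionCurve(
            grid.points, np.tile(levels[:, None], (1, 9)), ("T", 0, 1)
        )
        cfg = BfgmConfig(grid_m=8)
        b = run_bfgm(g1, g2, curve, config=cfg)
        s = sfgm_test(g1, g2, ScalarTrait(levels), config=cfg)
        assert b.K == 1
        assert s.p_value == pytest.approx(b.p_value, abs=1e-8)

    def test_df_is_JL(self, toy):
        g1, g2, curve = toy
        trait = ScalarTrait(curve.values.sum(axis=1))
        res = sfgm_test(g1, g2, trait)
        assert res.df == res.J * res.L
        assert res.K == 1


class TestRnamin:
    def test_single_position_equals_scalar_test(self, toy, rng):
        g1, g2, _ = toy
        y = rng.normal(size=g1.n_samples)
        curve = PositionCurve(np.array([0.5]), y[:, None], ("T", 0, 1))
        min_p, pos = rnamin_test(g1, g2, curve)
        ref = sfgm_test(g1, g2, ScalarTrait(y))
        assert min_p == pytest.approx(ref.p_value, rel=1e-10)
        assert pos == 0.5

    def test_matches_bruteforce_loop_oracle(self, toy):
        g1, g2, curve = toy
        min_p, pos = rnamin_test(g1, g2, curve)
        oracle = min(
            sfgm_test(g1, g2, ScalarTrait(curve.values[:, g])).p_value
            for g in range(curve.positions.size)
        )
        assert min_p == pytest.approx(oracle, rel=1e-12)

    def test_null_minimum_is_anticonservative(self, rng):
        # the raw minimum over positions sits stochastically below uniform
        n = 80
        g1 = GenotypeMatrix(rng.binomial(2, 0.3, (n, 2)), [1, 2], ("1", 1, 9))
        g2 = GenotypeMatrix(rng.binomial(2, 0.3, (n, 2)), [5, 6], ("2", 1, 9))
        grid = CommonGrid(8)
        mins = []
        for _ in range(40):
            curve = PositionCurve(
                grid.points, rng.normal(size=(n, 9)), ("T", 0, 1)
            )
            mins.append(rnamin_test(g1, g2, curve)[0])
        assert np.median(mins) < 0.5


class TestMinpPairwise:
    def test_single_pair(self, rng):
        n = 90
        g1 = GenotypeMatrix(rng.binomial(2, 0.3, (n, 1)), [3], ("1", 1, 9))
        g2 = GenotypeMatrix(rng.binomial(2, 0.4, (n, 1)), [7], ("2", 1, 9))
        grid = CommonGrid(8)
        curve = PositionCurve(grid.points, rng.normal(size=(n, 9)), ("T", 0, 1))
        cfg = BfgmConfig(grid_m=8)
        p, pair = minp_pairwise(g1, g2, curve, config=cfg)
        assert pair == (3, 7)
        # independent single-pair computation
        from funepi.bfgm import response_scores

        y_full, ev = response_scores(curve, cfg)
        K = int(np.searchsorted(np.cumsum(ev) / ev.sum(), 0.8 - 1e-12) + 1)
        x = encode(g1).values
        z = encode(g2).values
        design = build_design(x, z)
        ref = trailing_block_test(fit(design, y_full.scores[:, :K]), 1)
        assert p == pytest.approx(ref.p_value, rel=1e-10)

    def test_matches_enumeration_oracle(self, toy):
        g1, g2, curve = toy
        cfg = BfgmConfig(grid_m=8)
        p, pair = minp_pairwise(g1, g2, curve, config=cfg)
        from funepi.bfgm import response_scores

        y_full, ev = response_scores(curve, cfg)
        K = int(np.searchsorted(np.cumsum(ev) / ev.sum(), 0.8 - 1e-12) + 1)
        Y = y_full.scores[:, :K]
        e1, e2 = encode(g1), encode(g2)
        best = np.inf
        best_pair = None
        for a in range(g1.n_snps):
            for b in range(g2.n_snps):
                design = build_design(e1.values[:, [a]], e2.values[:, [b]])
                res = trailing_block_test(fit(design, Y), 1)
                if res.p_value < best:
                    best = res.p_value
                    best_pair = (g1.positions[a], g2.positions[b])
        assert p == pytest.approx(best, rel=1e-12)
        assert pair == best_pair

    def test_recovers_injected_pair(self, rng):
        n = 400
        grid = CommonGrid(8)
        hits = 0
        for rep in range(10):
            g1 = GenotypeMatrix(
                rng.binomial(2, [0.3, 0.4, 0.2], (n, 3)), [1, 2, 3], ("1", 1, 9)
            )
            g2 = GenotypeMatrix(
                rng.binomial(2, [0.25, 0.35], (n, 2)), [5, 6], ("2", 1, 9)
            )
            sig = (encode(g1).values[:, 1] * encode(g2).values[:, 0])[:, None]
            vals = rng.normal(size=(n, 9)) + 2.0 * sig * np.linspace(0, 1, 9)
            curve = PositionCurve(grid.points, vals, ("T", 0, 1))
            _, pair = minp_pairwise(g1, g2, curve, config=BfgmConfig(grid_m=8))
            hits += pair == (2, 5)
        assert hits >= 9


class TestPcaRegression:
    def test_rank_one_response_keeps_single_component(self, rng):
        n = 80
        g1 = GenotypeMatrix(rng.binomial(2, 0.3, (n, 2)), [1, 2], ("1", 1, 9))
        g2 = GenotypeMatrix(rng.binomial(2, 0.3, (n, 2)), [5, 6], ("2", 1, 9))
        grid = CommonGrid(8)
        f = np.sin(np.pi * grid.points)
        levels = rng.normal(size=n)
        curve = PositionCurve(
            grid.points, 3.0 + levels[:, None] * f[None, :], ("T", 0, 1)
        )
        res = pca_regression_test(g1, g2, curve)
        assert res.K == 1

    def test_component_count_matches_eigen_oracle(self, toy):
        g1, g2, curve = toy
        res = pca_regression_test(g1, g2, curve, var_explained=0.8)
        X = curve.values - curve.values.mean(axis=0)
        ev = np.linalg.svd(X, compute_uv=False) ** 2
        k_oracle = int(np.searchsorted(np.cumsum(ev) / ev.sum(), 0.8 - 1e-12) + 1)
        assert res.K == k_oracle

    def test_flat_curves_agree_with_other_tests(self, rng):
        n = 100
        g1 = GenotypeMatrix(rng.binomial(2, 0.3, (n, 2)), [1, 2], ("1", 1, 9))
        g2 = GenotypeMatrix(rng.binomial(2, 0.2, (n, 2)), [5, 6], ("2", 1, 9))
        levels = rng.normal(10.0, 2.0, size=n)
        grid = CommonGrid(8)
        curve = PositionCurve(
            grid.points, np.tile(levels[:, None], (1, 9)), ("T", 0, 1)
        )
        cfg = BfgmConfig(grid_m=8)
        b = run_bfgm(g1, g2, curve, config=cfg)
        p = pca_regression_test(g1, g2, curve, config=cfg)
        s = sfgm_test(g1, g2, ScalarTrait(levels), config=cfg)
        assert p.p_value == pytest.approx(b.p_value, abs=1e-8)
        assert s.p_value == pytest.approx(b.p_value, abs=1e-8)


class TestCalibration:
    @pytest.mark.parametrize("method", ["sfgm", "pca"])
    def test_null_type1_error_within_99ci(self, method, rng):
        n = 300
        reps = 300
        g1 = GenotypeMatrix(
            rng.binomial(2, rng.uniform(0.1, 0.4, 4), (n, 4)),
            [1, 2, 3, 4], ("1", 1, 9),
        )
        g2 = GenotypeMatrix(
            rng.binomial(2, rng.uniform(0.1, 0.4, 4), (n, 4)),
            [5, 6, 7, 8], ("2", 1, 9),
        )
        grid = CommonGrid(16)
        cfg = BfgmConfig(grid_m=16)
        # smooth low-rank curves as under the correlated-error null model
        f1 = np.sin(np.pi * grid.points)
        f2 = np.cos(np.pi * grid.points)
        rej = 0
        for _ in range(reps):
            vals = (
                5.0
                + rng.normal(size=(n, 1)) * f1
                + 0.5 * rng.normal(size=(n, 1)) * f2
                + 0.05 * rng.normal(size=(n, 17))
            )
            curve = PositionCurve(grid.points, vals, ("T", 0, 1))
            if method == "sfgm":
                p = sfgm_test(
                    g1, g2, ScalarTrait(vals.sum(axis=1)), config=cfg
                ).p_value
            else:
                p = pca_regression_test(g1, g2, curve, config=cfg).p_value
            rej += p < 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < half + 1e-12
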
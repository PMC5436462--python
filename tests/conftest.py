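import numpy as np
import pytest

from funepi.curves import CommonGrid, PositionCurve
from funepi.genotypes import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_grid():
    return CommonGrid(16)


@pytest.fixture
def random_curves(rng):
    """40 smooth random curves on a 33-point grid."""
    grid = CommonGrid(32)
    t = grid.points
    basis = np.vstack([np.ones_like(t), np.sin(np.pi * t), np.cos(np.pi * t)])
    coefs = rng.normal(size=(40, 3)) * np.array([2.0, 1.0, 0.5])
    return PositionCurve(t, coefs @ basis + 5.0, region=("X", 0, 1))


def hwe_counts(n_AA, n_Aa, n_aa, positions=None, region=("1", 1, 1000)):
    """GenotypeMatrix with one SNP of the given genotype counts."""
    col = np.concatenate(
        [np.zeros(n_AA, int), np.ones(n_Aa, int), np.full(n_aa, 2, int)]
    )
    pos = positions if positions is not None else [100]
    return GenotypeMatrix(col[:, None], np.asarray(pos), region)
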
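import numpy as np
import pytest

from teadiv.core import GenotypeMatrix, PopulationMap
from teadiv.simulate import make_study_like_dataset


@pytest.fixture(scope="session")
def study_bundle():
    """One synthetic survey bundle shared across tests (fixed seed)."""
    return make_study_like_dataset(7)


@pytest.fixture
def toy_genotypes():
    """4 individuals x 2 loci, one missing call, known allele counts."""
    calls = np.array(
        [
            [[100, 104], [200, 200]],
            [[100, 100], [200, 202]],
            [[104, 108], [-1, -1]],
            [[100, 104], [202, 202]],
        ]
    )
    g = GenotypeMatrix(["a", "b", "c", "d"], ["L1", "L2"], calls)
    m = PopulationMap({"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
    return g, m


def random_distance_matrix(labels, rng):
    """Generic random symmetric distance matrix (tie-free with prob. 1)."""
    from teadiv.core import DistanceMatrix

    n = len(labels)
    a = rng.random((n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return DistanceMatrix(labels, a)
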
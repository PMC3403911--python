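import numpy as np
import pytest

from seqspace import (
    DistanceMatrix,
    distance_matrix,
    mmds,
    synthetic_families,
)


@pytest.fixture(scope="session")
def family_alignment():
    """4 well-separated synthetic protein families, 25 sequences each."""
    aln, labels = synthetic_families(
        n_families=4, seqs_per_family=25, n_col=100, mutation_rate=0.1, seed=11
    )
    return aln, labels


@pytest.fixture(scope="session")
def family_space(family_alignment):
    aln, _ = family_alignment
    return mmds(distance_matrix(aln, "sqrt_difference"))


@pytest.fixture(scope="session")
def small_alignment():
    aln, labels = synthetic_families(
        n_families=3, seqs_per_family=5, n_col=40, mutation_rate=0.08, seed=3
    )
    return aln, labels


def euclidean_distance_matrix(points, ids=None):
    """Square DistanceMatrix of a point configuration."""
    from scipy.spatial.distance import pdist, squareform

    points = np.asarray(points, dtype=float)
    ids = list(ids) if ids is not None else [f"p{i}" for i in range(len(points))]
    return DistanceMatrix(
        row_ids=ids, col_ids=ids, values=squareform(pdist(points))
    )
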
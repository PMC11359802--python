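import numpy as np
import pytest

from chai.assignments import ClusterAssignment, align_ensemble, to_binary_similarity


def random_assignment(m, k, rng, name="algo"):
    """A partition of m cells into exactly k non-empty clusters."""
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=m - k)])
    rng.shuffle(labels)
    return ClusterAssignment(
        algorithm_name=name,
        cell_ids=tuple(f"c{i}" for i in range(m)),
        labels=tuple(str(l) for l in labels),
    )


def random_binary_matrix(m, rng, k=None):
    """A valid binary co-membership matrix from a random partition."""
    k = k or rng.integers(2, max(3, m // 3))
    return to_binary_similarity(random_assignment(m, k, rng)).values.astype(float)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_block_assignment():
    """15 cells in 3 equal clusters, block-ordered."""
    return ClusterAssignment(
        algorithm_name="blocks",
        cell_ids=tuple(f"c{i}" for i in range(15)),
        labels=tuple(["A"] * 5 + ["B"] * 5 + ["C"] * 5),
    )


@pytest.fixture
def perfect_ensemble(three_block_assignment):
    copies = [
        ClusterAssignment(
            algorithm_name=f"copy{i}",
            cell_ids=three_block_assignment.cell_ids,
            labels=three_block_assignment.labels,
        )
        for i in range(3)
    ]
    return align_ensemble(copies)
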
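"""Synthetic fixtures: ground-truth partitions, noisy label ensembles,
negative-binomial expression counts, and spatially organised coordinates.

The ensemble error model is symmetric label corruption: each simulated
"algorithm" independently reassigns each cell, with probability
``flip_rate``, to a uniformly chosen *wrong* cluster.  Errors are therefore
independent across views — exactly the regime in which consensus voting is
expected to help.  Real clustering algorithms make correlated errors; that
is deliberately not modelled here.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assignments import ClusterAssignment
from .errors import ValidationError
from .spatial import SpatialCoordinates

__all__ = [
    "SyntheticScenario",
    "simulate_truth",
    "simulate_noisy_views",
    "simulate_expression",
    "simulate_spatial",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one simulated consensus-clustering experiment.

    Parameters
    ----------
    m
        Number of cells.
    k_true
        Number of ground-truth clusters (≥ 2).
    proportions
        Cluster-size weights summing to 1; ``None`` = equal sizes.
    flip_rate
        Per-cell probability that a view reassigns the cell to a uniformly
        random wrong cluster (0 ≤ rate < 1).
    n_views
        Number of simulated algorithms in the ensemble.
    spatial_separation
        Ratio of between-cluster centre spacing to within-cluster spread of
        the simulated coordinates; ≥ ~5 gives nearly pure spatial
        neighbourhoods, ≤ ~0.5 is near-uninformative.
    seed
        Base seed; every generator derives its randomness from it.
    """

    m: int = 300
    k_true: int = 3
    proportions: tuple[float, ...] | None = None
    flip_rate: float = 0.1
    n_views: int = 5
    spatial_separation: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValidationError("k_true must be >= 2")
        if not (0 <= self.flip_rate < 1):
            raise ValidationError("flip_rate must be in [0, 1)")
        if self.proportions is not None:
            p = tuple(float(x) for x in self.proportions)
            if len(p) != self.k_true:
                raise ValidationError("proportions length must equal k_true")
            if abs(sum(p) - 1.0) > 1e-9 or min(p) <= 0:
                raise ValidationError("proportions must be positive and sum to 1")
            object.__setattr__(self, "proportions", p)
        if self.m < self.k_true:
            raise ValidationError("need at least one cell per cluster")


def _cluster_sizes(m: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of m cells to the given weights."""
    quotas = np.asarray(proportions) * m
    sizes = np.floor(quotas).astype(int)
    remainder = m - sizes.sum()
    if remainder:
        order = np.argsort(-(quotas - sizes), kind="stable")
        sizes[order[:remainder]] += 1
    return sizes


def simulate_truth(scenario: SyntheticScenario) -> ClusterAssignment:
    """Ground-truth partition: m cells over k_true clusters per proportions.

    Cluster sizes use largest-remainder rounding; cells are then assigned in
    a seeded random order so cluster membership is not a function of cell
    index.
    """
    rng = np.random.default_rng(scenario.seed)
    props = scenario.proportions or tuple([1.0 / scenario.k_true] * scenario.k_true)
    sizes = _cluster_sizes(scenario.m, props)
    labels = np.repeat(np.arange(1, scenario.k_true + 1), sizes)
    rng.shuffle(labels)
    width = len(str(scenario.m))
    cell_ids = tuple(f"cell_{i:0{width}d}" for i in range(1, scenario.m + 1))
    return ClusterAssignment(
        algorithm_name="truth", cell_ids=cell_ids, labels=tuple(str(l) for l in labels)
    )


def simulate_noisy_views(
    truth: ClusterAssignment,
    n_views: int,
    flip_rate: float,
    seed: int = 0,
) -> list[ClusterAssignment]:
    """Independent noisy copies of the truth, one per simulated algorithm.

    Each view flips each cell's label with probability ``flip_rate`` to a
    uniformly chosen different cluster; randomness is independent across
    views and cells.
    """
    if not (0 <= flip_rate < 1):
        raise ValidationError("flip_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    alphabet = sorted(set(truth.labels))
    k = len(alphabet)
    index = {l: i for i, l in enumerate(alphabet)}
    base = np.array([index[l] for l in truth.labels])
    m = len(base)
    views = []
    for v in range(n_views):
        flip = rng.random(m) < flip_rate
        offset = rng.integers(1, k, size=m)  # uniform over the k-1 wrong labels
        labels = np.where(flip, (base + offset) % k, base)
        views.append(
            ClusterAssignment(
                algorithm_name=f"view_{v + 1}",
                cell_ids=truth.cell_ids,
                labels=tuple(alphabet[c] for c in labels),
            )
        )
    return views


def simulate_expression(
    truth: ClusterAssignment,
    genes: int = 200,
    effect_size: float = 4.0,
    seed: int = 0,
    markers_per_cluster: int = 10,
    dispersion: float = 2.0,
) -> pd.DataFrame:
    """Cells×genes negative-binomial counts with cluster marker signal.

    Each cluster gets ``markers_per_cluster`` disjoint marker genes whose
    mean is multiplied by ``effect_size`` in that cluster; all other means
    are shared lognormal baselines.  ``effect_size=0`` collapses the fold
    change to 1 (no signal).  Counts are NB with gamma-shape ``dispersion``
    (smaller = noisier).
    """
    if genes < 10:
        raise ValidationError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    alphabet = sorted(set(truth.labels))
    k = len(alphabet)
    if genes < k * markers_per_cluster:
        markers_per_cluster = max(1, genes // (2 * k))
    codes = np.array([alphabet.index(l) for l in truth.labels])
    m = len(codes)

    base_mean = rng.lognormal(mean=1.0, sigma=0.5, size=genes)
    mean = np.tile(base_mean, (m, 1))
    fold = effect_size if effect_size > 0 else 1.0
    for c in range(k):
        marker_idx = np.arange(c * markers_per_cluster, (c + 1) * markers_per_cluster)
        rows = np.where(codes == c)[0]
        mean[np.ix_(rows, marker_idx)] *= fold

    # NB via gamma-Poisson mixture: mean μ, shape r=dispersion
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    counts = rng.poisson(lam)
    gene_names = [f"gene_{j + 1}" for j in range(genes)]
    return pd.DataFrame(counts, index=list(truth.cell_ids), columns=gene_names)


def simulate_spatial(
    truth: ClusterAssignment,
    spatial_separation: float = 10.0,
    seed: int = 0,
) -> SpatialCoordinates:
    """2-D coordinates with one Gaussian blob per truth cluster.

    Cluster centres sit on a unit-spacing grid scaled by
    ``spatial_separation``; within-cluster spread is standard normal, so
    the separation parameter is directly the between/within ratio.
    """
    if spatial_separation <= 0:
        raise ValidationError("spatial_separation must be > 0")
    rng = np.random.default_rng(seed)
    alphabet = sorted(set(truth.labels))
    k = len(alphabet)
    side = int(np.ceil(np.sqrt(k)))
    centers = np.array(
        [(c % side, c // side) for c in range(k)], dtype=float
    ) * spatial_separation
    codes = np.array([alphabet.index(l) for l in truth.labels])
    coords = centers[codes] + rng.standard_normal((len(codes), 2))
    return SpatialCoordinates(cell_ids=truth.cell_ids, coords=coords)
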